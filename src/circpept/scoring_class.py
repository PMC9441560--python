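"""Coding-potential scoring, IRES labeling, and six-class assignment.

A Naive Bayes classifier trained on coding-like peptides (proteins and
ncRNA-encoded peptides) versus randomly generated peptides gives every cORF a
0/1 coding score.  IRES status comes from a pluggable score source (e.g. a
precomputed table from an external IRES predictor) thresholded strictly at
0.5; circles labeled Non-IRES are retained, never dropped, since other
cap-independent mechanisms (e.g. m6A) may drive translation.  The lap group
of the supporting cORF crossed with the IRES label places each translatable
circRNA into one of six classes I-VI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB

from .corf_engine import CORF, LAP_GROUPS

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

FEATURE_SCHEMA = "comp20+loglen+dipep400/v1"

#: Fixed class convention: lap group x IRES label.
CLASS_MAP = {
    (LAP_GROUPS[0], "IRES"): "I",
    (LAP_GROUPS[0], "Non-IRES"): "II",
    (LAP_GROUPS[1], "IRES"): "III",
    (LAP_GROUPS[1], "Non-IRES"): "IV",
    (LAP_GROUPS[2], "IRES"): "V",
    (LAP_GROUPS[2], "Non-IRES"): "VI",
}


@dataclass
class CodingDataset:
    """Positive (coding-like) and negative (random) peptide sets with the
    train/test split fraction (8:2 by default)."""

    positives: Sequence[str]
    negatives: Sequence[str]
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(f"positive/negative sets overlap: {sorted(overlap)[:3]}")


@dataclass
class CodingModel:
    """A fitted coding-potential classifier plus its held-out test accuracy."""

    schema: str
    estimator: GaussianNB
    test_accuracy: float
    n_train: int
    n_test: int


@dataclass(frozen=True)
class ScoringConfig:
    ires_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.ires_threshold < 1:
            raise ValueError("ires_threshold must lie in (0, 1)")


def featurize_peptide(pep: str) -> np.ndarray:
    """Deterministic 421-dim feature vector: 20 amino-acid composition
    fractions, log length, and 400 dipeptide frequencies."""
    if not pep:
        raise ValueError("empty peptide")
    pep = pep.upper()
    n = len(pep)
    comp = np.zeros(20)
    for a in pep:
        if a not in _AA_INDEX:
            raise ValueError(f"non-standard residue {a!r}")
        comp[_AA_INDEX[a]] += 1
    comp /= n
    dipep = np.zeros(400)
    for a, b in zip(pep, pep[1:]):
        dipep[_AA_INDEX[a] * 20 + _AA_INDEX[b]] += 1
    if n > 1:
        dipep /= n - 1
    return np.concatenate([comp, [np.log(n)], dipep])


def featurize_many(peps: Iterable[str]) -> np.ndarray:
    return np.vstack([featurize_peptide(p) for p in peps])


def train_coding_model(ds: CodingDataset) -> CodingModel:
    """Fit Gaussian Naive Bayes on the feature schema with a stratified
    shuffled train/test split; the held-out accuracy is recorded on the model.
    Deterministic given (dataset, seed)."""
    if len(ds.positives) < 10 or len(ds.negatives) < 10:
        raise ValueError("each class needs at least 10 examples")
    X = featurize_many(list(ds.positives) + list(ds.negatives))
    y = np.concatenate([np.ones(len(ds.positives)), np.zeros(len(ds.negatives))])
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y,
        train_size=ds.train_fraction,
        random_state=ds.seed,
        shuffle=True,
        stratify=y,
    )
    est = GaussianNB()
    est.fit(X_tr, y_tr)
    acc = float(est.score(X_te, y_te))
    return CodingModel(
        schema=FEATURE_SCHEMA,
        estimator=est,
        test_accuracy=acc,
        n_train=len(y_tr),
        n_test=len(y_te),
    )


def score_corfs(corfs: Sequence[CORF], model: CodingModel) -> dict[tuple[str, int], int]:
    """0/1 coding score per cORF (1 = coding-like), keyed by
    (circ_id, corf_index); deterministic given the model."""
    if not corfs:
        return {}
    X = featurize_many([c.peptide for c in corfs])
    pred = model.estimator.predict(X).astype(int)
    return {(c.circ_id, c.corf_index): int(s) for c, s in zip(corfs, pred)}


def label_ires(
    scores: Mapping[str, float], cfg: ScoringConfig = ScoringConfig()
) -> dict[str, str]:
    """Label each circRNA "IRES" when its score is strictly greater than the
    threshold, else "Non-IRES"; no circle is dropped."""
    out = {}
    for circ_id, s in scores.items():
        if not 0 <= s <= 1:
            raise ValueError(f"{circ_id}: IRES score {s} outside [0, 1]")
        out[circ_id] = "IRES" if s > cfg.ires_threshold else "Non-IRES"
    return out


def read_ires_table(path: str | Path) -> dict[str, float]:
    """Two-column TSV circ_id<TAB>score (header optional)."""
    scores: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            try:
                scores[parts[0]] = float(parts[1])
            except ValueError:
                continue  # header row
    return scores


def classify_circ(group: str, ires: str) -> str:
    """Fixed mapping from (lap group, IRES label) to class I-VI.

    Class I, for example, holds circles whose cORF is shorter than the full
    circle (laps < 1) with IRES-driven translation.
    """
    try:
        return CLASS_MAP[(group, ires)]
    except KeyError:
        raise ValueError(f"unknown (group, ires) combination: ({group!r}, {ires!r})")
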