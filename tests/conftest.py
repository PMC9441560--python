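import pytest

from circpept import SynthConfig, gen_circ_set, gen_peptides


@pytest.fixture(scope="session")
def synth_small():
    """50 circles, 60% with a planted BSJ-crossing cORF (20% of those
    stopless), true junction peptides for half of the planted circles plus
    60 random noise peptides."""
    cfg = SynthConfig(seed=11, n_circ=50, frac_with_corf=0.6,
                      frac_true_junction_peptides=0.5, n_noise_peptides=60,
                      icorf_fraction=0.2)
    circs, truth = gen_circ_set(cfg)
    peps, labels = gen_peptides(circs, truth, cfg)
    return dict(cfg=cfg, circs=circs, truth=truth, peptides=peps, labels=labels)
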