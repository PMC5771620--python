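import pytest

from circout.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Reference synthetic cohort: 2000 genes, sigma=0.1, fixed seed."""
    cfg = SimulationConfig(seed=7, n_genes=2000, sigma=0.1)
    genes, peaks_a, peaks_b, truth, nascent, mrna = simulate_cohort(cfg)
    return {
        "cfg": cfg,
        "genes": genes,
        "peaks_a": peaks_a,
        "peaks_b": peaks_b,
        "truth": truth,
        "nascent": nascent,
        "mrna": mrna,
    }


@pytest.fixture(scope="session")
def small_cohort():
    """Noise-free 150-gene cohort for exact-recovery checks."""
    cfg = SimulationConfig(seed=3, n_genes=150, sigma=0.0, n_decoys_per_factor=30)
    genes, peaks_a, peaks_b, truth, nascent, mrna = simulate_cohort(cfg)
    return {
        "cfg": cfg,
        "genes": genes,
        "peaks_a": peaks_a,
        "peaks_b": peaks_b,
        "truth": truth,
        "nascent": nascent,
        "mrna": mrna,
    }
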