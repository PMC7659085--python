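"""Shared fixtures: small simulated datasets reused across test modules."""

import pytest

from ohnorhythm.simulate import (
    HomologySimConfig,
    SimulationConfig,
    simulate_counts,
    simulate_homology,
)


@pytest.fixture(scope="session")
def small_sim():
    """Two organs, 120 genes, strong planted rhythms: enough signal for
    detection at the Bonferroni-corrected 0.01 cutoff."""
    cfg = SimulationConfig(
        n_genes=120,
        organs=("skin", "liver"),
        cyclic_fraction=0.25,
        amplitude_range=(0.8, 1.0),
        seed=42,
    )
    return cfg, *simulate_counts(cfg)


@pytest.fixture(scope="session")
def homology_sim():
    """50 planted ohnolog pairs, 100 singletons, two decoy units of each
    of the eight decoy classes."""
    cfg = HomologySimConfig(n_ohnolog_pairs=50, n_singletons=100, seed=3)
    table, truth = simulate_homology(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def rhythm_results(small_sim):
    from ohnorhythm.rhythm import detect_rhythms

    _, cm, truth = small_sim
    res = detect_rhythms(cm, n_perm=10_000, seed=5)
    return cm, truth, res
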