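"""Shared fixtures: small simulated experiments reused across test modules."""

import pytest

from diaforge.core import AssayLibrary
from diaforge.library import generate_decoys
from diaforge.simulate import (
    SimConfig,
    generate_ground_truth,
    make_cascade_fixture,
    simulate_dia_experiment,
)


@pytest.fixture(scope="session")
def small_experiment():
    """A compact 4-population, 2-batch experiment with planted effects."""
    cfg = SimConfig(
        seed=11,
        n_proteins=40,
        peptides_per_protein=(2, 2),
        n_populations=4,
        replicates=3,
        batches=2,
        frac_differential=0.1,
        frac_signal_free=0.1,
    )
    lib, truth, annot = generate_ground_truth(cfg)
    full = AssayLibrary(lib.precursors + generate_decoys(lib, seed=11).precursors)
    chroms = simulate_dia_experiment(full, truth, cfg)
    return cfg, lib, full, truth, annot, chroms


@pytest.fixture(scope="session")
def cascade_fixture():
    return make_cascade_fixture(seed=7)
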