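import numpy as np
import pytest

from smallrna.core_io import CountTable, ReferenceLibrary
from smallrna.simulate import SimProfile, simulate_abundances, simulate_references


@pytest.fixture
def mirna_library() -> ReferenceLibrary:
    return ReferenceLibrary(
        name="mir",
        rna_class="miRNA",
        entries=[
            ("mir-1", "TGGAATGTAAAGAAGTATGTAT"),
            ("mir-2", "ACCCGTAGATCCGAACTTGTG"),
        ],
    )


@pytest.fixture
def small_table() -> CountTable:
    return CountTable(
        features=[("f1", "miRNA"), ("f2", "miRNA"), ("f3", "piRNA")],
        samples=["A", "B"],
        counts=np.array([[10.0, 5.0], [100.0, 120.0], [0.0, 7.0]]),
    )


@pytest.fixture(scope="session")
def sim_setup():
    """A small simulated study: references + abundances under a fixed seed."""
    profile = SimProfile(
        rng_seed=7,
        n_reads=4000,
        features_per_class={"miRNA": 30, "tRNA": 5, "rRNA": 2, "mRNA": 5, "piRNA": 10, "other": 3},
    )
    libraries = simulate_references(profile)
    abundances = simulate_abundances(profile, libraries)
    return profile, libraries, abundances
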