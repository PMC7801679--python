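import numpy as np
import pytest

from epihetkit import (
    EpialleleProfile,
    LocusKey,
    ModuleCohortSpec,
    SimulationSpec,
    simulate_module_cohort,
    simulate_profiles,
)


@pytest.fixture
def locus():
    return LocusKey("chr1", (100, 110, 120, 130), "+")


@pytest.fixture
def uniform_profile(locus):
    return EpialleleProfile(locus, np.full(16, 10))


@pytest.fixture
def clonal_profile(locus):
    counts = np.zeros(16, dtype=int)
    counts[15] = 60
    return EpialleleProfile(locus, counts)


def make_profile(locus, **code_counts):
    counts = np.zeros(16, dtype=int)
    for code, n in code_counts.items():
        counts[int(code)] = n
    return EpialleleProfile(locus, counts)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-group cohort: 6 planted DEH loci among 120, 5 vs 5 samples."""
    spec = SimulationSpec(seed=20, n_loci=120, n_samples=(5, 5))
    return simulate_profiles(spec)


@pytest.fixture(scope="session")
def module_cohort():
    """Two planted 40-node modules plus 120 background nodes, 12 samples."""
    return simulate_module_cohort(ModuleCohortSpec(seed=3))
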