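import pytest

from tease16.codebook import (
    AreaFramework,
    EnforcementLevel,
    PolicyObservation,
    default_codebook,
)
from tease16.scoring import star_weight_scheme
from tease16.synthetic import SimConfig, generate_frameworks


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture(scope="session")
def baseline(codebook):
    return star_weight_scheme("baseline", codebook)


def uniform_framework(codebook, area, level="max", enforcement="strong"):
    """Framework with every topic at its highest/lowest stringency level."""
    obs = []
    for t in codebook:
        lab = t.stringency_levels[-1 if level == "max" else 0]
        obs.append(PolicyObservation(area, t.id, lab, EnforcementLevel(enforcement)))
    return AreaFramework(area, tuple(obs))


@pytest.fixture(scope="session")
def all_max_framework(codebook):
    return uniform_framework(codebook, "allmax", "max", "strong")


@pytest.fixture(scope="session")
def all_min_framework(codebook):
    return uniform_framework(codebook, "allmin", "min", "poor")


@pytest.fixture(scope="session")
def nine_areas():
    return generate_frameworks(SimConfig(n_areas=9, seed=7))
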