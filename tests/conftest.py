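import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from phfeedback.model import load_archetypes

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

ARCHETYPE_KEYS = {
    "lp": "acid_lover_acidifier",
    "ca": "alkali_lover_alkalizer",
    "pv": "acid_lover_alkalizer",
    "sm": "mid_lover_acidifier",
}

#: canonical pairings exercising the four coculture motifs
MOTIF_PAIRS = {
    "bistability": ("lp", "ca"),
    "successive_growth": ("sm", "lp"),
    "extended_suicide": ("pv", "lp"),
    "stabilization": ("sm", "pv"),
}


@pytest.fixture(scope="session")
def archetypes():
    species, env = load_archetypes()
    return {short: species[full] for short, full in ARCHETYPE_KEYS.items()}, env


@pytest.fixture(scope="session")
def small_grids():
    return {
        "density": np.geomspace(1e-3, 9.0, 7),
        "fraction": np.linspace(0.0, 1.0, 7),
        "p0": np.linspace(0.5, 9.5, 7),
    }


@pytest.fixture(scope="session")
def single_sweeps_small(archetypes, small_grids):
    """Monoculture sweeps of the four archetypes on a small grid (shared)."""
    from phfeedback.outcomes import sweep_single

    species, env = archetypes
    return {
        key: sweep_single(sp, env, small_grids["density"], small_grids["p0"])
        for key, sp in species.items()
    }


@pytest.fixture(scope="session")
def pair_sweeps_small(archetypes, small_grids):
    """Coculture sweeps of the four canonical pairings on a small grid."""
    from phfeedback.outcomes import sweep_pair

    species, env = archetypes
    return {
        motif: sweep_pair(
            species[a], species[b], env, small_grids["fraction"], small_grids["p0"]
        )
        for motif, (a, b) in MOTIF_PAIRS.items()
    }


@pytest.fixture(scope="session")
def fuzzy_config():
    from phfeedback.fuzzy import load_fuzzy_config

    return load_fuzzy_config()


@pytest.fixture(scope="session")
def fuzzy_archetypes(archetypes):
    from phfeedback.fuzzy import FuzzySpecies

    species, env = archetypes
    return {k: FuzzySpecies.from_species_params(sp, env) for k, sp in species.items()}
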