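import numpy as np
import pandas as pd
import pytest

from traitenv.glmm import ModelData, ModelStructure
from traitenv.synthetic import make_scenario


@pytest.fixture(scope="session")
def tiny_data() -> ModelData:
    """2 species x 4 plots, centered covariates, fixed seed."""
    rng = np.random.default_rng(42)
    n, m = 4, 2
    X = rng.normal(0, 0.5, (n, 3))
    X -= X.mean(axis=0)
    Z = rng.normal(0, 0.5, (m, 4))
    Z -= Z.mean(axis=0)
    Y = rng.integers(0, 2, (n, m)).astype(float)
    return ModelData(X=X, Z=Z, Y=Y)


@pytest.fixture(scope="session")
def intercept_structure() -> ModelStructure:
    """Species random intercept only, no site effect (quadrature-friendly)."""
    return ModelStructure(species_effects=("intercept",), site_effect=False)


@pytest.fixture(scope="session")
def small_scenario():
    """Reduced community for fast end-to-end runs (full layout, fewer species)."""
    return make_scenario(m_species=8, seed=123)


@pytest.fixture(scope="session")
def default_scenario():
    return make_scenario(seed=202)


@pytest.fixture(scope="session")
def synthetic_tables(default_scenario):
    """Full plot/trait/occurrence tables at the default study layout."""
    from traitenv.synthetic import gen_occurrence, gen_topography, gen_traits

    rng = np.random.default_rng(default_scenario.seed)
    plots = gen_topography(default_scenario, rng)
    traits = gen_traits(default_scenario, rng)
    occurrence, truth = gen_occurrence(plots, traits, default_scenario, rng)
    return plots, traits, occurrence, truth
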