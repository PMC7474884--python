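import numpy as np
import pytest

from memsel import (
    SyntheticBaselineConfig,
    build_design,
    fit_species_glms,
    generate_baseline_community,
    generate_coordinates,
    mem_basis,
    mst_edges,
    pairwise_distances,
    weight_matrix,
)
from memsel.evaluation import DatasetSpec, build_basis, prepare_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20201)


@pytest.fixture(scope="session")
def small_coords():
    """10 well-spread seeded points on a 100x100 window."""
    r = np.random.default_rng(5)
    return r.uniform(0, 100, size=(10, 2))


@pytest.fixture(scope="session")
def chain_weighting():
    """4-site chain with unit binary weights (adjacent pairs only)."""
    W = np.zeros((4, 4))
    for i in range(3):
        W[i, i + 1] = W[i + 1, i] = 1.0
    return W


@pytest.fixture(scope="session")
def small_basis():
    """MEM basis of 20 seeded sites (MST, linear similarity)."""
    r = np.random.default_rng(17)
    xy = r.uniform(0, 50, size=(20, 2))
    d = pairwise_distances(xy)
    return mem_basis(weight_matrix(mst_edges(d), d))


@pytest.fixture(scope="session")
def river_prep():
    """Prepared 30-site river (AEM) dataset, cached for the whole session."""
    spec = DatasetSpec(
        name="river",
        connectivity="aem",
        synthetic=SyntheticBaselineConfig(
            n_sites=30, n_species=47, layout="river-tree", seed=30
        ),
    )
    return prepare_dataset(spec)


@pytest.fixture(scope="session")
def baseline_fit(small_basis):
    """Community + per-species GLM coefficients on the small MEM basis."""
    cfg = SyntheticBaselineConfig(n_sites=20, n_species=40, seed=9)
    r = np.random.default_rng(77)
    X = build_design(small_basis)
    eta = -1.0 + small_basis.vectors @ r.normal(0, 2.0, size=(small_basis.m, 40))
    Y = (r.random((20, 40)) < 1 / (1 + np.exp(-eta))).astype(int)
    C = fit_species_glms(Y, X)
    return Y, X, C
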