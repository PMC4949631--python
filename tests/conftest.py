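import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from semdyn import (
    NormsGenConfig,
    PropertyNorms,
    concept_statistics,
    feature_correlations,
    feature_statistics,
    generate_norms,
    sharedness_bands,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_norms(rows):
    """Build PropertyNorms from (concept, feature, freq, taxonomic) tuples."""
    return PropertyNorms(
        pd.DataFrame(rows, columns=["concept", "feature", "prod_freq", "taxonomic"])
    )


@pytest.fixture
def toy_norms():
    """Three concepts, five features; f_pair occurs in exactly two concepts,
    f_all in all three (shared), the rest are unique."""
    return make_norms(
        [
            ("cat", "has_fur", 20, False),
            ("cat", "f_pair", 10, False),
            ("cat", "f_all", 5, False),
            ("cat", "is_animal", 12, True),
            ("dog", "barks", 18, False),
            ("dog", "f_pair", 8, False),
            ("dog", "f_all", 6, False),
            ("dog", "is_animal", 11, True),
            ("eel", "swims", 15, False),
            ("eel", "f_all", 7, False),
        ]
    )


@pytest.fixture(scope="session")
def small_norms():
    """Generated norms small enough for brute-force oracles."""
    return generate_norms(
        NormsGenConfig(
            n_concepts=18,
            n_categories=3,
            features_per_concept=(6, 8),
            category_feature_pool=7,
            cross_category_pool=4,
            seed=3,
        )
    )


@pytest.fixture(scope="session")
def small_stats(small_norms):
    fstats = sharedness_bands(feature_statistics(small_norms))
    corr = feature_correlations(small_norms)
    cstats = concept_statistics(small_norms, fstats, corr)
    return fstats, corr, cstats


@pytest.fixture(scope="session")
def desk_norms():
    """The default desk-scale synthetic norms (60 concepts, 6 categories)."""
    return generate_norms(NormsGenConfig())


@pytest.fixture(scope="session")
def desk_stats(desk_norms):
    fstats = sharedness_bands(feature_statistics(desk_norms))
    corr = feature_correlations(desk_norms)
    cstats = concept_statistics(desk_norms, fstats, corr)
    return fstats, corr, cstats


def ols_oracle(y, X):
    """Independent normal-equations solver for standardized OLS betas."""
    Xz = (X - X.mean(axis=0)) / X.std(axis=0)
    yz = (y - y.mean()) / y.std()
    D = np.column_stack([np.ones(len(y)), Xz])
    return np.linalg.solve(D.T @ D, D.T @ yz)[1:]
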