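"""Shared fixtures: one session-scoped planted cohort at the benchmark
size (n=2000, four subgroups) plus a small cohort for cheap unit tests."""

from __future__ import annotations

import warnings

import pytest

from psnrisk.config import CohortConfig
from psnrisk.clustering import fit_kmeans
from psnrisk.network import similarity_matrix
from psnrisk.outcomes import classify_events
from psnrisk.preprocess import build_feature_matrix, impute_and_scale, remove_outliers
from psnrisk.synthetic import generate_cohort

PLANTED_SEED = 101


@pytest.fixture(scope="session")
def planted_cohort():
    """Benchmark cohort: 4 subgroups, default hazards 0.02/0.05/0.10/0.20."""
    return generate_cohort(CohortConfig(n_patients=2000, seed=PLANTED_SEED))


@pytest.fixture(scope="session")
def planted_features(planted_cohort):
    raw = build_feature_matrix(planted_cohort.measurements, planted_cohort.static)
    return impute_and_scale(remove_outliers(raw))


@pytest.fixture(scope="session")
def planted_sim(planted_features):
    return similarity_matrix(planted_features, "cosine")


@pytest.fixture(scope="session")
def planted_model(planted_sim):
    return fit_kmeans(planted_sim, 4, seed=7)


@pytest.fixture(scope="session")
def planted_outcomes(planted_cohort):
    return classify_events(
        planted_cohort.events,
        planted_cohort.static.set_index("patient_id")["cancer_dx_days"],
    )


@pytest.fixture(scope="session")
def small_cohort():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(CohortConfig(n_patients=150, seed=5))
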