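import numpy as np
import pandas as pd
import pytest

import phenorisk as pr
from phenorisk.pipeline import _derive_features
from phenorisk.preprocess import FeatureMatrix, StandardizationParams


def make_matrix(Xn, Xc=None):
    """Ad-hoc FeatureMatrix around raw arrays (identity standardization)."""
    Xn = np.asarray(Xn, dtype=float)
    n, p = Xn.shape
    if Xc is None:
        Xc = np.empty((n, 0), dtype=np.int64)
    Xc = np.asarray(Xc, dtype=np.int64)
    q = Xc.shape[1]
    levels = {f"c{j}": list(range(int(Xc[:, j].max()) + 1)) for j in range(q)}
    params = StandardizationParams(
        numeric_names=[f"x{j}" for j in range(p)],
        means=np.zeros(p),
        sds=np.ones(p),
        categorical_names=[f"c{j}" for j in range(q)],
        levels=levels,
    )
    return FeatureMatrix(
        numeric=Xn,
        categorical=Xc,
        numeric_names=params.numeric_names,
        categorical_names=params.categorical_names,
        params=params,
        row_ids=np.arange(n),
    )


def planted_mixed_data(n_per, centers, cat_codes, seed=0, scale=0.5):
    """Well-separated mixed-data blobs with concordant categories."""
    rng = np.random.default_rng(seed)
    Xn, Xc, truth = [], [], []
    for c, (center, code) in enumerate(zip(centers, cat_codes)):
        Xn.append(rng.normal(center, scale, size=(n_per, len(center))))
        Xc.append(np.full((n_per, 1), code))
        truth += [c] * n_per
    return make_matrix(np.vstack(Xn), np.vstack(Xc)), np.array(truth)


@pytest.fixture(scope="session")
def sdpp_specs():
    return pr.default_specs("sdpp")


@pytest.fixture(scope="session")
def small_cohort(sdpp_specs):
    """2000-participant synthetic cohort with survival and HOMA derived."""
    cc = pr.CohortConfig(n_participants=2000, seed=11)
    base = pr.generate_baseline(sdpp_specs, cc)
    base = pr.generate_survival(base, sdpp_specs, cc)
    return _derive_features(base, "homa1")


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    sub, _ = pr.apply_exclusions(small_cohort)
    m = pr.standardize_and_trim(sub)
    truth = (
        sub.set_index("participant_id").loc[m.row_ids, "true_cluster"].to_numpy()
    )
    return m, truth
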