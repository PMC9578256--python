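"""Variable derivation and feature-matrix construction.

Derives the homeostasis-model indices (HOMA-B, HOMA-IR) from fasting glucose
and insulin, applies glycemic classifications (ADA/WHO impaired fasting
glucose, impaired glucose tolerance, OGTT-defined diabetes), enforces cohort
exclusion rules, and standardizes/encodes the clustering variables into the
mixed numeric/categorical matrix the clusterer consumes.

The HOMA2 computer model is a licensed program with no published closed
form; the default here is the classical closed-form HOMA1 equations
(IR = G·I/22.5, B = 20·I/(G−3.5)), which preserve the relative ordering the
cluster structure depends on. Precomputed HOMA2 output can be passed through
instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "mgdl_to_mmol",
    "compute_homa",
    "classify_prediabetes",
    "classify_diabetes",
    "apply_exclusions",
    "standardize_and_trim",
    "transform_new",
    "inverse_transform",
    "FeatureMatrix",
    "StandardizationParams",
    "ExclusionLog",
    "DEFAULT_NUMERIC_FEATURES",
    "DEFAULT_CATEGORICAL_FEATURES",
]

#: clustering variables: glucose/insulin, derived HOMA indices, adiposity,
#: blood pressure + three social/heredity categoricals
DEFAULT_NUMERIC_FEATURES = (
    "fasting_glucose",
    "fasting_insulin",
    "homa_b",
    "homa_ir",
    "bmi",
    "sbp",
    "dbp",
)
DEFAULT_CATEGORICAL_FEATURES = ("sex", "family_history", "education")

MGDL_PER_MMOL = 0.0555

# glycemic thresholds, mmol/L
ADA_IFG_RANGE = (5.6, 6.9)
WHO_IFG_RANGE = (6.1, 6.9)
IGT_RANGE = (7.8, 11.0)  # [7.8, 11.0): 2-h >= 11.0 is diabetes
FPG_DIABETES = 7.0
TWO_H_DIABETES = 11.0


def mgdl_to_mmol(glucose_mgdl):
    """Convert glucose from mg/dL to mmol/L (× 0.0555)."""
    arr = np.asarray(glucose_mgdl, dtype=float)
    if np.any(arr < 0):
        raise ValueError("glucose cannot be negative")
    out = arr * MGDL_PER_MMOL
    return float(out) if np.isscalar(glucose_mgdl) else out


def compute_homa(glucose, insulin, method="homa1", homa_b=None, homa_ir=None):
    """Beta-cell function and insulin-resistance indices.

    Parameters
    ----------
    glucose : fasting glucose, mmol/L
    insulin : fasting insulin, μU/mL
    method : ``"homa1"`` for the closed-form equations, ``"precomputed"`` to
        pass supplied ``homa_b``/``homa_ir`` columns through unchanged.

    Returns
    -------
    (homa_b, homa_ir). With ``homa1``, glucose ≤ 3.5 mmol/L makes HOMA-B
    undefined; those entries are returned as NaN so the downstream
    missing-value exclusion rule can drop them.
    """
    if method == "precomputed":
        if homa_b is None or homa_ir is None:
            raise ValueError("precomputed method requires homa_b and homa_ir")
        return np.asarray(homa_b, dtype=float), np.asarray(homa_ir, dtype=float)
    if method != "homa1":
        raise ValueError(f"unknown HOMA method {method!r}")
    scalar = np.isscalar(glucose) and np.isscalar(insulin)
    g = np.atleast_1d(np.asarray(glucose, dtype=float))
    i = np.atleast_1d(np.asarray(insulin, dtype=float))
    if np.any(i < 0):
        raise ValueError("insulin cannot be negative")
    if np.any(g[~np.isnan(g)] <= 0):
        raise ValueError("glucose must be positive")
    ir = g * i / 22.5
    with np.errstate(divide="ignore", invalid="ignore"):
        b = 20.0 * i / (g - 3.5)
    b = np.where(g > 3.5, b, np.nan)
    b = np.where(i == 0, 0.0, b)  # zero insulin: both indices zero by formula
    if scalar:
        return float(b[0]), float(ir[0])
    return b, ir


def _in_closed(x, lo, hi):
    return (x >= lo) & (x <= hi)


def classify_prediabetes(fpg, two_h=None, criteria="ADA"):
    """Classify glycemia into {normal, IFG, IGT, IFG+IGT}.

    IFG uses fasting glucose 5.6–6.9 mmol/L (ADA) or 6.1–6.9 mmol/L (WHO);
    IGT uses 2-h glucose in [7.8, 11.0) under both. Missing 2-h glucose
    (e.g. a fasting-only cohort) never yields IGT.
    """
    crit = criteria.upper()
    if crit == "ADA":
        lo, hi = ADA_IFG_RANGE
    elif crit == "WHO":
        lo, hi = WHO_IFG_RANGE
    else:
        raise ValueError(f"unknown criteria {criteria!r}; use 'ADA' or 'WHO'")
    scalar = np.isscalar(fpg)
    g = np.atleast_1d(np.asarray(fpg, dtype=float))
    if two_h is None:
        h = np.full_like(g, np.nan)
    else:
        h = np.atleast_1d(np.asarray(two_h, dtype=float))
        if scalar and h.size == 1 and g.size == 1:
            pass
        h = np.broadcast_to(h, g.shape).copy()
    ifg = _in_closed(g, lo, hi)
    igt = ~np.isnan(h) & (h >= IGT_RANGE[0]) & (h < IGT_RANGE[1])
    out = np.where(
        ifg & igt, "IFG+IGT", np.where(ifg, "IFG", np.where(igt, "IGT", "normal"))
    )
    return str(out[0]) if scalar else out


def classify_diabetes(fpg, two_h=None):
    """OGTT diabetes: fasting glucose ≥ 7.0 mmol/L or 2-h glucose ≥ 11.0."""
    scalar = np.isscalar(fpg)
    g = np.atleast_1d(np.asarray(fpg, dtype=float))
    if two_h is None:
        h = np.full_like(g, np.nan)
    else:
        h = np.broadcast_to(np.atleast_1d(np.asarray(two_h, dtype=float)), g.shape)
    out = (g >= FPG_DIABETES) | (~np.isnan(h) & (h >= TWO_H_DIABETES))
    return bool(out[0]) if scalar else out


@dataclass
class ExclusionLog:
    """Per-rule exclusion counts, in application order."""

    rows_in: int
    rows_out: int
    counts: dict = field(default_factory=dict)  # rule -> rows removed
    removed_ids: dict = field(default_factory=dict)  # rule -> list of ids

    def validate(self) -> None:
        if sum(self.counts.values()) != self.rows_in - self.rows_out:
            raise AssertionError("exclusion counts do not sum to rows removed")


def apply_exclusions(
    cohort: pd.DataFrame,
    rules=("missing", "baseline_diabetes"),
    clustering_features=DEFAULT_NUMERIC_FEATURES + DEFAULT_CATEGORICAL_FEATURES,
    age_window=(30.0, 60.0),
    id_column="participant_id",
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply cohort exclusion rules in a fixed order:
    age window → missing clustering variables → diabetes at baseline.

    ``missing`` is complete-case on the clustering variables only.
    Baseline diabetes uses the OGTT definition on fasting (and, when
    present, 2-h) glucose.
    """
    known = {"missing", "baseline_diabetes", "age_window"}
    unknown = set(rules) - known
    if unknown:
        raise ValueError(f"unknown exclusion rules: {sorted(unknown)}")
    log = ExclusionLog(rows_in=len(cohort), rows_out=len(cohort))
    out = cohort

    order = [r for r in ("age_window", "missing", "baseline_diabetes") if r in rules]
    for rule in order:
        if rule == "age_window":
            lo, hi = age_window
            bad = (out["baseline_age"] < lo) | (out["baseline_age"] > hi)
        elif rule == "missing":
            feats = [f for f in clustering_features if f in out.columns]
            bad = out[feats].isna().any(axis=1)
        else:  # baseline_diabetes
            two_h = out["two_h_glucose"] if "two_h_glucose" in out.columns else None
            bad = pd.Series(
                classify_diabetes(out["fasting_glucose"].to_numpy(),
                                  None if two_h is None else two_h.to_numpy()),
                index=out.index,
            )
        log.counts[rule] = int(bad.sum())
        log.removed_ids[rule] = out.loc[bad, id_column].tolist() if id_column in out else []
        out = out.loc[~bad]
    log.rows_out = len(out)
    log.validate()
    return out.reset_index(drop=True), log


@dataclass
class StandardizationParams:
    """Frozen per-feature standardization and category encodings.

    Fitted once on the baseline analysis set and reused for follow-up
    visits and bootstrap replicates, so cluster geometry is consistent
    over time.
    """

    numeric_names: list
    means: np.ndarray
    sds: np.ndarray
    categorical_names: list
    levels: dict  # feature -> ordered list of category labels

    def to_json(self, path=None):
        obj = {
            "numeric_names": list(self.numeric_names),
            "means": [float(m) for m in self.means],
            "sds": [float(s) for s in self.sds],
            "categorical_names": list(self.categorical_names),
            "levels": {k: list(v) for k, v in self.levels.items()},
        }
        if path is None:
            return json.dumps(obj, indent=2)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    @classmethod
    def from_json(cls, src):
        if isinstance(src, str) and src.lstrip().startswith("{"):
            obj = json.loads(src)
        else:
            with open(src) as fh:
                obj = json.load(fh)
        return cls(
            numeric_names=obj["numeric_names"],
            means=np.asarray(obj["means"], dtype=float),
            sds=np.asarray(obj["sds"], dtype=float),
            categorical_names=obj["categorical_names"],
            levels=obj["levels"],
        )


@dataclass
class FeatureMatrix:
    """Standardized numeric block + integer-coded categorical block."""

    numeric: np.ndarray  # n × p, z-scores
    categorical: np.ndarray  # n × q, dense codes 0..levels-1
    numeric_names: list
    categorical_names: list
    params: StandardizationParams
    row_ids: np.ndarray

    @property
    def n(self) -> int:
        return self.numeric.shape[0]


def _encode_categorical(col: pd.Series, levels: list) -> np.ndarray:
    codes = pd.Categorical(col, categories=levels).codes
    if (codes < 0).any():
        raise ValueError(
            f"column {col.name!r} contains categories outside fitted levels {levels}"
        )
    return codes.astype(np.int64)


def standardize_and_trim(
    cohort: pd.DataFrame,
    numeric_features=DEFAULT_NUMERIC_FEATURES,
    categorical_features=DEFAULT_CATEGORICAL_FEATURES,
    sd_threshold: float = 5.0,
    id_column="participant_id",
) -> FeatureMatrix:
    """Standardize numeric features (mean 0, SD 1) and drop extreme outliers.

    Standardization parameters are fitted once on all provided rows; rows
    with |z| ≥ ``sd_threshold`` in any numeric feature are then removed, and
    the original parameters are kept for transforming new data. Categorical
    features are encoded as dense integer codes over their sorted levels.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 rows to standardize")
    X = cohort[list(numeric_features)].to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        bad = [numeric_features[j] for j in zero]
        raise ValueError(f"zero-variance feature(s): {bad}")
    Z = (X - means) / sds
    keep = (np.abs(Z) < sd_threshold).all(axis=1)

    levels = {
        f: sorted(cohort[f].dropna().unique().tolist()) for f in categorical_features
    }
    params = StandardizationParams(
        numeric_names=list(numeric_features),
        means=means,
        sds=sds,
        categorical_names=list(categorical_features),
        levels=levels,
    )
    sub = cohort.loc[keep]
    cat = np.column_stack(
        [_encode_categorical(sub[f], levels[f]) for f in categorical_features]
    ) if categorical_features else np.empty((keep.sum(), 0), dtype=np.int64)
    ids = (
        sub[id_column].to_numpy()
        if id_column in cohort.columns
        else sub.index.to_numpy()
    )
    return FeatureMatrix(
        numeric=Z[keep],
        categorical=cat,
        numeric_names=list(numeric_features),
        categorical_names=list(categorical_features),
        params=params,
        row_ids=ids,
    )


def transform_new(
    params: StandardizationParams, new_rows: pd.DataFrame, id_column="participant_id"
) -> FeatureMatrix:
    """Apply frozen standardization/encoding to new rows (never re-fits)."""
    missing = [c for c in params.numeric_names + params.categorical_names
               if c not in new_rows.columns]
    if missing:
        raise ValueError(f"new rows lack fitted features: {missing}")
    X = new_rows[params.numeric_names].to_numpy(dtype=float)
    Z = (X - params.means) / params.sds
    cat = np.column_stack(
        [_encode_categorical(new_rows[f], params.levels[f])
         for f in params.categorical_names]
    ) if params.categorical_names else np.empty((len(new_rows), 0), dtype=np.int64)
    ids = (
        new_rows[id_column].to_numpy()
        if id_column in new_rows.columns
        else new_rows.index.to_numpy()
    )
    return FeatureMatrix(
        numeric=Z,
        categorical=cat,
        numeric_names=list(params.numeric_names),
        categorical_names=list(params.categorical_names),
        params=params,
        row_ids=ids,
    )


def inverse_transform(params: StandardizationParams, z_block: np.ndarray) -> np.ndarray:
    """Map z-scores back to the original scale."""
    return np.asarray(z_block, dtype=float) * params.sds + params.means
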