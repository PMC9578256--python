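"""Synthetic cohort generator for diabetes risk-phenotype analyses.

Emulates a prospective diabetes-free adult cohort with six planted risk
phenotypes — very low-risk (VLR), low-risk low beta-cell function (LRLB),
low-risk high beta-cell function (LRHB), high-risk high blood pressure
(HRHBP), high-risk beta-cell failure (HRBF) and high-risk insulin-resistant
(HRIR) — using published per-cluster means/SDs and category proportions for
the clustering variables, cluster-specific incident-diabetes hazards, and two
later follow-up visits with measurement drift.

Within-cluster features are drawn independently by default (only marginal
moments are published); an optional equicorrelation knob is provided for
robustness checks. HOMA indices are *not* drawn: they are derived from the
drawn glucose and insulin downstream, preserving the deterministic
dependency the real data have.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import gamma as _gamma_fn

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeSpec",
    "CohortConfig",
    "default_specs",
    "generate_baseline",
    "generate_survival",
    "generate_followups",
    "generate_cohort",
    "write_cohort",
    "CLUSTER_NUMERIC_FEATURES",
    "CLUSTER_CATEGORICAL_FEATURES",
    "PHENOTYPE_ORDER",
]

#: numeric features drawn by the generator that feed the cluster analysis
#: (HOMA-B / HOMA-IR are derived later from glucose and insulin)
CLUSTER_NUMERIC_FEATURES = ("fasting_glucose", "fasting_insulin", "bmi", "sbp", "dbp")
CLUSTER_CATEGORICAL_FEATURES = ("sex", "family_history", "education")
PHENOTYPE_ORDER = ("VLR", "LRLB", "LRHB", "HRHBP", "HRBF", "HRIR")

#: physiologic truncation floors (keeps HOMA computable and values plausible)
FLOORS = {
    "fasting_glucose": 3.6,   # mmol/L
    "fasting_insulin": 1.0,   # uU/mL
    "two_h_glucose": 2.0,     # mmol/L
    "bmi": 15.0,              # kg/m^2
    "sbp": 80.0,              # mmHg
    "dbp": 50.0,              # mmHg
}

#: covariate marginals, drawn independently of cluster (confounder slots)
COVARIATE_PARAMS = {
    "smoking": {"never": 0.45, "former": 0.30, "current": 0.25},
    "comorbidity": {"no": 0.80, "yes": 0.20},
    "physical_activity": {"lower": 0.25, "average": 0.50, "higher": 0.25},
    "general_health": {"good": 0.70, "fair": 0.25, "poor": 0.05},
}

# ---------------------------------------------------------------------------
# Published per-phenotype parameters.
# Numeric entries are (mean, SD) in natural units; categorical entries are
# member counts per category (normalised to probabilities at build time);
# incidence is events per 1000 person-years.


def _sdpp_cluster_params():
    # name: n, age, fpg, 2h glucose, insulin, bmi, sbp, dbp,
    #       women, family-history-yes, education (primary, secondary, university)
    return {
        "VLR": dict(n=1891, age=(46.10, 5.20), fpg=(4.52, 0.37), g2h=(4.24, 1.07),
                    ins=(9.41, 3.19), bmi=(22.97, 2.45), sbp=(107.78, 7.91),
                    dbp=(66.52, 5.16), women=1636, fh=1015, edu=(456, 634, 801),
                    rate=1.84),
        "LRLB": dict(n=1681, age=(48.17, 4.44), fpg=(4.58, 0.35), g2h=(4.54, 1.16),
                     ins=(9.22, 2.72), bmi=(24.53, 2.74), sbp=(126.09, 8.85),
                     dbp=(79.21, 5.26), women=1337, fh=964, edu=(516, 679, 486),
                     rate=3.57),
        "LRHB": dict(n=1237, age=(46.01, 5.04), fpg=(4.32, 0.38), g2h=(4.42, 1.25),
                     ins=(19.28, 3.92), bmi=(25.33, 2.83), sbp=(120.62, 10.27),
                     dbp=(77.47, 7.10), women=212, fh=664, edu=(336, 604, 297),
                     rate=4.61),
        "HRHBP": dict(n=731, age=(48.70, 4.09), fpg=(4.88, 0.50), g2h=(5.33, 1.51),
                      ins=(14.46, 4.60), bmi=(27.64, 3.95), sbp=(149.72, 13.22),
                      dbp=(92.59, 7.81), women=459, fh=465, edu=(298, 249, 184),
                      rate=11.81),
        "HRBF": dict(n=1229, age=(47.45, 4.91), fpg=(5.31, 0.42), g2h=(5.31, 1.50),
                     ins=(16.02, 4.06), bmi=(27.93, 3.73), sbp=(121.16, 10.13),
                     dbp=(75.94, 6.38), women=722, fh=814, edu=(439, 509, 281),
                     rate=15.87),
        "HRIR": dict(n=548, age=(46.76, 4.72), fpg=(5.01, 0.61), g2h=(5.74, 1.81),
                     ins=(31.82, 6.39), bmi=(29.99, 4.17), sbp=(133.40, 14.54),
                     dbp=(85.48, 8.72), women=76, fh=356, edu=(204, 245, 99),
                     rate=22.45),
    }


def _msc_cluster_params():
    # the Mexican validation cohort has no 2-h glucose (fasting-based OGTT only)
    return {
        "VLR": dict(n=559, age=(40.66, 7.16), fpg=(4.61, 0.40), g2h=None,
                    ins=(7.94, 2.96), bmi=(26.17, 2.91), sbp=(101.17, 8.16),
                    dbp=(66.01, 6.19), women=434, fh=440, edu=(188, 112, 259),
                    rate=6.43),
        "LRLB": dict(n=643, age=(43.34, 7.70), fpg=(4.83, 0.40), g2h=None,
                     ins=(7.66, 2.53), bmi=(27.36, 3.08), sbp=(118.56, 8.12),
                     dbp=(80.41, 5.04), women=411, fh=509, edu=(313, 129, 201),
                     rate=14.91),
        "LRHB": dict(n=374, age=(40.28, 7.10), fpg=(4.49, 0.39), g2h=None,
                     ins=(15.74, 4.04), bmi=(30.88, 4.22), sbp=(113.23, 9.38),
                     dbp=(76.74, 7.46), women=293, fh=287, edu=(187, 63, 124),
                     rate=11.22),
        "HRHBP": dict(n=254, age=(46.65, 7.69), fpg=(5.17, 0.51), g2h=None,
                      ins=(14.00, 4.73), bmi=(32.02, 4.62), sbp=(138.84, 13.81),
                      dbp=(91.44, 7.50), women=157, fh=207, edu=(121, 42, 91),
                      rate=45.10),
        "HRBF": dict(n=360, age=(44.24, 7.93), fpg=(5.60, 0.39), g2h=None,
                     ins=(14.19, 4.18), bmi=(31.10, 4.33), sbp=(111.33, 9.60),
                     dbp=(74.11, 7.59), women=261, fh=295, edu=(197, 50, 113),
                     rate=47.45),
        "HRIR": dict(n=142, age=(41.68, 7.44), fpg=(5.25, 0.58), g2h=None,
                     ins=(31.05, 6.31), bmi=(34.39, 5.37), sbp=(119.63, 15.07),
                     dbp=(78.98, 11.68), women=107, fh=118, edu=(71, 23, 48),
                     rate=55.38),
    }


_COHORT_TABLES = {"sdpp": _sdpp_cluster_params, "msc": _msc_cluster_params}

#: fraction of the cross-sectional SD used as default between-visit drift
DEFAULT_DRIFT_FRACTION = 0.6


@dataclass
class PhenotypeSpec:
    """Generative parameters for one synthetic risk phenotype."""

    name: str
    weight: float
    numeric_params: dict  # feature -> (mean, SD), natural units
    categorical_params: dict  # feature -> {category: probability}
    hazard_rate: float  # incident events per person-year
    drift_sd: dict = field(default_factory=dict)  # feature -> visit-drift SD

    def validate(self) -> None:
        if self.hazard_rate <= 0:
            raise ValueError(f"hazard_rate must be > 0, got {self.hazard_rate}")
        for feat, (mu, sd) in self.numeric_params.items():
            if sd <= 0:
                raise ValueError(f"SD of {feat} must be > 0")
        for feat, probs in self.categorical_params.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"category probabilities of {feat} sum to {total}, not 1"
                )


def validate_specs(specs: list[PhenotypeSpec]) -> None:
    """Check a spec set: individual validity plus unit mixing weights."""
    if not specs:
        raise ValueError("empty spec set")
    for s in specs:
        s.validate()
    total = sum(s.weight for s in specs)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixing weights sum to {total}, not 1")


@dataclass
class CohortConfig:
    """Study-design knobs for one synthetic cohort."""

    n_participants: int = 7317
    seed: int = 0
    baseline_age_range: tuple = (30.0, 60.0)
    followup_times: tuple = (10.0, 20.0)
    censor_time: float = 23.0
    birth_year_range: tuple = (1938, 1961)
    baseline_year_range: tuple = (1992, 1998)
    weibull_shape: float = 1.0  # 1 = constant hazard (exponential)
    numeric_correlation: float = 0.0  # within-cluster equicorrelation

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        ft = list(self.followup_times)
        if any(b <= a for a, b in zip(ft, ft[1:])):
            raise ValueError("followup_times must be strictly increasing")
        if self.censor_time < 0:
            raise ValueError("censor_time must be >= 0")
        if not (0 <= self.numeric_correlation < 1):
            raise ValueError("numeric_correlation must be in [0, 1)")


def default_specs(cohort: str = "sdpp") -> list[PhenotypeSpec]:
    """Build the six published phenotype specs for the ``sdpp`` (Swedish,
    main) or ``msc`` (Mexican, validation) cohort.

    Mixing weights are cluster sizes over the cohort total; hazard rates are
    the published per-1000-person-year incidence rates converted to per
    person-year.
    """
    key = cohort.lower().replace("-like", "")
    if key not in _COHORT_TABLES:
        raise ValueError(f"unknown cohort label {cohort!r}; use 'sdpp' or 'msc'")
    table = _COHORT_TABLES[key]()
    total = sum(p["n"] for p in table.values())
    specs = []
    for name in PHENOTYPE_ORDER:
        p = table[name]
        numeric = {
            "baseline_age": p["age"],
            "fasting_glucose": p["fpg"],
            "fasting_insulin": p["ins"],
            "bmi": p["bmi"],
            "sbp": p["sbp"],
            "dbp": p["dbp"],
        }
        if p["g2h"] is not None:
            numeric["two_h_glucose"] = p["g2h"]
        n = p["n"]
        cats = {
            "sex": {"female": p["women"] / n, "male": (n - p["women"]) / n},
            "family_history": {"no": (n - p["fh"]) / n, "yes": p["fh"] / n},
            "education": {
                "primary": p["edu"][0] / n,
                "secondary": p["edu"][1] / n,
                "university": p["edu"][2] / n,
            },
        }
        drift = {
            feat: DEFAULT_DRIFT_FRACTION * sd
            for feat, (mu, sd) in numeric.items()
            if feat != "baseline_age"
        }
        specs.append(
            PhenotypeSpec(
                name=name,
                weight=n / total,
                numeric_params=numeric,
                categorical_params=cats,
                hazard_rate=p["rate"] / 1000.0,
                drift_sd=drift,
            )
        )
    validate_specs(specs)
    return specs


# ---------------------------------------------------------------------------
# sampling


def _empty_cohort(specs: list[PhenotypeSpec]) -> pd.DataFrame:
    numeric = sorted({f for s in specs for f in s.numeric_params})
    cols = (
        ["participant_id", "true_cluster", "baseline_age", "birth_year"]
        + [f for f in numeric if f != "baseline_age"]
        + list(CLUSTER_CATEGORICAL_FEATURES)
        + list(COVARIATE_PARAMS)
    )
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def _draw_numeric(rng, spec, features, n, correlation):
    """Independent (or equicorrelated) Gaussian draws, floor-truncated."""
    p = len(features)
    z = rng.standard_normal((n, p))
    if correlation > 0 and p > 1:
        # equicorrelated latent: shared factor + idiosyncratic noise
        shared = rng.standard_normal((n, 1))
        z = np.sqrt(correlation) * shared + np.sqrt(1 - correlation) * z
    out = {}
    for j, feat in enumerate(features):
        mu, sd = spec.numeric_params[feat]
        vals = mu + sd * z[:, j]
        floor = FLOORS.get(feat)
        if floor is not None:
            vals = np.maximum(vals, floor)
        out[feat] = vals
    return out


def generate_baseline(
    specs: list[PhenotypeSpec], config: CohortConfig
) -> pd.DataFrame:
    """Draw a baseline cohort table: one row per participant with a planted
    phenotype label, clustering features in natural units, and covariates."""
    validate_specs(specs)
    config.validate()
    if config.n_participants == 0:
        return _empty_cohort(specs)

    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    weights = np.array([s.weight for s in specs])
    assign = rng.choice(len(specs), size=n, p=weights)

    numeric_feats = sorted({f for s in specs for f in s.numeric_params})
    frames = []
    for ci, spec in enumerate(specs):
        idx = np.flatnonzero(assign == ci)
        if idx.size == 0:
            continue
        m = idx.size
        draw_feats = [f for f in numeric_feats if f in spec.numeric_params]
        cols = _draw_numeric(rng, spec, draw_feats, m, config.numeric_correlation)
        lo, hi = config.baseline_age_range
        cols["baseline_age"] = np.clip(cols["baseline_age"], lo, hi)
        for feat in numeric_feats:
            if feat not in cols:
                cols[feat] = np.full(m, np.nan)
        for feat, probs in spec.categorical_params.items():
            levels = list(probs)
            cols[feat] = rng.choice(levels, size=m, p=[probs[l] for l in levels])
        df = pd.DataFrame(cols, index=idx)
        df["true_cluster"] = spec.name
        frames.append(df)

    cohort = pd.concat(frames).sort_index()
    cohort["participant_id"] = np.arange(n)

    for feat, probs in COVARIATE_PARAMS.items():
        levels = list(probs)
        cohort[feat] = rng.choice(levels, size=n, p=[probs[l] for l in levels])

    y0, y1 = config.baseline_year_range
    baseline_year = rng.integers(y0, y1 + 1, size=n)
    birth_year = baseline_year - np.round(cohort["baseline_age"]).astype(int)
    cohort["birth_year"] = np.clip(birth_year, *config.birth_year_range)

    front = ["participant_id", "true_cluster", "baseline_age", "birth_year"]
    other = [c for c in cohort.columns if c not in front]
    return cohort[front + other].reset_index(drop=True)


def generate_survival(
    cohort: pd.DataFrame, specs: list[PhenotypeSpec], config: CohortConfig
) -> pd.DataFrame:
    """Add ``event``, ``event_time`` and ``exit_age``.

    Event times are exponential with the phenotype's hazard (Weibull when
    ``config.weibull_shape`` != 1, scaled to the same mean), administratively
    censored at ``config.censor_time`` years after baseline.
    """
    if "true_cluster" not in cohort.columns:
        raise ValueError("cohort lacks true_cluster; generate baseline first")
    validate_specs(specs)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    out = cohort.copy()
    n = len(out)
    t = np.empty(n)
    by_name = {s.name: s for s in specs}
    for name, group in out.groupby("true_cluster"):
        spec = by_name[name]
        lam = spec.hazard_rate
        shape = config.weibull_shape
        e = rng.exponential(size=len(group))
        if shape == 1.0:
            times = e / lam
        else:
            # Weibull with the same mean event time as Exponential(lam)
            scale = 1.0 / (lam * _gamma_fn(1.0 + 1.0 / shape))
            times = scale * e ** (1.0 / shape)
        t[group.index.to_numpy()] = times
    event = t < config.censor_time
    out["event"] = event.astype(int)
    out["event_time"] = np.minimum(t, config.censor_time)
    out["exit_age"] = out["baseline_age"] + out["event_time"]
    return out


def generate_followups(
    cohort: pd.DataFrame, specs: list[PhenotypeSpec], config: CohortConfig
) -> pd.DataFrame:
    """Long-format visit table: baseline plus each follow-up time.

    At a follow-up visit, each numeric clustering feature is re-drawn as its
    baseline value plus Gaussian drift (per-feature SD from the spec),
    truncated at physiologic floors. A participant whose event precedes the
    visit carries the absorbing ``t2d`` state from then on; feature values
    are not re-drawn for them.
    """
    if "event_time" not in cohort.columns:
        raise ValueError("cohort lacks survival fields; run generate_survival first")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    by_name = {s.name: s for s in specs}
    drift_feats = sorted({f for s in specs for f in s.drift_sd})

    base = cohort.copy()
    base["visit_time"] = 0.0
    base["t2d"] = False
    rows = [base]
    for vt in config.followup_times:
        if vt > config.censor_time:
            continue
        visit = cohort.copy()
        visit["visit_time"] = float(vt)
        had_event = (cohort["event"] == 1) & (cohort["event_time"] <= vt)
        visit["t2d"] = had_event.to_numpy()
        for name, group in cohort.groupby("true_cluster"):
            spec = by_name[name]
            gi = group.index.to_numpy()
            for feat in drift_feats:
                sd = spec.drift_sd.get(feat, 0.0)
                vals = group[feat].to_numpy(dtype=float)
                if sd > 0:
                    vals = vals + rng.normal(0.0, sd, size=len(gi))
                floor = FLOORS.get(feat)
                if floor is not None:
                    vals = np.maximum(vals, floor)
                visit.loc[gi, feat] = vals
        visit.loc[had_event, drift_feats] = np.nan
        rows.append(visit)
    panel = pd.concat(rows, ignore_index=True)
    return panel.sort_values(["participant_id", "visit_time"]).reset_index(drop=True)


def generate_cohort(
    cohort: str = "sdpp",
    config: CohortConfig | None = None,
    specs: list[PhenotypeSpec] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: baseline + survival + follow-up panel.

    Returns ``(baseline_table, visit_panel)``.
    """
    if specs is None:
        specs = default_specs(cohort)
    if config is None:
        config = CohortConfig()
    base = generate_baseline(specs, config)
    base = generate_survival(base, specs, config)
    panel = generate_followups(base, specs, config)
    return base, panel


def write_cohort(
    cohort: pd.DataFrame,
    path: str,
    specs: list[PhenotypeSpec],
    config: CohortConfig,
) -> None:
    """Write the cohort as CSV plus a JSON sidecar with generator provenance."""
    cohort.to_csv(path, index=False)
    sidecar = {
        "config": asdict(config),
        "specs": [asdict(s) for s in specs],
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=list)
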