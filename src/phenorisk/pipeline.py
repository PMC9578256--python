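"""End-to-end orchestration of the phenotyping analysis.

Ties the stages together: cohort simulation (or CSV load) → variable
derivation and exclusions → feature standardization → cluster-number
selection → k-prototypes fit → bootstrap stability → phenotype naming →
person-time/rates/Cox → marker accuracy, transitions and agreement.
Every stage draws its seed deterministically from the global seed, and a
manifest (config hash, seeds, row counts) is written alongside the
artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as pp
from . import synthetic_cohort as sc
from .kprototypes import KPConfig, KPrototypesModel, fit_kprototypes, predict
from .validity import bootstrap_stability, gap_statistic, match_clusters
from .survival import fit_cox, person_time
from .evaluation import (
    T2D_STATE,
    cohens_kappa,
    compare_markers,
    gwets_ac1,
    transition_analysis,
)

__all__ = ["RunConfig", "run_full_analysis", "label_risk_groups",
            "assign_states", "name_clusters"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    cohort: str = "sdpp"  # synthetic cohort family, or ignored when csv given
    csv_path: str | None = None  # load a cohort instead of simulating
    n_participants: int = 5000
    seed: int = 0
    numeric_features: tuple = pp.DEFAULT_NUMERIC_FEATURES
    categorical_features: tuple = pp.DEFAULT_CATEGORICAL_FEATURES
    exclusion_rules: tuple = ("missing", "baseline_diabetes")
    homa_method: str = "homa1"
    k: int = 6  # used when run_gap is False
    run_gap: bool = False
    k_range: tuple = (2, 3, 4, 5, 6, 7, 8)
    n_refs: int = 10
    n_init: int = 10
    stability_B: int = 50
    covariates: tuple = ()
    reference_cluster: str = "LRHB"
    strata_width: int = 5
    outdir: str | None = None

    def stage_seed(self, stage: int) -> int:
        state = np.random.SeedSequence([int(self.seed), stage]).generate_state(1)
        return int(state[0] % (2**31 - 1))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def label_risk_groups(cluster_rates: dict, overall_rate: float) -> dict:
    """Flag each cluster high- or low-risk by comparing its incidence rate
    to the overall rate; exact ties are flagged."""
    out = {}
    for name, rate in cluster_rates.items():
        if rate > overall_rate:
            out[name] = "high"
        elif rate < overall_rate:
            out[name] = "low"
        else:
            out[name] = "tied"
    return out


def _reference_prototype_model(specs, params, gamma) -> KPrototypesModel:
    """Pseudo-model whose prototypes are the published per-phenotype means
    (HOMA derived from mean glucose/insulin), standardized with the fitted
    params — used only to attach names to fitted clusters."""
    num_rows, cat_rows = [], []
    for s in specs:
        vals = {}
        g, _ = s.numeric_params["fasting_glucose"]
        i, _ = s.numeric_params["fasting_insulin"]
        hb, hir = pp.compute_homa(g, i)
        derived = {"homa_b": hb, "homa_ir": hir}
        for feat in params.numeric_names:
            if feat in s.numeric_params:
                vals[feat] = s.numeric_params[feat][0]
            else:
                vals[feat] = derived[feat]
        num_rows.append([vals[f] for f in params.numeric_names])
        codes = []
        for feat in params.categorical_names:
            probs = s.categorical_params[feat]
            mode_label = max(sorted(probs), key=lambda lvl: probs[lvl])
            codes.append(params.levels[feat].index(mode_label))
        cat_rows.append(codes)
    z = (np.asarray(num_rows, dtype=float) - params.means) / params.sds
    return KPrototypesModel(
        k=len(specs), gamma=gamma,
        numeric_prototypes=z,
        categorical_prototypes=np.asarray(cat_rows, dtype=np.int64),
        labels=np.arange(len(specs)),
        cost=0.0, n_iter=0, converged=True,
        numeric_names=list(params.numeric_names),
        categorical_names=list(params.categorical_names),
    )


def name_clusters(model, specs, params) -> dict:
    """Map fitted cluster indices to phenotype names by nearest reference
    prototype (optimal one-to-one assignment on the standardized scale)."""
    ref = _reference_prototype_model(specs, params, model.gamma)
    mapping, _ = match_clusters(model, ref, mode="prototype")
    return {idx: specs[ref_idx].name for idx, ref_idx in mapping.items()}


def _derive_features(df: pd.DataFrame, method: str) -> pd.DataFrame:
    out = df.copy()
    hb, hir = pp.compute_homa(
        out["fasting_glucose"].to_numpy(), out["fasting_insulin"].to_numpy(),
        method=method,
        homa_b=out.get("homa_b"), homa_ir=out.get("homa_ir"),
    )
    out["homa_b"], out["homa_ir"] = hb, hir
    return out


def assign_states(
    panel: pd.DataFrame, model, params, names: dict, homa_method: str = "homa1"
) -> pd.DataFrame:
    """Per-visit phenotype states: diabetes is absorbing (``T2D``); all
    other rows are assigned to the nearest baseline prototype using the
    frozen standardization."""
    panel = panel.copy()
    states = np.empty(len(panel), dtype=object)
    t2d = panel["t2d"].to_numpy(dtype=bool)
    states[t2d] = T2D_STATE
    alive = ~t2d
    if alive.any():
        sub = _derive_features(panel.loc[alive], homa_method)
        fm = pp.transform_new(params, sub)
        labels = predict(model, fm)
        states[np.flatnonzero(alive)] = [names[l] for l in labels]
    panel["state"] = states
    return panel


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and return (and optionally write) the
    artifacts: cohort, exclusion log, gap curve, fitted model, stability,
    rates with risk groups, hazard ratios, marker accuracy, transitions and
    agreement, plus a manifest."""
    t0 = time.time()
    results: dict = {"timings": {}}

    # --- cohort -----------------------------------------------------------
    specs = sc.default_specs(config.cohort)
    if config.csv_path is not None:
        baseline = pd.read_csv(config.csv_path)
        panel = None
    else:
        cc = sc.CohortConfig(
            n_participants=config.n_participants, seed=config.stage_seed(0)
        )
        baseline, panel = sc.generate_cohort(config.cohort, cc, specs)
    results["timings"]["cohort"] = time.time() - t0

    # --- preprocess -------------------------------------------------------
    t = time.time()
    baseline = _derive_features(baseline, config.homa_method)
    analysis, exclusions = pp.apply_exclusions(
        baseline,
        rules=config.exclusion_rules,
        clustering_features=tuple(config.numeric_features)
        + tuple(config.categorical_features),
    )
    matrix = pp.standardize_and_trim(
        analysis, config.numeric_features, config.categorical_features
    )
    analysis = analysis[analysis["participant_id"].isin(matrix.row_ids)].reset_index(
        drop=True
    )
    results["exclusions"] = exclusions
    results["timings"]["preprocess"] = time.time() - t

    # --- cluster number ---------------------------------------------------
    t = time.time()
    kp = KPConfig(k=config.k, n_init=config.n_init, seed=config.stage_seed(1))
    if config.run_gap:
        gap = gap_statistic(
            matrix, config.k_range, kp, n_refs=config.n_refs,
            seed=config.stage_seed(2),
        )
        results["gap"] = gap
        kp = KPConfig(k=gap.chosen_k, n_init=config.n_init,
                      seed=config.stage_seed(1))
    results["timings"]["gap"] = time.time() - t

    # --- fit + stability --------------------------------------------------
    t = time.time()
    model = fit_kprototypes(matrix, kp)
    results["model"] = model
    stability = bootstrap_stability(
        matrix, kp, B=config.stability_B, seed=config.stage_seed(3),
        reference_model=model,
    )
    results["stability"] = stability
    results["timings"]["cluster"] = time.time() - t

    # --- phenotype naming -------------------------------------------------
    if model.k == len(specs):
        names = name_clusters(model, specs, matrix.params)
    else:  # non-standard k: no reference phenotypes to match against
        names = {i: f"C{i}" for i in range(model.k)}
    results["cluster_names"] = names
    analysis = analysis.assign(
        cluster=[names[l] for l in model.labels]
    )
    results["analysis_table"] = analysis

    # --- survival ---------------------------------------------------------
    t = time.time()
    rates = person_time(analysis, group_by="cluster")
    overall = person_time(analysis).iloc[0]
    risk_groups = label_risk_groups(
        dict(zip(rates["group"], rates["rate"])), overall["rate"]
    )
    rates["risk_group"] = rates["group"].map(risk_groups)
    results["rates"] = rates
    results["overall_rate"] = float(overall["rate"])
    results["risk_groups"] = risk_groups
    reference = config.reference_cluster
    if reference not in set(names.values()):
        # fall back to the largest cluster when the named reference is absent
        reference = analysis["cluster"].value_counts().idxmax()
    cox = fit_cox(
        analysis, exposure="cluster", reference=reference,
        covariates=(), strata_width=config.strata_width,
    )
    results["cox_crude"] = cox
    if config.covariates:
        results["cox_adjusted"] = fit_cox(
            analysis, exposure="cluster", reference=reference,
            covariates=config.covariates, strata_width=config.strata_width,
        )
    results["timings"]["survival"] = time.time() - t

    # --- evaluation -------------------------------------------------------
    t = time.time()
    high = {c for c, g in risk_groups.items() if g == "high"}
    two_h = (
        analysis["two_h_glucose"].to_numpy()
        if "two_h_glucose" in analysis and analysis["two_h_glucose"].notna().any()
        else None
    )
    fpg = analysis["fasting_glucose"].to_numpy()
    markers = {
        "high_risk_clusters": analysis["cluster"].isin(high).to_numpy(),
        "ADA_prediabetes": pp.classify_prediabetes(fpg, two_h, "ADA") != "normal",
        "WHO_prediabetes": pp.classify_prediabetes(fpg, two_h, "WHO") != "normal",
    }
    outcome = analysis["event"].to_numpy(dtype=bool)
    results["accuracy"] = compare_markers(markers, outcome)

    if panel is not None:
        panel = panel[panel["participant_id"].isin(analysis["participant_id"])]
        panel = assign_states(panel, model, matrix.params, names,
                              config.homa_method)
        results["panel"] = panel
        results["transitions"] = transition_analysis(panel, high_risk_states=high)
        results["agreement"] = _pairwise_agreement(panel)
    results["timings"]["evaluation"] = time.time() - t
    results["timings"]["total"] = time.time() - t0

    if config.outdir is not None:
        _write_artifacts(config, specs, matrix, results)
    return results


def _pairwise_agreement(panel: pd.DataFrame) -> pd.DataFrame:
    """Cluster-assignment agreement between each pair of visits, among
    participants free of diabetes at both visits in the pair."""
    wide = panel.pivot_table(
        index="participant_id", columns="visit_time", values="state",
        aggfunc="first",
    ).dropna()
    times = list(wide.columns)
    recs = []
    for i in range(len(times)):
        for j in range(i + 1, len(times)):
            a, b = wide[times[i]], wide[times[j]]
            keep = (a != T2D_STATE) & (b != T2D_STATE)
            kap = cohens_kappa(a[keep], b[keep])
            ac1 = gwets_ac1(a[keep], b[keep])
            recs.append(
                dict(
                    visit_a=times[i], visit_b=times[j], n=int(keep.sum()),
                    p_observed=kap.p_observed, kappa=kap.value, ac1=ac1.value,
                )
            )
    return pd.DataFrame(recs)


def _write_artifacts(config, specs, matrix, results) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results["analysis_table"].to_csv(outdir / "cohort.csv", index=False)
    results["rates"].to_csv(outdir / "rates.csv", index=False)
    results["cox_crude"].to_frame().to_csv(outdir / "hazard_ratios.csv", index=False)
    results["accuracy"].to_csv(outdir / "accuracy.csv", index=False)
    results["stability"].to_frame().to_csv(outdir / "stability.csv", index=False)
    if "gap" in results:
        results["gap"].to_frame().to_csv(outdir / "gap.csv", index=False)
    if "transitions" in results:
        results["transitions"].summary.to_csv(outdir / "transitions.csv", index=False)
        results["agreement"].to_csv(outdir / "agreement.csv", index=False)
    matrix.params.to_json(outdir / "standardization.json")
    results["model"].to_json(outdir / "model.json", params=matrix.params)
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stage_seeds": {s: config.stage_seed(s) for s in range(4)},
        "n_analysis_rows": int(len(results["analysis_table"])),
        "cluster_names": {int(k): v for k, v in results["cluster_names"].items()},
        "risk_groups": results["risk_groups"],
        "overall_rate_per_1000": results["overall_rate"],
        "timings_s": {k: round(v, 3) for k, v in results["timings"].items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
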