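"""Clinical-utility evaluation of risk markers.

Compares dichotomous risk markers (high-risk cluster membership, ADA/WHO
prediabetes) for predicting incident type 2 diabetes: 2×2 accuracy with
sensitivity/specificity (Wilson CIs) and the two-point AUC
(sens + spec)/2 with a Hanley–McNeil CI; long-term state-transition tables
with an absorbing diabetes state; and chance-corrected agreement between
repeat classifications (Cohen's kappa and Gwet's AC1 — AC1's chance model
is robust to skewed marginals, where kappa is notoriously paradoxical).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "AccuracyResult",
    "AgreementResult",
    "TransitionTable",
    "binary_accuracy",
    "cohens_kappa",
    "gwets_ac1",
    "transition_analysis",
    "compare_markers",
]

Z95 = 1.959963984540054
T2D_STATE = "T2D"


@dataclass
class AccuracyResult:
    """2×2 predictive accuracy of a dichotomous marker."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    sensitivity_ci: tuple
    specificity: float
    specificity_ci: tuple
    auc: float
    auc_ci: tuple
    marker: str = ""

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "sensitivity": self.sensitivity,
            "sens_lcl": self.sensitivity_ci[0], "sens_ucl": self.sensitivity_ci[1],
            "specificity": self.specificity,
            "spec_lcl": self.specificity_ci[0], "spec_ucl": self.specificity_ci[1],
            "auc": self.auc, "auc_lcl": self.auc_ci[0], "auc_ucl": self.auc_ci[1],
        }


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def binary_accuracy(marker, outcome, label: str = "") -> AccuracyResult:
    """Sensitivity, specificity and two-point AUC of a boolean marker
    against a boolean outcome. For a dichotomous marker the ROC has a
    single interior point, so AUC = (sens + spec)/2 exactly."""
    m = np.asarray(marker, dtype=bool)
    y = np.asarray(outcome, dtype=bool)
    if m.shape != y.shape:
        raise ValueError("marker and outcome lengths differ")
    tp = int((m & y).sum())
    fp = int((m & ~y).sum())
    fn = int((~m & y).sum())
    tn = int((~m & ~y).sum())
    return accuracy_from_counts(tp=tp, fp=fp, fn=fn, tn=tn, label=label)


def accuracy_from_counts(tp: int, fp: int, fn: int, tn: int,
                         label: str = "") -> AccuracyResult:
    """Accuracy metrics from a 2×2 table (marker rows × outcome columns)."""
    n_pos, n_neg = tp + fn, fp + tn
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one case and one non-case")
    sens = tp / n_pos
    spec = tn / n_neg
    sens_ci = proportion_confint(tp, n_pos, alpha=0.05, method="wilson")
    spec_ci = proportion_confint(tn, n_neg, alpha=0.05, method="wilson")
    auc = (sens + spec) / 2.0
    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    auc_ci = (max(0.0, auc - Z95 * se), min(1.0, auc + Z95 * se))
    return AccuracyResult(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=sens, sensitivity_ci=tuple(map(float, sens_ci)),
        specificity=spec, specificity_ci=tuple(map(float, spec_ci)),
        auc=auc, auc_ci=auc_ci, marker=label,
    )


@dataclass
class AgreementResult:
    """Chance-corrected agreement between two classifications."""

    p_observed: float
    p_chance: float
    value: float
    statistic: str  # "kappa" or "ac1"
    n_categories: int


def _agreement_table(a, b):
    a = pd.Series(a).astype(str)
    b = pd.Series(b).astype(str)
    if len(a) != len(b):
        raise ValueError("rating vectors differ in length")
    cats = sorted(set(a.unique()) | set(b.unique()))
    if len(cats) < 2:
        raise ValueError("need >= 2 categories across the two raters")
    table = pd.crosstab(
        pd.Categorical(a, categories=cats), pd.Categorical(b, categories=cats),
        dropna=False,
    ).to_numpy()
    return table, cats


def cohens_kappa(ratings_a, ratings_b) -> AgreementResult:
    """Cohen's kappa: (p_o − p_e)/(1 − p_e) with p_e the sum of products of
    the two raters' marginal proportions."""
    table, cats = _agreement_table(ratings_a, ratings_b)
    n = table.sum()
    p_o = np.trace(table) / n
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    p_e = float((row * col).sum())
    if abs(1.0 - p_e) < 1e-12:
        raise ValueError("chance agreement is 1 (single category): kappa undefined")
    return AgreementResult(
        p_observed=float(p_o), p_chance=p_e,
        value=float((p_o - p_e) / (1.0 - p_e)),
        statistic="kappa", n_categories=len(cats),
    )


def gwets_ac1(ratings_a, ratings_b) -> AgreementResult:
    """Gwet's AC1: chance agreement (1/(q−1)) Σ_k π_k(1−π_k) with π_k the
    mean of the two raters' marginal proportions for category k."""
    table, cats = _agreement_table(ratings_a, ratings_b)
    q = len(cats)
    n = table.sum()
    p_o = np.trace(table) / n
    pi = (table.sum(axis=1) + table.sum(axis=0)) / (2.0 * n)
    p_e = float((pi * (1 - pi)).sum() / (q - 1))
    if abs(1.0 - p_e) < 1e-12:
        raise ValueError("chance agreement is 1: AC1 undefined")
    return AgreementResult(
        p_observed=float(p_o), p_chance=p_e,
        value=float((p_o - p_e) / (1.0 - p_e)),
        statistic="ac1", n_categories=q,
    )


@dataclass
class TransitionTable:
    """Between-visit state transitions with an absorbing diabetes state."""

    pair_counts: dict  # (t_from, t_to) -> DataFrame of counts
    pair_proportions: dict  # (t_from, t_to) -> row-normalized DataFrame
    summary: pd.DataFrame  # remained/regressed/progressed vs baseline group
    states: list
    complete_case: bool = True


def _check_absorbing(wide: pd.DataFrame) -> None:
    arr = wide.to_numpy()
    for row in arr:
        seen = False
        for s in row:
            if s == T2D_STATE:
                seen = True
            elif seen:
                raise ValueError("non-absorbing T2D sequence detected")


def transition_analysis(
    panel: pd.DataFrame,
    high_risk_states=(),
    state_col: str = "state",
    time_col: str = "visit_time",
    id_col: str = "participant_id",
) -> TransitionTable:
    """Transition counts/proportions between consecutive visits, and a
    baseline-anchored summary of who remained / regressed / progressed.

    ``panel`` is long format (participant, visit time, state); only
    participants observed at every visit are used (complete case). States
    in ``high_risk_states`` form the "high-risk" group for the summary;
    ``T2D`` is absorbing and validated as such.
    """
    times = sorted(panel[time_col].unique())
    if len(times) < 2:
        raise ValueError("need at least two visits")
    wide = panel.pivot_table(
        index=id_col, columns=time_col, values=state_col, aggfunc="first"
    )[times].dropna()
    _check_absorbing(wide)
    states = sorted(set(panel[state_col].unique()) - {T2D_STATE}) + [T2D_STATE]

    pair_counts, pair_props = {}, {}
    for t0, t1 in zip(times, times[1:]):
        ct = pd.crosstab(
            pd.Categorical(wide[t0], categories=states),
            pd.Categorical(wide[t1], categories=states),
            dropna=False,
        )
        ct.index.name, ct.columns.name = "from", "to"
        pair_counts[(t0, t1)] = ct
        with np.errstate(invalid="ignore"):
            pair_props[(t0, t1)] = ct.div(ct.sum(axis=1), axis=0).fillna(0.0)

    high = set(high_risk_states)
    base, final = wide[times[0]], wide[times[-1]]
    recs = []
    for group_name, members in (
        ("high_risk", base.isin(high)),
        ("low_risk", ~base.isin(high) & (base != T2D_STATE)),
    ):
        sub_final = final[members]
        n = int(members.sum())
        progressed = int((sub_final == T2D_STATE).sum())
        stayed_high = int(sub_final.isin(high).sum())
        stayed_low = int((~sub_final.isin(high) & (sub_final != T2D_STATE)).sum())
        remained = stayed_high if group_name == "high_risk" else stayed_low
        moved = stayed_low if group_name == "high_risk" else stayed_high
        recs.append(
            dict(
                baseline_group=group_name, n=n, remained=remained,
                crossed=moved, progressed=progressed,
                remained_pct=100.0 * remained / n if n else np.nan,
                crossed_pct=100.0 * moved / n if n else np.nan,
                progressed_pct=100.0 * progressed / n if n else np.nan,
            )
        )
    return TransitionTable(
        pair_counts=pair_counts,
        pair_proportions=pair_props,
        summary=pd.DataFrame(recs),
        states=states,
    )


def compare_markers(markers: dict, outcome) -> pd.DataFrame:
    """Side-by-side accuracy of several dichotomous markers against one
    outcome; returns one tidy row per marker."""
    rows = [
        binary_accuracy(mvals, outcome, label=name).to_dict()
        for name, mvals in markers.items()
    ]
    return pd.DataFrame(rows)
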