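"""Cluster-number selection and stability assessment.

Implements the gap statistic adapted to mixed data (reference datasets draw
numeric features uniformly over each observed column range and categorical
features from the observed marginal frequencies), clusterwise bootstrap
stability via the Jaccard similarity index, and optimal one-to-one cluster
matching between two fitted models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .preprocess import FeatureMatrix
from .kprototypes import KPConfig, KPrototypesModel, fit_kprototypes

__all__ = [
    "GapResult",
    "StabilityResult",
    "gap_statistic",
    "jaccard",
    "bootstrap_stability",
    "match_clusters",
]

#: bootstrap mean Jaccard above which a cluster is called stable
STABILITY_THRESHOLD = 0.75


@dataclass
class GapResult:
    """Gap-statistic curve over a range of cluster counts."""

    k_range: list
    log_w: np.ndarray  # log observed total within-cluster dissimilarity
    log_w_ref: np.ndarray  # mean log reference dissimilarity per k
    gap: np.ndarray
    s_k: np.ndarray  # reference SD × sqrt(1 + 1/B)
    chosen_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_range,
                "log_w": self.log_w,
                "log_w_ref": self.log_w_ref,
                "gap": self.gap,
                "s_k": self.s_k,
            }
        )


@dataclass
class StabilityResult:
    """Per-cluster mean bootstrap Jaccard similarity."""

    mean_jaccard: np.ndarray  # per reference cluster
    B: int
    threshold: float = STABILITY_THRESHOLD
    per_replicate: np.ndarray | None = None  # B × k, for diagnostics

    @property
    def stable(self) -> np.ndarray:
        return self.mean_jaccard > self.threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": np.arange(len(self.mean_jaccard)),
                "mean_jaccard": self.mean_jaccard,
                "stable": self.stable,
            }
        )


def _reference_sample(matrix: FeatureMatrix, rng) -> FeatureMatrix:
    """Null dataset: numeric uniform over each observed column range,
    categorical multinomial with the observed marginal proportions."""
    Xn, Xc = matrix.numeric, matrix.categorical
    n, p = Xn.shape
    lo, hi = Xn.min(axis=0), Xn.max(axis=0)
    if np.any(hi - lo == 0):
        raise ValueError("degenerate (constant) numeric feature in gap reference")
    ref_num = rng.uniform(lo, hi, size=(n, p))
    ref_cat = np.empty_like(Xc)
    for j in range(Xc.shape[1]):
        vals, counts = np.unique(Xc[:, j], return_counts=True)
        ref_cat[:, j] = rng.choice(vals, size=n, p=counts / counts.sum())
    return FeatureMatrix(
        numeric=ref_num,
        categorical=ref_cat,
        numeric_names=matrix.numeric_names,
        categorical_names=matrix.categorical_names,
        params=matrix.params,
        row_ids=matrix.row_ids,
    )


def gap_statistic(
    matrix: FeatureMatrix,
    k_range,
    config: KPConfig,
    n_refs: int = 50,
    seed: int = 0,
) -> GapResult:
    """Gap(k) = mean_b log W_b(k) − log W(k), with W the total k-prototypes
    cost; ``chosen_k`` is the smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1}
    (the largest k in range if none qualifies)."""
    k_range = sorted(k_range)
    if n_refs < 2:
        raise ValueError("n_refs must be >= 2")
    if k_range[0] < 1 or k_range[-1] >= matrix.n:
        raise ValueError("k_range must lie in [1, n)")

    ss = np.random.SeedSequence([int(seed), 7919])
    ref_rngs = [np.random.default_rng(c) for c in ss.spawn(n_refs)]
    refs = [_reference_sample(matrix, rng) for rng in ref_rngs]

    log_w = np.empty(len(k_range))
    log_w_ref = np.empty(len(k_range))
    s_k = np.empty(len(k_range))
    for i, k in enumerate(k_range):
        cfg = replace(config, k=k)
        log_w[i] = np.log(fit_kprototypes(matrix, cfg).cost)
        ref_logs = np.array(
            [np.log(fit_kprototypes(ref, cfg).cost) for ref in refs]
        )
        log_w_ref[i] = ref_logs.mean()
        s_k[i] = ref_logs.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_refs)
    gap = log_w_ref - log_w

    chosen = k_range[-1]
    for i in range(len(k_range) - 1):
        if gap[i] >= gap[i + 1] - s_k[i + 1]:
            chosen = k_range[i]
            break
    return GapResult(
        k_range=list(k_range), log_w=log_w, log_w_ref=log_w_ref, gap=gap,
        s_k=s_k, chosen_k=chosen,
    )


def jaccard(a, b) -> float:
    """|A∩B| / |A∪B|; two empty sets give 0 by convention."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def bootstrap_stability(
    matrix: FeatureMatrix,
    config: KPConfig,
    B: int = 1000,
    seed: int = 0,
    reference_model: KPrototypesModel | None = None,
) -> StabilityResult:
    """Clusterwise bootstrap stability (clusterboot-style).

    For each of ``B`` replicates, rows are resampled with replacement and
    the clusterer refit on the replicate. Each reference cluster's member
    set, restricted to the unique resampled row positions, is compared
    against every bootstrap cluster's member set (duplicates counted once)
    and the maximum Jaccard recorded. A cluster whose mean over replicates
    exceeds 0.75 is considered stable.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if reference_model is None:
        reference_model = fit_kprototypes(matrix, config)
    k = reference_model.k
    n = matrix.n
    ref_sets = [set(np.flatnonzero(reference_model.labels == c)) for c in range(k)]

    ss = np.random.SeedSequence([int(seed), 104729])
    per_rep = np.empty((B, k))
    for b, child in enumerate(ss.spawn(B)):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        boot = FeatureMatrix(
            numeric=matrix.numeric[idx],
            categorical=matrix.categorical[idx],
            numeric_names=matrix.numeric_names,
            categorical_names=matrix.categorical_names,
            params=matrix.params,
            row_ids=matrix.row_ids[idx],
        )
        cfg = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        model_b = fit_kprototypes(boot, cfg)
        unique_ids = set(idx.tolist())
        boot_sets = [
            set(idx[model_b.labels == c].tolist()) for c in range(model_b.k)
        ]
        for c in range(k):
            ref_c = ref_sets[c] & unique_ids
            per_rep[b, c] = max(jaccard(ref_c, bs) for bs in boot_sets)
    return StabilityResult(
        mean_jaccard=per_rep.mean(axis=0), B=B, per_replicate=per_rep
    )


def _prototype_distance_matrix(model_a, model_b):
    pa, pb = model_a.numeric_prototypes, model_b.numeric_prototypes
    d = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    if model_a.categorical_prototypes.shape[1]:
        d = d + model_a.gamma * (
            model_a.categorical_prototypes[:, None, :]
            != model_b.categorical_prototypes[None, :, :]
        ).sum(axis=2)
    return d


def match_clusters(
    model_a: KPrototypesModel,
    model_b: KPrototypesModel,
    mode: str = "overlap",
) -> tuple[dict, float]:
    """Optimal one-to-one cluster correspondence between two models.

    ``overlap`` maximizes total Jaccard overlap of member sets (models fit
    on the same rows); ``prototype`` minimizes summed prototype distance on
    the standardized scale (models from different cohorts). Returns
    ``(mapping a-cluster -> b-cluster, total score)``; the score is the
    summed Jaccard (overlap) or summed distance (prototype).
    """
    if model_a.k != model_b.k:
        raise ValueError("models have different k")
    k = model_a.k
    if mode == "overlap":
        sets_a = [set(np.flatnonzero(model_a.labels == c)) for c in range(k)]
        sets_b = [set(np.flatnonzero(model_b.labels == c)) for c in range(k)]
        score_mat = np.array(
            [[jaccard(sa, sb) for sb in sets_b] for sa in sets_a]
        )
        rows, cols = linear_sum_assignment(-score_mat)
    elif mode == "prototype":
        score_mat = _prototype_distance_matrix(model_a, model_b)
        rows, cols = linear_sum_assignment(score_mat)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mapping = {int(r): int(c) for r, c in zip(rows, cols)}
    total = float(score_mat[rows, cols].sum())
    return mapping, total
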