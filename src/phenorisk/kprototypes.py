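"""K-prototypes clustering of mixed continuous/categorical data.

Huang-style alternating optimization: the dissimilarity between a row and a
prototype is the squared Euclidean distance on the numeric block plus γ
times the number of categorical mismatches; prototypes are within-cluster
means (numeric) and modes (categorical). The best of ``n_init`` seeded
restarts by final cost is kept.

Determinism notes: prototype initialization draws distinct data rows from a
seeded generator; mode ties break toward the lowest category code; nearest-
prototype ties break toward the lowest cluster index; an emptied cluster is
reseeded from the row farthest from its assigned prototype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .preprocess import FeatureMatrix

__all__ = [
    "KPConfig",
    "KPrototypesModel",
    "kproto_distance",
    "pairwise_distances",
    "fit_kprototypes",
    "predict",
    "auto_gamma",
]


@dataclass
class KPConfig:
    """Fitting options for one k-prototypes run."""

    k: int = 6
    gamma: float | str = "auto"
    n_init: int = 20
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0
    init: str = "random-points"  # or "frequency-weighted"

    def validate(self, n_rows: int | None = None) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if n_rows is not None and self.k > n_rows:
            raise ValueError(f"k={self.k} exceeds n rows={n_rows}")
        if self.n_init < 1 or self.max_iter < 1:
            raise ValueError("n_init and max_iter must be >= 1")
        if self.gamma != "auto" and self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.init not in ("random-points", "frequency-weighted"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class KPrototypesModel:
    """A fitted mixed-data partition."""

    k: int
    gamma: float
    numeric_prototypes: np.ndarray  # k × p, standardized scale
    categorical_prototypes: np.ndarray  # k × q, category codes
    labels: np.ndarray
    cost: float
    n_iter: int
    converged: bool
    numeric_names: list = field(default_factory=list)
    categorical_names: list = field(default_factory=list)

    def to_json(self, path=None, params=None):
        """Serialize; when standardization params are given, prototypes are
        also reported on the original measurement scale."""
        obj = {
            "k": self.k,
            "gamma": self.gamma,
            "numeric_prototypes": self.numeric_prototypes.tolist(),
            "categorical_prototypes": self.categorical_prototypes.tolist(),
            "cost": self.cost,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "numeric_names": self.numeric_names,
            "categorical_names": self.categorical_names,
        }
        if params is not None:
            from .preprocess import inverse_transform

            obj["numeric_prototypes_original_scale"] = inverse_transform(
                params, self.numeric_prototypes
            ).tolist()
            obj["categorical_prototype_labels"] = [
                [params.levels[name][code]
                 for name, code in zip(params.categorical_names, row)]
                for row in self.categorical_prototypes
            ]
        if path is None:
            return json.dumps(obj, indent=2)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)


def kproto_distance(row_num, row_cat, proto_num, proto_cat, gamma: float) -> float:
    """Dissimilarity between one row and one prototype:
    Σ (numeric difference)² + γ · #{categorical mismatches}."""
    rn = np.asarray(row_num, dtype=float)
    pn = np.asarray(proto_num, dtype=float)
    rc = np.asarray(row_cat)
    pc = np.asarray(proto_cat)
    if rn.shape != pn.shape or rc.shape != pc.shape:
        raise ValueError("row/prototype dimension mismatch")
    return float(((rn - pn) ** 2).sum() + gamma * (rc != pc).sum())


def pairwise_distances(Xn, Xc, protos_num, protos_cat, gamma):
    """n × k matrix of k-prototypes dissimilarities."""
    # squared Euclidean via the expansion trick, clipped for fp safety
    sq = (
        (Xn**2).sum(axis=1)[:, None]
        - 2.0 * Xn @ protos_num.T
        + (protos_num**2).sum(axis=1)[None, :]
    )
    np.maximum(sq, 0.0, out=sq)
    if Xc.shape[1]:
        mismatch = (Xc[:, None, :] != protos_cat[None, :, :]).sum(axis=2)
        sq += gamma * mismatch
    return sq


def auto_gamma(matrix: FeatureMatrix) -> float:
    """Huang's heuristic: half the mean per-feature SD of the numeric block
    (0.5 on standardized data)."""
    if matrix.numeric.shape[1] == 0:
        raise ValueError("auto gamma needs at least one numeric feature")
    return 0.5 * float(matrix.numeric.std(axis=0, ddof=0).mean())


def _resolve_gamma(matrix: FeatureMatrix, config: KPConfig) -> float:
    return auto_gamma(matrix) if config.gamma == "auto" else float(config.gamma)


def _mode_rows(Xc, labels, k, q, old_protos):
    """Per-cluster modes; ties break to the lowest code (bincount argmax)."""
    out = old_protos.copy()
    for c in range(k):
        members = Xc[labels == c]
        if members.shape[0] == 0:
            continue
        for j in range(q):
            out[c, j] = np.bincount(members[:, j]).argmax()
    return out


def _init_prototypes(Xn, Xc, k, rng, init):
    n, q = Xn.shape[0], Xc.shape[1]
    idx = rng.choice(n, size=k, replace=False)
    protos_num = Xn[idx].copy()
    if init == "frequency-weighted" and q:
        protos_cat = np.empty((k, q), dtype=Xc.dtype)
        for j in range(q):
            vals, counts = np.unique(Xc[:, j], return_counts=True)
            protos_cat[:, j] = rng.choice(vals, size=k, p=counts / counts.sum())
    else:
        protos_cat = Xc[idx].copy()
    return protos_num, protos_cat


def _single_fit(Xn, Xc, k, gamma, max_iter, tol, rng, init):
    n, q = Xn.shape[0], Xc.shape[1]
    protos_num, protos_cat = _init_prototypes(Xn, Xc, k, rng, init)
    labels = np.full(n, -1)
    prev_cost = np.inf
    converged = False
    for it in range(1, max_iter + 1):
        d = pairwise_distances(Xn, Xc, protos_num, protos_cat, gamma)
        new_labels = d.argmin(axis=1)  # argmin ties -> lowest cluster index

        # reseed emptied clusters from the currently worst-fit row
        for c in range(k):
            if not (new_labels == c).any():
                worst = d[np.arange(n), new_labels].argmax()
                new_labels[worst] = c
                d[worst, :] = np.inf
                d[worst, c] = 0.0

        cost = float(d[np.arange(n), new_labels].sum())
        if cost > prev_cost + 1e-9:
            raise AssertionError("k-prototypes cost increased across iterations")
        labels_stable = (new_labels == labels).all()
        rel_change = (prev_cost - cost) / prev_cost if np.isfinite(prev_cost) and prev_cost > 0 else np.inf
        labels = new_labels
        prev_cost = cost
        if labels_stable or rel_change < tol:
            converged = True
            break
        # update step
        for c in range(k):
            protos_num[c] = Xn[labels == c].mean(axis=0)
        if q:
            protos_cat = _mode_rows(Xc, labels, k, q, protos_cat)
    # final cost against final prototypes
    d = pairwise_distances(Xn, Xc, protos_num, protos_cat, gamma)
    labels = d.argmin(axis=1)
    cost = float(d[np.arange(n), labels].sum())
    return protos_num, protos_cat, labels, cost, it, converged


def fit_kprototypes(matrix: FeatureMatrix, config: KPConfig) -> KPrototypesModel:
    """Fit k-prototypes by alternating optimization, best of ``n_init``
    seeded restarts by final cost."""
    Xn, Xc = matrix.numeric, matrix.categorical
    n = Xn.shape[0]
    config.validate(n_rows=n)
    gamma = _resolve_gamma(matrix, config)
    k = config.k

    best = None
    ss = np.random.SeedSequence([int(config.seed), k])
    for child in ss.spawn(config.n_init):
        rng = np.random.default_rng(child)
        result = _single_fit(Xn, Xc, k, gamma, config.max_iter, config.tol, rng,
                             config.init)
        if best is None or result[3] < best[3] - 1e-12:
            best = result
    protos_num, protos_cat, labels, cost, n_iter, converged = best
    model = KPrototypesModel(
        k=k,
        gamma=gamma,
        numeric_prototypes=protos_num,
        categorical_prototypes=protos_cat,
        labels=labels,
        cost=cost,
        n_iter=n_iter,
        converged=converged,
        numeric_names=list(matrix.numeric_names),
        categorical_names=list(matrix.categorical_names),
    )
    _check_cost(model, matrix)
    return model


def _check_cost(model: KPrototypesModel, matrix: FeatureMatrix) -> None:
    d = pairwise_distances(
        matrix.numeric, matrix.categorical,
        model.numeric_prototypes, model.categorical_prototypes, model.gamma
    )
    recomputed = float(d[np.arange(matrix.n), model.labels].sum())
    if abs(recomputed - model.cost) > 1e-6 * max(1.0, abs(model.cost)):
        raise AssertionError("model cost does not match recomputed dissimilarity")
    counts = np.bincount(model.labels, minlength=model.k)
    if (counts == 0).any():
        raise AssertionError("fitted model contains an empty cluster")


def predict(model: KPrototypesModel, matrix: FeatureMatrix) -> np.ndarray:
    """Nearest-prototype labels for new rows under the model's γ; ties break
    toward the lowest cluster index."""
    if list(matrix.numeric_names) != list(model.numeric_names) or list(
        matrix.categorical_names
    ) != list(model.categorical_names):
        raise ValueError("feature schema does not match the fitted model")
    d = pairwise_distances(
        matrix.numeric, matrix.categorical,
        model.numeric_prototypes, model.categorical_prototypes, model.gamma
    )
    return d.argmin(axis=1)
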