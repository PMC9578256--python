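import itertools

import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

import phenorisk as pr
from phenorisk.kprototypes import kproto_distance, pairwise_distances

from conftest import make_matrix, planted_mixed_data


class TestDistance:
    def test_identical_row_and_prototype(self):
        assert kproto_distance([1.0, 2.0], [0], [1.0, 2.0], [0], 0.7) == 0.0

    def test_formula(self):
        # numeric diff (1, 0), one categorical mismatch, gamma 0.5
        assert kproto_distance([1.0, 0.0], [1], [0.0, 0.0], [2], 0.5) == 1.5

    def test_gamma_zero_is_squared_euclidean(self):
        d = kproto_distance([1.0, 2.0], [1], [3.0, 0.0], [2], 0.0)
        assert d == pytest.approx(8.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            kproto_distance([1.0], [0], [1.0, 2.0], [0], 0.5)


class TestFit:
    def test_planted_partition_recovered_exactly(self):
        m, truth = planted_mixed_data(
            50, centers=[(-4.0, -4.0), (4.0, 4.0)], cat_codes=[0, 1], seed=3
        )
        model = pr.fit_kprototypes(m, pr.KPConfig(k=2, n_init=5, seed=0))
        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_k1_is_global_mean_and_mode(self):
        rng = np.random.default_rng(0)
        Xn = rng.normal(size=(40, 2))
        Xc = rng.integers(0, 3, size=(40, 1))
        m = make_matrix(Xn, Xc)
        model = pr.fit_kprototypes(m, pr.KPConfig(k=1, gamma=0.5, n_init=1, seed=0))
        assert (model.labels == 0).all()
        expected = ((Xn - Xn.mean(axis=0)) ** 2).sum() + 0.5 * (
            len(Xc) - np.bincount(Xc[:, 0]).max()
        )
        assert model.cost == pytest.approx(expected)

    def test_invalid_k_rejected(self):
        m, _ = planted_mixed_data(5, [(0.0,), (1.0,)], [0, 1])
        with pytest.raises(ValueError):
            pr.fit_kprototypes(m, pr.KPConfig(k=11))
        with pytest.raises(ValueError):
            pr.fit_kprototypes(m, pr.KPConfig(k=0))

    def test_determinism(self, small_matrix):
        m, _ = small_matrix
        cfg = pr.KPConfig(k=4, n_init=3, seed=7)
        a = pr.fit_kprototypes(m, cfg)
        b = pr.fit_kprototypes(m, cfg)
        assert (a.labels == b.labels).all()
        assert a.cost == b.cost

    def test_no_empty_clusters_and_recomputable_cost(self, small_matrix):
        m, _ = small_matrix
        model = pr.fit_kprototypes(m, pr.KPConfig(k=6, n_init=3, seed=1))
        counts = np.bincount(model.labels, minlength=6)
        assert (counts > 0).all()
        d = pairwise_distances(
            m.numeric, m.categorical, model.numeric_prototypes,
            model.categorical_prototypes, model.gamma,
        )
        assert d[np.arange(m.n), model.labels].sum() == pytest.approx(model.cost)

    def test_frequency_weighted_init_runs(self, small_matrix):
        m, _ = small_matrix
        model = pr.fit_kprototypes(
            m, pr.KPConfig(k=4, n_init=3, seed=2, init="frequency-weighted")
        )
        assert model.k == 4


def _brute_force_cost(Xn, Xc, k, gamma):
    """Exhaustive-enumeration optimum over all k-labelings (all clusters
    non-empty); prototypes are the within-cluster mean/mode."""
    n = Xn.shape[0]
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        labels = np.asarray(labels)
        if len(np.unique(labels)) < k:
            continue
        cost = 0.0
        for c in range(k):
            mask = labels == c
            sub = Xn[mask]
            cost += ((sub - sub.mean(axis=0)) ** 2).sum()
            for j in range(Xc.shape[1]):
                counts = np.bincount(Xc[mask][:, j])
                cost += gamma * (mask.sum() - counts.max())
        best = min(best, cost)
    return best


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(6, 10))
        k = int(rng.integers(2, 4))
        Xn = rng.normal(size=(n, int(rng.integers(1, 3))))
        Xc = rng.integers(0, 3, size=(n, int(rng.integers(1, 3))))
        gamma = 0.5
        bf = _brute_force_cost(Xn, Xc, k, gamma)
        m = make_matrix(Xn, Xc)
        model = pr.fit_kprototypes(
            m, pr.KPConfig(k=k, gamma=gamma, n_init=50, seed=trial)
        )
        assert model.cost == pytest.approx(bf, abs=1e-8)


class TestKMeansLimit:
    def test_no_categoricals_matches_lloyd(self):
        """With q=0 the objective is exactly k-means inertia."""
        rng = np.random.default_rng(4)
        Xn = np.vstack(
            [rng.normal(c, 0.4, size=(60, 3)) for c in (-3.0, 0.0, 3.0)]
        )
        m = make_matrix(Xn)
        model = pr.fit_kprototypes(m, pr.KPConfig(k=3, gamma=0.0, n_init=10, seed=0))
        km = KMeans(n_clusters=3, n_init=10, random_state=0).fit(Xn)
        assert model.cost == pytest.approx(km.inertia_, rel=1e-6)


class TestPredict:
    def test_training_rows_reproduce_labels(self, small_matrix):
        m, _ = small_matrix
        model = pr.fit_kprototypes(m, pr.KPConfig(k=5, n_init=3, seed=0))
        assert (pr.predict(model, m) == model.labels).all()

    def test_prototype_rows_map_to_their_cluster(self, small_matrix):
        m, _ = small_matrix
        model = pr.fit_kprototypes(m, pr.KPConfig(k=4, n_init=3, seed=0))
        proto_matrix = make_matrix(
            model.numeric_prototypes, model.categorical_prototypes
        )
        proto_matrix.numeric_names = m.numeric_names
        proto_matrix.categorical_names = m.categorical_names
        assert (pr.predict(model, proto_matrix) == np.arange(4)).all()

    def test_equidistant_tie_breaks_to_lowest_index(self):
        model = pr.KPrototypesModel(
            k=3, gamma=0.5,
            numeric_prototypes=np.array([[-1.0], [5.0], [1.0]]),
            categorical_prototypes=np.array([[0], [0], [0]]),
            labels=np.array([0, 1, 2]), cost=0.0, n_iter=1, converged=True,
            numeric_names=["x0"], categorical_names=["c0"],
        )
        probe = make_matrix(np.array([[0.0]]), np.array([[0]]))
        # equidistant between prototypes 0 and 2 -> lowest index wins
        assert pr.predict(model, probe)[0] == 0

    def test_schema_mismatch_rejected(self, small_matrix):
        m, _ = small_matrix
        model = pr.fit_kprototypes(m, pr.KPConfig(k=3, n_init=2, seed=0))
        other, _ = planted_mixed_data(5, [(0.0,), (1.0,)], [0, 1])
        with pytest.raises(ValueError, match="schema"):
            pr.predict(model, other)


class TestGamma:
    def test_standardized_matrix_gives_half(self):
        rng = np.random.default_rng(6)
        X = rng.normal(5.0, 2.0, size=(300, 4))
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        assert pr.auto_gamma(make_matrix(Z)) == pytest.approx(0.5, abs=1e-12)

    def test_scaling_linearity(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(100, 3)))
        g = pr.auto_gamma(m)
        m2 = make_matrix(2.0 * m.numeric)
        assert pr.auto_gamma(m2) == pytest.approx(2.0 * g)

    def test_all_categorical_rejected(self):
        m = make_matrix(np.empty((10, 0)), np.zeros((10, 1), dtype=int))
        with pytest.raises(ValueError):
            pr.auto_gamma(m)


def test_label_permutation_leaves_cost_unchanged(small_matrix):
    m, _ = small_matrix
    model = pr.fit_kprototypes(m, pr.KPConfig(k=4, n_init=2, seed=3))
    perm = np.array([2, 0, 3, 1])
    d = pairwise_distances(
        m.numeric, m.categorical,
        model.numeric_prototypes[perm], model.categorical_prototypes[perm],
        model.gamma,
    )
    inv = np.argsort(perm)
    relabeled = inv[model.labels]
    assert d[np.arange(m.n), relabeled].sum() == pytest.approx(model.cost)


def test_model_json_includes_original_scale(small_matrix, tmp_path):
    m, _ = small_matrix
    model = pr.fit_kprototypes(m, pr.KPConfig(k=3, n_init=2, seed=0))
    path = tmp_path / "model.json"
    model.to_json(path, params=m.params)
    import json

    obj = json.loads(path.read_text())
    assert len(obj["numeric_prototypes_original_scale"]) == 3
    assert obj["categorical_prototype_labels"][0][0] in ("female", "male")
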