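import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import phenorisk as pr
from phenorisk import preprocess as pp


class TestUnitConversion:
    @pytest.mark.parametrize(
        "mgdl,mmol", [(100, 5.55), (0, 0.0), (126, 6.993)]
    )
    def test_mgdl_to_mmol(self, mgdl, mmol):
        assert pr.mgdl_to_mmol(mgdl) == pytest.approx(mmol)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pr.mgdl_to_mmol(-1.0)


class TestHoma:
    @pytest.mark.parametrize(
        "g,i,b,ir",
        [(4.5, 9.0, 180.0, 1.8), (5.0, 22.5, 300.0, 5.0), (4.0, 0.0, 0.0, 0.0)],
    )
    def test_closed_form(self, g, i, b, ir):
        hb, hir = pr.compute_homa(g, i)
        assert hb == pytest.approx(b)
        assert hir == pytest.approx(ir)

    def test_low_glucose_flags_homa_b_missing(self):
        hb, hir = pr.compute_homa(np.array([3.4, 4.5]), np.array([10.0, 10.0]))
        assert np.isnan(hb[0]) and not np.isnan(hb[1])
        assert np.isfinite(hir).all()

    def test_negative_insulin_rejected(self):
        with pytest.raises(ValueError, match="insulin"):
            pr.compute_homa(5.0, -1.0)

    def test_precomputed_passthrough(self):
        hb, hir = pr.compute_homa(
            np.array([5.0]), np.array([10.0]), method="precomputed",
            homa_b=np.array([150.0]), homa_ir=np.array([1.2]),
        )
        assert hb[0] == 150.0 and hir[0] == 1.2


class TestGlycemicClassification:
    @pytest.mark.parametrize(
        "fpg,two_h,criteria,expected",
        [
            (5.8, None, "ADA", "IFG"),
            (5.8, None, "WHO", "normal"),
            (4.5, 5.0, "ADA", "normal"),
            (4.5, 5.0, "WHO", "normal"),
            (6.5, 8.5, "ADA", "IFG+IGT"),
            (6.5, 8.5, "WHO", "IFG+IGT"),
            (4.5, 8.5, "ADA", "IGT"),
            (5.0, None, "ADA", "normal"),
        ],
    )
    def test_cutoffs(self, fpg, two_h, criteria, expected):
        assert pr.classify_prediabetes(fpg, two_h, criteria) == expected

    def test_unknown_criteria(self):
        with pytest.raises(ValueError):
            pr.classify_prediabetes(5.0, None, "IDF")

    def test_who_ifg_implies_ada_ifg(self):
        """The WHO fasting interval is a subset of the ADA interval."""
        fpg = np.random.default_rng(0).uniform(3.0, 9.0, size=10_000)
        who = pr.classify_prediabetes(fpg, None, "WHO")
        ada = pr.classify_prediabetes(fpg, None, "ADA")
        who_ifg = np.isin(who, ["IFG", "IFG+IGT"])
        ada_ifg = np.isin(ada, ["IFG", "IFG+IGT"])
        assert (ada_ifg[who_ifg]).all()

    @pytest.mark.parametrize(
        "fpg,two_h,expected",
        [(7.0, None, True), (5.0, None, False), (6.0, 11.2, True),
         (6.9, 10.9, False)],
    )
    def test_diabetes_thresholds(self, fpg, two_h, expected):
        assert pr.classify_diabetes(fpg, two_h) is expected

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        g1=st.floats(3.0, 12.0), g2=st.floats(3.0, 12.0),
        h1=st.floats(3.0, 15.0), h2=st.floats(3.0, 15.0),
    )
    def test_diabetes_monotone_in_both_arguments(self, g1, g2, h1, h2):
        lo_g, hi_g = sorted((g1, g2))
        lo_h, hi_h = sorted((h1, h2))
        if pr.classify_diabetes(lo_g, lo_h):
            assert pr.classify_diabetes(hi_g, hi_h)


class TestExclusions:
    def _toy(self):
        rows = []
        for i in range(10):
            rows.append(
                dict(participant_id=i, baseline_age=45.0, fasting_glucose=5.0,
                     fasting_insulin=10.0, homa_b=120.0, homa_ir=1.5,
                     bmi=25.0, sbp=120.0, dbp=80.0, sex="female",
                     family_history="no", education="primary")
            )
        df = pd.DataFrame(rows)
        df.loc[0, "baseline_age"] = 25.0  # outside the 30-60 window
        df.loc[[1, 2], "fasting_insulin"] = np.nan
        return df

    def test_toy_counts_in_order(self):
        out, log = pr.apply_exclusions(
            self._toy(), rules=("age_window", "missing", "baseline_diabetes")
        )
        assert len(out) == 7
        assert log.counts == {"age_window": 1, "missing": 2, "baseline_diabetes": 0}
        log.validate()

    def test_baseline_diabetes_rule(self):
        df = self._toy().iloc[3:].copy()
        df.loc[df.index[0], "fasting_glucose"] = 7.2
        out, log = pr.apply_exclusions(df, rules=("baseline_diabetes",))
        assert log.counts == {"baseline_diabetes": 1}
        assert len(out) == 6

    def test_no_rules_is_identity(self):
        df = self._toy()
        out, log = pr.apply_exclusions(df, rules=())
        assert len(out) == len(df)
        assert log.counts == {}

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown exclusion"):
            pr.apply_exclusions(self._toy(), rules=("bmi_cap",))


class TestStandardization:
    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"x": [1.0] * 5, "sex": ["f", "m", "f", "m", "f"]})
        with pytest.raises(ValueError, match="zero-variance"):
            pr.standardize_and_trim(df, ["x"], ["sex"])

    def test_constructed_outlier_removed(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(1000)
        x = np.append(x, x.mean() + 8 * x.std())
        df = pd.DataFrame({"x": x, "sex": ["f", "m"] * 500 + ["f"]})
        m = pr.standardize_and_trim(df, ["x"], ["sex"])
        assert m.n == 1000
        assert 1000 not in m.row_ids  # exactly the planted row is gone

    def test_fit_params_give_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.normal(10, 3, 500),
                           "sex": rng.choice(["f", "m"], 500)})
        m = pr.standardize_and_trim(df, ["x"], ["sex"])
        z_all = (df["x"] - m.params.means[0]) / m.params.sds[0]
        assert z_all.mean() == pytest.approx(0.0, abs=1e-9)
        assert z_all.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_synthetic_cohort_trims_under_one_percent(self, small_cohort):
        sub, _ = pr.apply_exclusions(small_cohort)
        m = pr.standardize_and_trim(sub)
        assert (len(sub) - m.n) / len(sub) < 0.01

    def test_category_codes_dense(self, small_matrix):
        m, _ = small_matrix
        for j, name in enumerate(m.categorical_names):
            codes = m.categorical[:, j]
            assert codes.min() == 0
            assert codes.max() == len(m.params.levels[name]) - 1


class TestTransformNew:
    def test_transform_of_fitting_rows_is_identity(self, small_cohort):
        sub, _ = pr.apply_exclusions(small_cohort)
        m = pr.standardize_and_trim(sub)
        kept = sub[sub["participant_id"].isin(m.row_ids)]
        again = pr.transform_new(m.params, kept)
        assert np.allclose(again.numeric, m.numeric)
        assert (again.categorical == m.categorical).all()

    def test_mean_row_maps_to_zero(self, small_matrix):
        m, _ = small_matrix
        row = pd.DataFrame([dict(zip(m.params.numeric_names, m.params.means))
                            | {c: m.params.levels[c][0]
                               for c in m.params.categorical_names}])
        out = pr.transform_new(m.params, row)
        assert np.allclose(out.numeric, 0.0)

    def test_roundtrip_inverse(self, small_matrix):
        m, _ = small_matrix
        raw = pp.inverse_transform(m.params, m.numeric)
        z = (raw - m.params.means) / m.params.sds
        assert np.allclose(z, m.numeric, atol=1e-12)

    def test_schema_mismatch_rejected(self, small_matrix):
        m, _ = small_matrix
        with pytest.raises(ValueError, match="lack fitted"):
            pr.transform_new(m.params, pd.DataFrame({"bmi": [25.0]}))

    def test_params_json_roundtrip(self, small_matrix, tmp_path):
        m, _ = small_matrix
        path = tmp_path / "params.json"
        m.params.to_json(path)
        back = pp.StandardizationParams.from_json(path)
        assert np.allclose(back.means, m.params.means)
        assert back.levels == m.params.levels
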