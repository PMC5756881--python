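"""Cohort statistics: transforms, AICc arithmetic, two-stage selection,
exclusion models, predictions and diagnostics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import frondshape as fs
from frondshape import stats as st


@pytest.fixture(scope="module")
def cohort():
    return fs.simulate_cohort(seed=101).table


class TestTransforms:
    def test_circularity_log1m(self):
        assert st.transform_response("circularity", np.array([0.9]))[0] == pytest.approx(
            np.log(0.1)
        )

    def test_csm_log(self):
        assert st.transform_response("csm", np.array([1.0]))[0] == 0.0

    def test_size_identity(self):
        x = np.array([1.5, 2.5])
        assert np.array_equal(st.transform_response("area_mm2", x), x)

    def test_zero_csm_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            out = st.transform_response("csm", np.array([0.0, 0.01, 0.04]))
        assert out[0] == pytest.approx(np.log(0.005))

    def test_circularity_at_one_floored(self):
        with pytest.warns(UserWarning, match="floored"):
            out = st.transform_response("circularity", np.array([1.0, 0.9]))
        assert np.isfinite(out).all()


class TestAicc:
    def test_closed_form_example(self):
        assert st.aicc(-50, 2, 100) == pytest.approx(104 + 12 / 97)

    @settings(max_examples=50, deadline=None)
    @given(
        ll=hst.floats(-1e4, 1e4),
        k=hst.integers(1, 20),
        n=hst.integers(30, 10000),
    )
    def test_closed_form_property(self, ll, k, n):
        assert st.aicc(ll, k, n) == pytest.approx(
            -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1), abs=1e-9
        )

    def test_approaches_aic_for_large_n(self):
        assert st.aicc(-50, 3, 10**7) == pytest.approx(106, abs=1e-5)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            st.aicc(-10, 5, 6)


class TestAkaikeWeights:
    def test_two_model_example(self):
        w = st.akaike_weights(np.array([0.0, 2.0]))
        assert w == pytest.approx([0.7311, 0.2689], abs=1e-4)

    @settings(max_examples=30, deadline=None)
    @given(shift=hst.floats(-1000, 1000), seed=hst.integers(0, 2**31 - 1))
    def test_sum_to_one_and_shift_invariant(self, shift, seed):
        a = np.random.default_rng(seed).uniform(100, 200, 6)
        w = st.akaike_weights(a)
        assert w.sum() == pytest.approx(1.0)
        assert np.allclose(st.akaike_weights(a + shift), w)


class TestSelectRandomStructure:
    def test_strong_random_slopes_selected(self, cohort):
        data = st.prepare_response(cohort, "area_mm2")
        assert st.select_random_structure(data)["structure"] == "slope"

    def test_no_random_effects_data_avoids_slope_structure(self):
        # re_sd = 0 generator: the penalized slope structure should not win
        wins = 0
        for seed in range(10):
            rp = fs.ResponseParams(beta=(5.0, 0.0, 0.0, 0.0), shelf=(0, 0, 0, 0), resid_sd=0.5)
            params = fs.CohortParams(
                responses={"area_mm2": rp}, excl_beta=(-50.0, 0.0), seed=seed
            )
            t = fs.simulate_cohort(params).table
            sel = st.select_random_structure(st.prepare_response(t, "area_mm2"))
            wins += sel["structure"] == "slope"
        assert wins <= 2

    def test_deterministic(self, cohort):
        data = st.prepare_response(cohort, "csm")
        a = st.select_random_structure(data)
        b = st.select_random_structure(data)
        assert a["structure"] == b["structure"]
        assert a["winners_by_degree"] == b["winners_by_degree"]


class TestDredgeFixed:
    def test_table_invariants(self, cohort):
        data = st.prepare_response(cohort, "csm_forced")
        tbl, best = st.dredge_fixed(data, "none")
        assert len(tbl) == 8
        assert tbl["weight"].sum() == pytest.approx(1.0)
        assert tbl["dAICc"].iloc[0] == 0.0
        assert (tbl["dAICc"].diff().dropna() >= 0).all()
        assert best is not None and best.random == "none"

    def test_cubic_generator_ranks_cubic_first(self, cohort):
        data = st.prepare_response(cohort, "area_mm2")
        tbl, _ = st.dredge_fixed(data, "slope", refit_best=False)
        assert tbl.iloc[0]["degree"] == 3

    def test_df_convention_matches_reported_layout(self, cohort):
        # cubic + intercept&slope RE: 4 fixed + 3 variance + 1 residual = 8
        data = st.prepare_response(cohort, "area_mm2")
        f = st.fit_gaussian(data, 3, False, "slope", reml=False)
        assert f.k == 8
        f2 = st.fit_gaussian(data, 3, True, "slope", reml=False)
        assert f2.k == 11  # + 3 shelf dummies


class TestExclusion:
    def test_positive_slope_recovered_with_strong_wald_z(self, cohort):
        res = st.fit_exclusion(cohort)
        assert res["best_fit"].fe_params[1] > 0
        assert res["z"] > 2
        assert res["table"]["weight"].sum() == pytest.approx(1.0)

    def test_prediction_monotone_when_slope_positive(self, cohort):
        res = st.fit_exclusion(cohort)
        pred = res["curve"]["predicted"].to_numpy()
        assert (np.diff(pred) > 0).all()
        assert (res["curve"]["lower"] <= res["curve"]["predicted"]).all()
        assert (res["curve"]["predicted"] <= res["curve"]["upper"]).all()


class TestPredictWithBands:
    def test_bands_bracket_prediction(self, cohort):
        res = st.analyze_response(cohort, "area_mm2")
        curve = st.predict_with_bands(res["best_fit"], np.arange(1.0, 31.0))
        assert (curve["lower"] <= curve["predicted"]).all()
        assert (curve["predicted"] <= curve["upper"]).all()

    def test_shelf_averaging_is_identity_without_shelf(self, cohort):
        data = st.prepare_response(cohort, "csm")
        fit = st.fit_gaussian(data, 1, False, "none", reml=True)
        a = st.predict_with_bands(fit, np.arange(1.0, 31.0), average_shelf=True)
        b = st.predict_with_bands(fit, np.arange(1.0, 31.0), average_shelf=False)
        assert np.allclose(a["predicted"], b["predicted"])

    def test_band_width_shrinks_with_sample_size(self):
        widths = []
        for n in (403, 4 * 403):
            params = fs.CohortParams(n_offspring=n, excl_beta=(-50.0, 0.0), seed=8)
            t = fs.simulate_cohort(params).table
            data = st.prepare_response(t, "csm")
            fit = st.fit_gaussian(data, 1, False, "none", reml=True)
            c = st.predict_with_bands(fit, np.arange(2.0, 29.0))
            widths.append((c["upper"] - c["lower"]).mean())
        assert widths[1] < widths[0] * 0.7  # ~ 1/sqrt(4) = 0.5 expected

    def test_extrapolation_warns(self, cohort):
        data = st.prepare_response(cohort, "csm")
        fit = st.fit_gaussian(data, 1, False, "none", reml=True)
        with pytest.warns(UserWarning, match="beyond"):
            st.predict_with_bands(fit, np.array([0.0, 50.0]))


class TestDiagnostics:
    def test_gaussian_residuals_have_small_skewness(self, cohort, tmp_path):
        res = st.analyze_response(cohort, "area_mm2")
        d = st.residual_diagnostics(res["best_fit"], tmp_path, "area_mm2")
        assert abs(d["skewness"]) < 0.3
        for p in d["plots"].values():
            from pathlib import Path

            f = Path(p)
            assert f.exists() and f.stat().st_size > 0

    def test_log_transform_reduces_csm_skewness(self, cohort):
        raw = cohort["csm"].dropna().to_numpy()
        from scipy.stats import skew

        assert skew(raw) > 0
        assert abs(skew(np.log(raw))) < skew(raw)


def test_n_grows_selection_of_generating_model_non_decreasing():
    """With 10x the data the generating cubic model is selected at least as
    often (coarse consistency check, few replicates)."""
    freq = []
    for n in (120, 1200):
        hits = 0
        for seed in range(5):
            params = fs.CohortParams(n_offspring=n, excl_beta=(-50.0, 0.0), seed=seed)
            t = fs.simulate_cohort(params).table
            data = st.prepare_response(t, "area_mm2")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tbl, _ = st.dredge_fixed(data, "slope", refit_best=False)
            hits += tbl.iloc[0]["degree"] == 3
        freq.append(hits)
    assert freq[1] >= freq[0]
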