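"""Design rows, OLS diagnostics, and the two emissions estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from puffs import (
    DomainError,
    EmissionsTrial,
    NicotineMassRatioModel,
    SingularDesignError,
    TpmConcentrationModel,
    fit_nic_model,
    fit_tpm_model,
    load_model,
    ols_fit,
    read_trials,
    save_model,
    tpm_design_row,
    write_trials,
)
from puffs.emissions import adjusted_r_squared

# Independently computed (symbolic evaluation at 20 digits) design row and
# surface value at (q, d) = (30.4, 2.3) with the packaged reference b1..b6.
ROW_30p4_2p3 = [
    1.0,
    3.4144426084121760,
    2.3,
    11.658418326140544,
    -6.0748461560470330,
    69.92,
]
C_REF_30p4_2p3 = 0.016587885385054041


class TestDesignRow:
    def test_log_identities_at_e_and_1000(self):
        row = tpm_design_row(math.e, 1000.0)
        np.testing.assert_allclose(
            row, [1.0, 1.0, 1000.0, 1.0, 0.0, 1000.0 * math.e], atol=1e-12
        )

    def test_unit_point(self):
        row = tpm_design_row(1.0, 1.0)
        np.testing.assert_allclose(
            row, [1.0, 0.0, 1.0, 0.0, -math.log(1000.0), 1.0], atol=1e-12
        )

    def test_frozen_symbolic_oracle(self):
        np.testing.assert_allclose(tpm_design_row(30.4, 2.3), ROW_30p4_2p3, rtol=1e-12)

    def test_vectorized_rows_match_scalar(self):
        q = np.array([5.0, 30.4, 60.0])
        d = np.array([1.0, 2.3, 4.0])
        rows = tpm_design_row(q, d)
        assert rows.shape == (3, 6)
        for i in range(3):
            np.testing.assert_allclose(rows[i], tpm_design_row(q[i], d[i]), rtol=1e-14)

    @pytest.mark.parametrize("q,d", [(0.0, 1.0), (-1.0, 2.0), (1.0, 0.0), (np.nan, 1.0)])
    def test_domain_errors(self, q, d):
        with pytest.raises(DomainError):
            tpm_design_row(q, d)


class TestTpmPrediction:
    def test_log_prediction_is_dot_product(self):
        model = TpmConcentrationModel.from_coefficients([1.0, 0.5, -0.1, 0.02, 0.3, 1e-3])
        for q, d in [(5.0, 1.0), (30.4, 2.3), (80.0, 4.0)]:
            lnc = model.predict_log(np.array([[q, d]]))[0]
            assert lnc == pytest.approx(float(tpm_design_row(q, d) @ model.coef_), abs=1e-12)
            assert math.log(model.predict_one(q, d)) == pytest.approx(lnc, abs=1e-12)

    def test_reference_surface_frozen_value(self, reference_models):
        tpm, _ = reference_models
        assert tpm.predict_one(30.4, 2.3) == pytest.approx(C_REF_30p4_2p3, rel=1e-12)

    def test_intercept_shift_scales_prediction(self, reference_models):
        tpm, _ = reference_models
        shifted = TpmConcentrationModel.from_coefficients(
            tpm.coef_ + np.array([math.log(2.0), 0, 0, 0, 0, 0])
        )
        for q, d in [(15.0, 1.5), (40.0, 3.0), (60.0, 4.0)]:
            assert shifted.predict_one(q, d) == pytest.approx(
                2.0 * tpm.predict_one(q, d), rel=1e-12
            )

    def test_positivity_everywhere(self, reference_models):
        tpm, _ = reference_models
        q = np.linspace(1, 120, 40)
        d = np.linspace(0.2, 8, 40)
        qq, dd = np.meshgrid(q, d)
        pred = tpm.predict(np.column_stack([qq.ravel(), dd.ravel()]))
        assert np.all(pred > 0)

    def test_ln_d_reparameterization_invariance(self, reference_models):
        # ln(d/1000) = ln d - ln 1000: moving the constant into the intercept
        # leaves the surface unchanged
        tpm, _ = reference_models
        b = tpm.coef_
        for q, d in [(12.0, 1.0), (30.4, 2.3), (65.0, 4.4)]:
            alt = (
                (b[0] - b[4] * math.log(1000.0))
                + b[1] * math.log(q)
                + b[2] * d
                + b[3] * math.log(q) ** 2
                + b[4] * math.log(d)
                + b[5] * q * d
            )
            assert alt == pytest.approx(math.log(tpm.predict_one(q, d)), rel=1e-12)


class TestNicPrediction:
    def test_constant_model(self):
        nic = NicotineMassRatioModel.from_coefficients([0.0098, 0.0])
        for q in [0.0, 10.0, 55.0]:
            assert nic.predict_one(q) == pytest.approx(0.0098)

    def test_intercept_at_zero_flow(self, reference_models):
        _, nic = reference_models
        assert nic.predict_one(0.0) == pytest.approx(nic.coef_[0], abs=0)

    def test_frozen_reference_value_at_q50(self, reference_models):
        _, nic = reference_models
        assert nic.predict_one(50.0) == pytest.approx(0.009559, abs=1e-12)

    def test_below_unpuffed_liquid_fraction(self, reference_models):
        # the aerosol mass ratio must not exceed the ratio measured in the
        # un-puffed e-liquid (0.0140 mg/mg) anywhere in the behaviour range
        _, nic = reference_models
        q = np.linspace(0, 100, 201)
        assert np.all(nic.predict(q) < 0.0140)

    def test_warns_outside_unit_interval(self):
        nic = NicotineMassRatioModel.from_coefficients([0.5, 0.02])
        with pytest.warns(RuntimeWarning):
            nic.predict(np.array([40.0]))


class TestOlsFit:
    def test_exact_fit_guarded(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        y = 2.0 + 3.0 * np.arange(5.0)
        beta, report = ols_fit(X, y)
        np.testing.assert_allclose(beta, [2.0, 3.0], atol=1e-12)
        assert report.r_squared == pytest.approx(1.0)
        assert report.extra.get("exact_fit") is True
        assert np.all(report.std_errors == 0)
        assert np.all(np.isinf(report.t_stats))

    def test_three_point_line_recovery(self):
        X = np.column_stack([np.ones(3), np.array([1.0, 2.0, 4.0])])
        y = np.array([1.0, 3.0, 7.0])  # y = -1 + 2x exactly
        beta, _ = ols_fit(X, y)
        np.testing.assert_allclose(beta, [-1.0, 2.0], atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=8, max_value=20),
        p=st.integers(min_value=2, max_value=6),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_matches_normal_equations_oracle(self, n, p, seed):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = rng.normal(size=n)
        beta, report = ols_fit(X, y)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(beta, oracle, rtol=1e-8, atol=1e-10)
        # SE oracle from the normal-equations covariance
        resid = y - X @ beta
        s2 = resid @ resid / (n - p)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(report.std_errors, se, rtol=1e-8)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 3))])
        y = X @ np.array([1.0, 0.5, -2.0, 0.1]) + rng.normal(scale=0.7, size=30)
        beta, report = ols_fit(X, y)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(beta, ref.params, rtol=1e-10)
        np.testing.assert_allclose(report.std_errors, ref.bse, rtol=1e-10)
        np.testing.assert_allclose(report.t_stats, ref.tvalues, rtol=1e-10)
        np.testing.assert_allclose(report.p_values, ref.pvalues, rtol=1e-8, atol=1e-12)
        assert report.r_squared == pytest.approx(ref.rsquared, rel=1e-12)
        assert report.adj_r_squared == pytest.approx(ref.rsquared_adj, rel=1e-12)
        assert report.rmse == pytest.approx(np.sqrt(ref.mse_resid), rel=1e-12)

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(SingularDesignError, match="x2"):
            ols_fit(X, np.arange(10.0))

    def test_underdetermined_rejected(self):
        with pytest.raises(DomainError):
            ols_fit(np.ones((3, 3)), np.ones(3))


def _trials_from_surface(tpm, nic, conditions, nic_subset=None):
    trials = []
    for i, (q, d) in enumerate(conditions):
        vol = 12 * q * d
        c = tpm.predict_one(q, d)
        nic_mass = None
        if nic is not None and (nic_subset is None or i in nic_subset):
            nic_mass = nic.predict_one(q) * c * vol
        trials.append(
            EmissionsTrial(
                condition_id=f"T{i:02d}",
                q=q,
                d=d,
                n_puffs=12,
                total_volume=vol,
                tpm_mass=c * vol,
                nicotine_mass=nic_mass,
            )
        )
    return trials


CONDITIONS = [
    (12.0, 1.0), (20.0, 1.5), (28.0, 2.0), (36.0, 2.5), (44.0, 3.0),
    (52.0, 3.5), (60.0, 4.0), (15.0, 3.8), (48.0, 1.2), (33.0, 4.4),
]


class TestModelFitting:
    def test_noise_free_tpm_recovery(self, reference_models):
        tpm, nic = reference_models
        trials = _trials_from_surface(tpm, nic, CONDITIONS)
        model, report = fit_tpm_model(trials)
        np.testing.assert_allclose(model.coef_, tpm.coef_, rtol=1e-8)
        assert report.r_squared == pytest.approx(1.0)

    def test_noise_free_nic_recovery(self, reference_models):
        tpm, nic = reference_models
        trials = _trials_from_surface(tpm, nic, CONDITIONS)
        model, _ = fit_nic_model(trials)
        np.testing.assert_allclose(model.coef_, nic.coef_, rtol=1e-8, atol=1e-14)

    def test_constant_mass_ratio_fits_intercept_only(self, reference_models):
        tpm, _ = reference_models
        const = NicotineMassRatioModel.from_coefficients([0.0123, 0.0])
        trials = _trials_from_surface(tpm, const, CONDITIONS)
        model, _ = fit_nic_model(trials)
        assert model.coef_[0] == pytest.approx(0.0123, rel=1e-10)
        assert model.coef_[1] == pytest.approx(0.0, abs=1e-12)

    def test_report_identities(self, reference_models):
        tpm, nic = reference_models
        rng = np.random.default_rng(5)
        trials = []
        for i, (q, d) in enumerate(CONDITIONS * 3):
            vol = 12 * q * d
            c = tpm.predict_one(q, d) * math.exp(rng.normal(0, 0.15))
            trials.append(
                EmissionsTrial(f"T{i}", q, d, 12, vol, c * vol, None)
            )
        _, report = fit_tpm_model(trials)
        np.testing.assert_allclose(
            report.t_stats, report.estimates / report.std_errors, rtol=1e-9
        )
        assert report.adj_r_squared == pytest.approx(
            adjusted_r_squared(report.r_squared, report.n_obs, report.n_params), rel=1e-12
        )
        assert 0.0 <= report.r_squared <= 1.0
        assert report.n_obs > report.n_params
        assert "rmse_natural_scale" in report.extra

    def test_too_few_trials_rejected(self, reference_models):
        tpm, nic = reference_models
        trials = _trials_from_surface(tpm, nic, CONDITIONS[:5])
        with pytest.raises(DomainError):
            fit_tpm_model(trials)
        with pytest.raises(DomainError):
            fit_nic_model(trials[:2])

    def test_nonpositive_mass_names_trial(self, reference_models):
        tpm, nic = reference_models
        trials = _trials_from_surface(tpm, nic, CONDITIONS)
        bad = EmissionsTrial("BAD-1", 30.0, 2.0, 12, 720.0, 0.0, None)
        with pytest.raises(DomainError, match="BAD-1"):
            fit_tpm_model(trials + [bad])


class TestTrialIO:
    def test_trials_roundtrip(self, tmp_path, reference_models):
        tpm, nic = reference_models
        trials = _trials_from_surface(tpm, nic, CONDITIONS, nic_subset={0, 3, 7})
        path = tmp_path / "trials.csv"
        write_trials(trials, path)
        back = read_trials(path)
        assert len(back) == len(trials)
        for a, b in zip(trials, back):
            assert b.condition_id == a.condition_id
            assert b.q == pytest.approx(a.q, rel=1e-12)
            assert b.tpm_mass == pytest.approx(a.tpm_mass, rel=1e-12)
            if a.nicotine_mass is None:
                assert b.nicotine_mass is None
            else:
                assert b.nicotine_mass == pytest.approx(a.nicotine_mass, rel=1e-12)

    def test_model_json_roundtrip(self, tmp_path, reference_models):
        tpm, nic = reference_models
        path = tmp_path / "model.json"
        save_model(path, tpm, nic, meta={"note": "test"})
        tpm2, nic2, meta = load_model(path)
        np.testing.assert_allclose(tpm2.coef_, tpm.coef_, rtol=0)
        np.testing.assert_allclose(nic2.coef_, nic.coef_, rtol=0)
        assert meta["note"] == "test"
        assert tpm2.q_range_ == tpm.q_range_


class TestSklearnProtocol:
    def test_get_params_and_clone(self):
        from sklearn.base import clone

        model = TpmConcentrationModel()
        assert model.get_params() == {}
        clone(model)  # must not raise

    def test_fit_predict_shapes(self, reference_models):
        tpm, nic = reference_models
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.uniform(12, 65, 40), rng.uniform(1, 4.4, 40)])
        y = tpm.predict(X) * np.exp(rng.normal(0, 0.1, 40))
        fitted = TpmConcentrationModel().fit(X, y)
        assert fitted.predict(X).shape == (40,)
        assert fitted.coef_.shape == (6,)
        assert fitted.q_range_[0] >= 12.0
        score = fitted.score(X, y)  # RegressorMixin R^2 on the natural scale
        assert 0.0 < score <= 1.0
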