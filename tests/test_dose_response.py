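"""Dose-response curves: evaluation, inversion, fitting, model selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from herbtox.dose_response import (DoseResponseCurve, ResponseModel,
                                   curve_db_read, curve_db_write, ecx,
                                   effect_at, fit_model, select_best)

CONC_GRID = np.geomspace(1e-3, 1e5, 60)


def grid_search_fit(family, conc, resp, thetas, alphas, betas):
    """Independent brute-force least-squares oracle over a parameter grid."""
    best, best_sse = None, np.inf
    for th, al, be in itertools.product(thetas, alphas, betas):
        pred = effect_at(ResponseModel(family, th, al, be), conc)
        sse = float(np.sum((pred - resp) ** 2))
        if sse < best_sse:
            best, best_sse = (th, al, be), sse
    return best, best_sse


class TestEffectAndInversion:
    def test_logistic_midpoint(self, logistic_unit):
        assert effect_at(logistic_unit, 10.0) == pytest.approx(0.5)

    def test_zero_concentration_is_zero_effect(self, logistic_unit, weibull_unit):
        assert effect_at(logistic_unit, 0.0) == 0.0
        assert effect_at(weibull_unit, 0.0) == 0.0

    def test_logistic_formula_value(self, logistic_unit):
        # alpha + beta*log10(100) = 1 => effect 1/(1+e^-1)
        assert effect_at(logistic_unit, 100.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-1.0)), rel=1e-12)

    def test_negative_concentration_rejected(self, logistic_unit):
        with pytest.raises(ValueError):
            effect_at(logistic_unit, -1.0)

    def test_ec50_symmetry_point(self, logistic_unit):
        assert ecx(logistic_unit, 0.5) == pytest.approx(10.0, rel=1e-12)

    def test_weibull_characteristic_point(self, weibull_unit):
        # exp(alpha + beta*0) = 1 forces effect 1 - 1/e at c = 1
        assert ecx(weibull_unit, 1.0 - np.exp(-1.0)) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("c", [0.1, 1.0, 10.0, 100.0])
    def test_roundtrip_concentration(self, logistic_unit, weibull_unit, c):
        for m in (logistic_unit, weibull_unit):
            assert ecx(m, effect_at(m, c)) == pytest.approx(c, rel=1e-9)

    @pytest.mark.parametrize("frac", [0.05, 0.10, 0.25, 0.5])
    def test_inversion_consistency(self, curve_db, frac):
        for model in curve_db.curves.values():
            x = frac * model.theta_max
            assert abs(effect_at(model, ecx(model, x)) - x) < 1e-9

    def test_ecx_domain_error_names_theta_max(self, logistic_unit):
        with pytest.raises(ValueError, match="theta_max"):
            ecx(logistic_unit, 1.5)
        with pytest.raises(ValueError):
            ecx(logistic_unit, 0.0)

    def test_monotone_over_wide_grid(self, curve_db):
        for model in curve_db.curves.values():
            e = effect_at(model, CONC_GRID)
            assert np.all(np.diff(e) >= 0)
            # open upper bound mathematically; allow float saturation at 1e5
            assert np.all((e >= 0) & (e <= model.theta_max))

    @given(alpha=st.floats(-4, 4), beta=st.floats(0.3, 4.0),
           theta=st.floats(0.3, 1.0), x_frac=st.floats(0.01, 0.99))
    @settings(max_examples=60, deadline=None)
    def test_inverse_identity_property(self, alpha, beta, theta, x_frac):
        for family in ("logistic", "weibull"):
            m = ResponseModel(family, theta, alpha, beta)
            x = x_frac * theta
            assert effect_at(m, ecx(m, x)) == pytest.approx(x, rel=1e-9, abs=1e-12)


class TestFitting:
    conc8 = 0.625 * 2.0 ** np.arange(8)  # spans the midpoint at 10

    def test_noiseless_recovery(self, logistic_unit):
        y = effect_at(logistic_unit, self.conc8)
        fr = fit_model(self.conc8, y, "logistic")
        assert fr.converged
        assert fr.model.alpha == pytest.approx(-1.0, rel=1e-6)
        assert fr.model.beta == pytest.approx(1.0, rel=1e-6)
        assert fr.model.theta_max == pytest.approx(1.0, rel=1e-6)
        assert fr.rss < 1e-15

    def test_estimator_api(self, logistic_unit):
        y = effect_at(logistic_unit, self.conc8)
        est = DoseResponseCurve(family="logistic").fit(self.conc8[:, None], y)
        assert est.converged_
        assert est.get_params() == {"family": "logistic"}
        pred = est.predict(self.conc8[:, None])
        np.testing.assert_allclose(pred, y, atol=1e-8)

    def test_matches_grid_search_oracle(self, rng):
        fixtures = [
            ResponseModel("logistic", 1.0, -2.0, 1.0),
            ResponseModel("logistic", 0.9, 0.0, 2.0),
            ResponseModel("weibull", 1.0, -1.0, 0.8),
            ResponseModel("weibull", 0.8, -2.5, 1.5),
            ResponseModel("logistic", 0.7, -3.0, 0.7),
        ]
        conc = 0.1 * 4.0 ** np.arange(9)
        thetas = np.linspace(0.3, 1.0, 15)
        alphas = np.linspace(-5, 3, 81)
        betas = np.linspace(0.3, 3.0, 28)
        for truth in fixtures:
            y = effect_at(truth, conc) + rng.normal(0, 0.01, conc.size)
            y = np.clip(y, -0.1, 1.1)
            fr = fit_model(conc, y, truth.family)
            (th, al, be), sse = grid_search_fit(truth.family, conc, y,
                                                thetas, alphas, betas)
            # optimizer must be at least as good as the grid optimum
            assert fr.rss <= sse + 1e-12
            assert abs(fr.model.alpha - al) <= (alphas[1] - alphas[0])
            assert abs(fr.model.beta - be) <= (betas[1] - betas[0])

    def test_noisy_ec50_recovery_within_ten_percent(self):
        truth = ResponseModel("logistic", 1.0, -1.2 * np.log10(100.0), 1.2)
        conc = 12.5 * 2.0 ** np.arange(8)
        errs = []
        for seed in range(12):
            r = np.random.default_rng(seed)
            c = np.repeat(conc, 3)
            y = np.clip(effect_at(truth, c) + r.normal(0, 0.02, c.size), -0.1, 1.1)
            fr = fit_model(c, y, "logistic")
            errs.append(abs(fr.model.ec50 - 100.0) / 100.0)
        assert np.median(errs) < 0.10

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_model([1, 2, 4], [0.1, 0.3, 0.5], "logistic")

    def test_out_of_window_response_rejected(self):
        with pytest.raises(ValueError, match="data errors"):
            fit_model([1, 2, 4, 8], [0.0, 0.2, 1.5, 0.9], "logistic")

    def test_flat_data_does_not_converge(self):
        fr = fit_model([1, 2, 4, 8, 16], [0.5, 0.502, 0.499, 0.501, 0.5],
                       "logistic")
        assert not fr.converged
        assert fr.model is None

    def test_zero_concentration_controls_excluded(self, logistic_unit):
        conc = np.concatenate([[0.0, 0.0], self.conc8])
        y = effect_at(logistic_unit, conc)
        fr = fit_model(conc, y, "logistic")
        assert fr.converged and fr.n_points == 8


class TestSelection:
    conc = 0.1 * 4.0 ** np.arange(8)

    @pytest.mark.parametrize("family", ["logistic", "weibull"])
    def test_true_family_selected_on_noiseless_data(self, family):
        truth = ResponseModel(family, 1.0, -1.0, 1.2)
        y = effect_at(truth, self.conc)
        best = select_best(self.conc, y)
        assert best.model.family == family

    def test_weibull_truth_has_lower_aic(self, weibull_unit):
        y = effect_at(weibull_unit, self.conc)
        f_w = fit_model(self.conc, y, "weibull")
        f_l = fit_model(self.conc, y, "logistic")
        assert f_w.aic < f_l.aic

    def test_single_converged_family_wins(self, logistic_unit):
        y = effect_at(logistic_unit, self.conc)
        best = select_best(self.conc, y, families=("weibull",))
        assert best.model.family == "weibull"

    def test_all_failed_raises(self):
        flat = np.full(8, 0.4)
        with pytest.raises(RuntimeError, match="no converged"):
            select_best(self.conc, flat)


class TestCurveDatabase:
    def test_roundtrip_bitwise(self, curve_db, tmp_path):
        path = tmp_path / "curves.yaml"
        fits = {name: fit_model(0.01 * 4.0 ** np.arange(10),
                                effect_at(m, 0.01 * 4.0 ** np.arange(10)),
                                m.family)
                for name, m in curve_db.curves.items()}
        curve_db_write(fits, path)
        back = curve_db_read(path)
        assert set(back) == set(fits)
        for name in fits:
            a, b = fits[name].model, back[name].model
            assert (a.family, a.theta_max, a.alpha, a.beta) == \
                   (b.family, b.theta_max, b.alpha, b.beta)

    def test_empty_database(self, tmp_path):
        path = tmp_path / "empty.yaml"
        curve_db_write({}, path)
        assert curve_db_read(path) == {}

    def test_duplicate_name_rejected(self, tmp_path, logistic_unit):
        path = tmp_path / "dup.yaml"
        curve_db_write({"atrazine": logistic_unit}, path)
        text = path.read_text()
        dup = text + text[text.index("- herbicide:"):]
        path.write_text(dup)
        with pytest.raises(ValueError, match="duplicate"):
            curve_db_read(path)

    def test_unknown_family_tag_named(self, tmp_path, logistic_unit):
        path = tmp_path / "bad.yaml"
        curve_db_write({"atrazine": logistic_unit}, path)
        path.write_text(path.read_text().replace("logistic", "probit"))
        with pytest.raises(ValueError, match="probit"):
            curve_db_read(path)
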