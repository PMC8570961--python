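"""Dynamic prediction: conditioning identities, closed forms, MC behaviour."""
import numpy as np
import pandas as pd
import pytest

from aclfjm.predict import (PlugInPredictor, PredictionError, predict_survival,
                            rank_by_mortality)


def history(values, times=None, pid="x"):
    times = np.arange(len(values), dtype=float) * 3 if times is None else times
    return pd.DataFrame({"patient_id": pid, "t": times, "meld_na": values})


BASE = {"patient_id": "x"}


class TestContracts:
    @pytest.mark.parametrize("method", ["mc", "plugin"])
    def test_survival_at_landmark_is_exactly_one(self, toy_fit_factory, method):
        fit = toy_fit_factory()
        dp = predict_survival(fit, BASE, history([20, 22, 24]), t=6.0,
                              u_grid=[6.0, 20.0], method=method, seed=1)
        assert dp.pi[0] == 1.0

    @pytest.mark.parametrize("method", ["mc", "plugin"])
    def test_curve_monotone_non_increasing(self, toy_fit_factory, method):
        fit = toy_fit_factory(alpha_slope=1.0)
        u = np.linspace(6.0, 96.0, 31)
        dp = predict_survival(fit, BASE, history([18, 25, 31]), t=6.0, u_grid=u,
                              method=method, seed=2)
        assert np.all(np.diff(dp.pi) <= 1e-12)
        assert np.all((dp.pi >= 0) & (dp.pi <= 1))

    def test_band_contains_point_estimate(self, toy_fit_factory):
        fit = toy_fit_factory()
        u = np.linspace(6.0, 60.0, 10)
        dp = predict_survival(fit, BASE, history([20, 26, 30]), t=6.0, u_grid=u,
                              n_draws=300, seed=3)
        assert np.all(dp.band_lo <= dp.pi + 1e-12)
        assert np.all(dp.band_hi >= dp.pi - 1e-12)

    def test_probability_bounds_randomized(self, toy_fit_factory):
        """10,000 randomized (history, horizon) outputs all land in [0,1]."""
        fit = toy_fit_factory(alpha_value=0.2, alpha_slope=3.0, lam=0.01)
        rng = np.random.default_rng(4)
        total = 0
        for _ in range(100):
            k = rng.integers(1, 8)
            vals = rng.uniform(6, 40, k)
            t = 3.0 * (k - 1)
            u = np.sort(rng.uniform(t, t + 120, 100))
            dp = predict_survival(fit, BASE, history(vals), t=t, u_grid=u,
                                  method="plugin")
            assert np.all((dp.pi >= 0.0) & (dp.pi <= 1.0))
            total += dp.pi.size
        assert total == 10_000

    def test_errors_for_bad_landmarks(self, toy_fit_factory):
        fit = toy_fit_factory()
        with pytest.raises(PredictionError, match="precedes"):
            predict_survival(fit, BASE, history([20], times=[5.0]), t=2.0,
                             u_grid=[10.0])
        with pytest.raises(PredictionError, match="empty"):
            predict_survival(fit, BASE, history([]), t=0.0, u_grid=[10.0])


class TestClosedForm:
    def test_flat_trajectory_constant_hazard_limit(self, toy_fit_factory):
        """Noise-free flat history, tight random effects, no slope term:
        pi(u|t) = exp(-lam * e^{alpha*m} * (u - t))."""
        m, lam, alpha = 24.0, 0.002, 0.1
        fit = toy_fit_factory(intercept=20.0, alpha_value=alpha,
                              alpha_slope=0.0, lam=lam, sigma=0.05,
                              d_diag=(25.0, 1e-8))
        hist = history([m] * 8, times=np.linspace(0, 21, 8))
        u = np.array([21.0, 30.0, 60.0, 90.0])
        dp = predict_survival(fit, BASE, hist, t=21.0, u_grid=u, n_draws=4000,
                              seed=5)
        expected = np.exp(-lam * np.exp(alpha * m) * (u - 21.0))
        np.testing.assert_allclose(dp.pi, expected, atol=5e-3)

    def test_new_high_measurement_lowers_whole_curve(self, toy_fit_factory):
        fit = toy_fit_factory(alpha_value=0.15, alpha_slope=5.0, lam=0.002)
        u = np.linspace(9.0, 60.0, 12)
        before = predict_survival(fit, BASE, history([20, 21, 22]), t=9.0,
                                  u_grid=u, method="plugin")
        after = predict_survival(fit, BASE,
                                 history([20, 21, 22, 35],
                                         times=[0, 3, 6, 9.0]), t=9.0,
                                 u_grid=u, method="plugin")
        assert np.all(after.pi[1:] < before.pi[1:])

    def test_interpolating_posterior_with_diffuse_prior(self, toy_fit_factory):
        """With an essentially flat random-effects prior the EB line passes
        through a two-point noise-free history exactly (BLUP limit)."""
        from aclfjm.predict import _posterior_moments
        fit = toy_fit_factory(intercept=0.0, slope=0.0, sigma=1e-4,
                              d_diag=(1e6, 1e6))
        t_obs = np.array([2.0, 10.0])
        y_obs = np.array([15.0, 27.0])
        mu, _, _, _ = _posterior_moments(fit, np.empty(0), t_obs, y_obs)
        np.testing.assert_allclose(mu[0] + mu[1] * t_obs, y_obs, atol=1e-4)


class TestChaining:
    def test_plugin_predictions_chain_multiplicatively(self, toy_fit_factory):
        """With no new measurements between landmarks, conditioning is
        consistent: pi(u|t) = pi(u|t') * pi(t'|t) for t < t' < u."""
        fit = toy_fit_factory(alpha_value=0.12, alpha_slope=2.0, lam=0.003)
        hist = history([22, 27, 31])
        t, t2, u = 6.0, 15.0, 60.0
        pi_u_t = predict_survival(fit, BASE, hist, t=t, u_grid=[t2, u],
                                  method="plugin")
        pi_u_t2 = predict_survival(fit, BASE, hist, t=t2, u_grid=[u],
                                   method="plugin")
        assert pi_u_t.pi[1] == pytest.approx(pi_u_t.pi[0] * pi_u_t2.pi[0],
                                             abs=1e-10)


class TestMonteCarlo:
    def test_mc_error_halves_per_doubling(self, toy_fit_factory):
        fit = toy_fit_factory(alpha_value=0.12, lam=0.004, sigma=2.0)
        hist = history([20, 26, 33])
        sizes = [50, 100, 200, 400, 800]
        sds = []
        for n in sizes:
            vals = [predict_survival(fit, BASE, hist, t=6.0, u_grid=[60.0],
                                     n_draws=n, seed=s).pi[0]
                    for s in range(30)]
            sds.append(np.std(vals))
        slope = np.polyfit(np.log(sizes), np.log(sds), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.17)

    def test_seed_reproducibility(self, toy_fit_factory):
        fit = toy_fit_factory()
        a1 = predict_survival(fit, BASE, history([20, 25]), t=3.0,
                              u_grid=[30.0], seed=7)
        a2 = predict_survival(fit, BASE, history([20, 25]), t=3.0,
                              u_grid=[30.0], seed=7)
        assert a1.pi[0] == a2.pi[0]
        assert (a1.band_lo[0], a1.band_hi[0]) == (a2.band_lo[0], a2.band_hi[0])


class TestRanking:
    def _cohort(self, values_by_pid, gamma_names=()):
        base = pd.DataFrame([{"patient_id": pid, "listing_day": 0.0,
                              **{g: 0.0 for g in gamma_names}}
                             for pid in values_by_pid])
        lng = pd.concat([history(v, pid=pid) for pid, v in values_by_pid.items()],
                        ignore_index=True)
        return base, lng

    def test_higher_meldna_ranked_first(self, toy_fit_factory):
        fit = toy_fit_factory()
        base, lng = self._cohort({"a": [20, 20, 20], "b": [30, 30, 30]})
        order = rank_by_mortality(fit, base, lng, t=6.0, horizon=28.0)
        assert order == ["b", "a"]

    def test_steep_riser_outranks_high_flat_under_slope_dominant_model(
            self, toy_fit_factory):
        """Value-30-and-flat vs value-20-and-climbing: with a strong slope
        association the accelerating patient carries the greater risk."""
        fit = toy_fit_factory(alpha_value=0.05, alpha_slope=20.0)
        times = np.linspace(0, 20, 6)
        base = pd.DataFrame([{"patient_id": p, "listing_day": 0.0}
                             for p in ("A", "C")])
        lng = pd.concat([
            history([30.0] * 6, times=times, pid="A"),
            history(20 + 0.75 * times, times=times, pid="C")],
            ignore_index=True)
        order = rank_by_mortality(fit, base, lng, t=20.0, horizon=28.0)
        assert order == ["C", "A"]

    def test_ranking_matches_risk_score_ordering(self, toy_fit_factory):
        fit = toy_fit_factory(alpha_value=0.2, alpha_slope=2.0)
        rng = np.random.default_rng(9)
        vals = {f"p{i}": rng.uniform(10, 38, 4) for i in range(12)}
        base, lng = self._cohort(vals)
        order = rank_by_mortality(fit, base, lng, t=9.0, horizon=28.0)
        pred = PlugInPredictor(fit, base, lng)
        pi = pred.survival(9.0, 28.0)
        assert order == list(pi.sort_values().index)

    def test_empty_cohort_gives_empty_ranking(self, toy_fit_factory):
        fit = toy_fit_factory()
        base = pd.DataFrame(columns=["patient_id", "listing_day"])
        lng = pd.DataFrame(columns=["patient_id", "t", "meld_na"])
        assert rank_by_mortality(fit, base, lng, 0.0, 28.0) == []


class TestPlugInPredictor:
    def test_modes_update_only_at_measurements(self, toy_fit_factory):
        fit = toy_fit_factory()
        base = pd.DataFrame([{"patient_id": "a", "listing_day": 0.0}])
        lng = history([20, 30], times=[0.0, 10.0], pid="a")
        pred = PlugInPredictor(fit, base, lng)
        m5 = pred.eb_modes_at(5.0)
        m9 = pred.eb_modes_at(9.0)
        m11 = pred.eb_modes_at(11.0)
        np.testing.assert_allclose(m5, m9)
        assert not np.allclose(m9, m11)

    def test_matrix_agrees_with_single_calls(self, toy_fit_factory):
        fit = toy_fit_factory(alpha_value=0.1, alpha_slope=1.0)
        rng = np.random.default_rng(10)
        base = pd.DataFrame([{"patient_id": f"p{i}", "listing_day": 0.0}
                             for i in range(5)])
        lng = pd.concat([history(rng.uniform(10, 35, 4), pid=f"p{i}")
                         for i in range(5)], ignore_index=True)
        pred = PlugInPredictor(fit, base, lng)
        times = np.array([1.0, 5.0, 11.0])
        mat = pred.survival_matrix(times, 28.0)
        for k, tau in enumerate(times):
            np.testing.assert_allclose(mat[:, k],
                                       pred.survival(tau, 28.0).to_numpy())
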