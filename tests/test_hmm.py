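"""Emission densities, transition model, likelihood (vs path-enumeration
oracle), decoding, stationary distributions and derived bias statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import icebear as ib
from icebear.hmm import (EmissionParams, HMMSpec, TransitionModel,
                         attraction_angle, emission_logdensity,
                         emission_logmatrix, fit_hmm, forward_loglik,
                         forward_loglik_matrices, gamma_logpdf_meansd,
                         scaled_attraction, stationary_distribution,
                         stationary_with_ci, step_mean,
                         transition_matrices, transition_matrix, turn_mean,
                         viterbi, vonmises_logpdf, D, ARS, OL, OR)
from icebear.preprocess import StepSeries
from conftest import make_truth_spec, simulate_annotated

# ---------------------------------------------------------------------------
# oracles


def brute_force_loglik(logB, Gammas, delta):
    """Log-likelihood by explicit summation over all state paths."""
    T, N = logB.shape
    total = -np.inf
    for path in itertools.product(range(N), repeat=T):
        lp = np.log(delta[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(Gammas[t, path[t - 1], path[t]]) + logB[t, path[t]]
        total = np.logaddexp(total, lp)
    return total


def brute_force_viterbi(logB, Gammas, delta):
    """Most likely path by exhaustive enumeration."""
    T, N = logB.shape
    best, arg = -np.inf, None
    for path in itertools.product(range(N), repeat=T):
        lp = np.log(delta[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(Gammas[t, path[t - 1], path[t]]) + logB[t, path[t]]
        if lp > best:
            best, arg = lp, path
    return np.array(arg)


def random_spec(rng):
    mu = np.sort(rng.uniform(0.2, 3.0, 3))
    mu += np.array([0.0, 0.05, 0.1])
    em = EmissionParams(mu_step=mu, sigma_step=rng.uniform(0.2, 1.0, 3),
                        kappa=rng.uniform(0.3, 5.0, 3),
                        beta_tide=rng.normal(0, 0.3),
                        alpha1_drift=rng.normal(0, 1.0),
                        alpha1_olf=rng.normal(0, 0.3),
                        alpha2_olf=rng.normal(0, 0.3))
    tm = TransitionModel()
    tm.coef[:, 0] = rng.normal(-1.0, 0.8, 7)
    return HMMSpec(em, tm)


def random_series(rng, T):
    turn = rng.uniform(-np.pi, np.pi, T)
    turn[0] = np.nan
    df = pd.DataFrame({
        "speed_kmh": rng.gamma(2.0, 0.5, T) + 0.05,
        "turn_rad": turn,
        "psi_wind": rng.uniform(-np.pi, np.pi, T),
        "psi_tide": rng.uniform(-np.pi, np.pi, T),
        "r_tide": rng.uniform(0.0, 0.6, T),
    })
    return StepSeries("x", df)


def matrices_for(series, spec):
    df = series.data
    logB = emission_logmatrix(df["speed_kmh"].to_numpy(),
                              df["turn_rad"].to_numpy(),
                              df["psi_wind"].to_numpy(),
                              df["psi_tide"].to_numpy(),
                              df["r_tide"].to_numpy(), spec.emission)
    X = spec.transition.design(df)
    Gammas = transition_matrices(X, spec.transition.coef)
    delta = stationary_distribution(Gammas[0])
    return logB, Gammas, delta


# ---------------------------------------------------------------------------
# emission-case functions


class TestStepMean:
    def test_ars_ignores_tide(self):
        p = make_truth_spec().emission
        assert float(step_mean(ARS, 5.0, p)) == pytest.approx(0.76)

    def test_drift_without_tide_is_intercept(self):
        p = make_truth_spec().emission
        assert float(step_mean(D, 0.0, p)) == pytest.approx(0.5)

    def test_drift_tidal_slope_arithmetic(self):
        p = EmissionParams(mu_step=np.array([0.5, 0.76, 2.04]),
                           sigma_step=np.array([0.31, 0.59, 0.93]),
                           kappa=np.array([1.0, 1.0, 1.0]), beta_tide=0.45)
        assert float(step_mean(D, 0.29, p)) == pytest.approx(0.6305)


class TestTurnMean:
    def test_ars_is_zero_always(self):
        p = make_truth_spec().emission
        rng = np.random.default_rng(0)
        out = turn_mean(ARS, rng.uniform(-np.pi, np.pi, 100),
                        rng.uniform(-np.pi, np.pi, 100),
                        rng.uniform(0, 1, 100), p)
        assert np.all(out == 0.0)

    def test_drift_without_tide_is_pure_persistence(self):
        p = make_truth_spec().emission
        assert float(turn_mean(D, 0.3, 1.2, 0.0, p)) == 0.0

    def test_left_right_mirror_property(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = make_truth_spec().emission
            p.alpha1_olf = rng.normal(0, 0.5)
            p.alpha2_olf = rng.normal(0, 0.5)
            psi = rng.uniform(-np.pi, np.pi)
            left = float(turn_mean(OL, psi, 0.0, 0.0, p))
            right = float(turn_mean(OR, -psi, 0.0, 0.0, p))
            assert left == pytest.approx(-right, abs=1e-12)


class TestEmissionDensity:
    def test_gamma_mean_sd_reduces_to_exponential_at_mu_eq_sigma(self):
        mu = 0.8
        l = np.array([0.1, 0.5, 1.3, 4.0])
        expect = -np.log(mu) - l / mu
        assert np.allclose(gamma_logpdf_meansd(l, mu, mu), expect)

    def test_vonmises_uniform_limit(self):
        lp = vonmises_logpdf(np.array([-3.0, 0.0, 2.0]), 1.0, 1e-12)
        assert np.allclose(lp, -np.log(2 * np.pi))

    def test_density_integrates_to_one(self):
        spec = make_truth_spec()
        cov = {"psi_wind": 0.7, "psi_tide": -1.2, "r_tide": 0.29}
        for state in (D, ARS, OL, OR):
            Il, _ = quad(lambda l: np.exp(
                emission_logdensity(l, None, state, cov, spec)), 0, np.inf)
            phi = np.linspace(-np.pi, np.pi, 20001)
            p = spec.emission
            g = {D: 0, ARS: 1, OL: 2, OR: 2}[state]
            mphi = turn_mean(state, cov["psi_wind"], cov["psi_tide"],
                             cov["r_tide"], p)
            Ip = np.trapezoid(np.exp(vonmises_logpdf(phi, mphi, p.kappa[g])),
                              phi)
            assert Il * Ip == pytest.approx(1.0, abs=1e-6)


class TestTransitionMatrix:
    def test_zero_coefficients_give_uniform_quarter(self):
        tm = TransitionModel()
        G = transition_matrix({}, tm)
        assert np.allclose(G, 0.25)

    def test_single_log3_offdiagonal(self):
        tm = TransitionModel()
        tm.coef[0, 0] = np.log(3.0)  # D->ARS slot
        G = transition_matrix({}, tm)
        assert G[0, 1] == pytest.approx(3.0 / 6.0)
        assert G[0, 0] == pytest.approx(1.0 / 6.0)
        assert G[0, 2] == pytest.approx(1.0 / 6.0)

    def test_rows_sum_to_one_random(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(300), rng.normal(size=300)])
        coef = rng.normal(0, 2, (7, 2))
        G = transition_matrices(X, coef)
        assert np.allclose(G.sum(axis=-1), 1.0)
        assert np.all(G >= 0)

    def test_olfactory_states_share_rows_and_columns(self):
        rng = np.random.default_rng(3)
        tm = TransitionModel()
        tm.coef[:, 0] = rng.normal(size=7)
        G = transition_matrix({}, tm)
        assert np.allclose(G[OL, [D, ARS]], G[OR, [D, ARS]])
        assert G[D, OL] == pytest.approx(G[D, OR])
        assert G[OL, OR] == pytest.approx(G[OR, OL])


# ---------------------------------------------------------------------------
# likelihood and decoding vs enumeration


class TestForwardAgainstEnumeration:
    def test_forward_equals_path_sum_and_viterbi_equals_argmax(self):
        rng = np.random.default_rng(42)
        for _ in range(10):  # the acceptance suite runs 50
            T = int(rng.integers(4, 7))
            spec = random_spec(rng)
            series = random_series(rng, T)
            logB, Gammas, delta = matrices_for(series, spec)
            ll = forward_loglik(series, spec)
            assert ll == pytest.approx(brute_force_loglik(logB, Gammas,
                                                          delta), abs=1e-8)
            path = viterbi(series, spec)
            assert np.array_equal(path, brute_force_viterbi(logB, Gammas,
                                                            delta))

    def test_label_swap_with_alpha2_flip_preserves_loglik(self):
        rng = np.random.default_rng(5)
        spec = random_spec(rng)
        series = random_series(rng, 60)
        ll = forward_loglik(series, spec)
        flipped = make_truth_spec()
        flipped.emission.__dict__.update(spec.emission.__dict__)
        flipped.emission.alpha2_olf = -spec.emission.alpha2_olf
        flipped.transition.coef = spec.transition.coef.copy()
        assert forward_loglik(series, flipped) == pytest.approx(ll,
                                                                abs=1e-9)

    def test_single_state_collapse_is_sum_of_emissions(self):
        rng = np.random.default_rng(6)
        T = 40
        logB = rng.normal(-1, 1, (T, 1))
        Gammas = np.ones((T, 1, 1))
        ll = forward_loglik_matrices(logB, Gammas, np.ones(1))
        assert ll == pytest.approx(logB.sum(), abs=1e-10)


class TestViterbi:
    def test_single_state_constant_path(self):
        rng = np.random.default_rng(7)
        spec = make_truth_spec()
        spec.transition.coef[:, 0] = -40.0  # effectively absorbing
        series = random_series(rng, 30)
        path = viterbi(series, spec)
        assert len(set(path.tolist())) == 1

    def test_well_separated_emissions_recover_truth(self, wind_field,
                                                    tide_field):
        em = EmissionParams(mu_step=np.array([0.05, 0.8, 12.0]),
                            sigma_step=np.array([0.02, 0.2, 2.0]),
                            kappa=np.array([8.0, 8.0, 8.0]),
                            alpha1_olf=0.3, alpha2_olf=0.5)
        tm = TransitionModel()
        tm.coef[:, 0] = -1.5
        spec = HMMSpec(em, tm)
        series, truths = simulate_annotated(spec, wind_field, tide_field,
                                            n_tracks=1, T=400, seed0=900)
        path = viterbi(series[0], spec)
        truth = truths[0].data["state"].to_numpy()
        merged_path = np.where(path >= 2, 2, path)
        merged_truth = np.where(truth >= 2, 2, truth)
        assert (merged_path == merged_truth).mean() >= 0.99


# ---------------------------------------------------------------------------
# stationary distribution


class TestStationary:
    def test_uniform_matrix(self):
        pi = stationary_distribution(np.full((4, 4), 0.25))
        assert np.allclose(pi, 0.25)

    def test_two_state_closed_form(self):
        G = np.array([[0.9, 0.1], [0.3, 0.7]])
        pi = stationary_distribution(G)
        assert pi[0] == pytest.approx(0.75)

    def test_fixed_point_property_random(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            G = rng.gamma(1.0, 1.0, (4, 4)) + 1e-3
            G /= G.sum(axis=1, keepdims=True)
            pi = stationary_distribution(G)
            assert np.max(np.abs(pi @ G - pi)) < 1e-10
            assert pi.sum() == pytest.approx(1.0)

    def test_ci_grid_is_coherent(self, base_fit):
        grid = pd.DataFrame({"r_tide": [0.29]})
        out = stationary_with_ci(base_fit, grid)
        assert out["prob"].sum() == pytest.approx(1.0)
        assert ((out["lo"] <= out["prob"]) & (out["prob"] <= out["hi"])).all()
        assert (out["hi"] - out["lo"]).between(0, 1).all()


# ---------------------------------------------------------------------------
# derived statistics


class TestAttractionStatistics:
    def test_reported_olfactory_bias_values(self):
        # the fitted olfactory coefficients: alpha1=-0.011, alpha2=0.303
        assert round(scaled_attraction(-0.011, 0.303), 3) == 0.233
        assert round(attraction_angle(-0.011, 0.303, degrees=True)) == 92

    def test_limits_and_simple_points(self):
        assert scaled_attraction(0.0, 0.0) == 0.0
        assert scaled_attraction(1.0, 0.0) == pytest.approx(0.5)
        assert attraction_angle(1.0, 0.0, degrees=True) == 0.0
        assert attraction_angle(0.0, 1.0, degrees=True) == pytest.approx(90.0)
        with pytest.raises(ValueError):
            attraction_angle(0.0, 0.0)

    def test_monotone_in_bias_magnitude(self):
        mags = [scaled_attraction(a, 0.1) for a in np.linspace(0, 5, 20)]
        assert np.all(np.diff(mags) > 0)
        assert all(0 <= m < 1 for m in mags)


# ---------------------------------------------------------------------------
# fitting behaviour


class TestFitting:
    def test_ordering_constraint_holds_at_optimum(self, base_fit):
        mu = base_fit.spec.emission.mu_step
        assert mu[0] < mu[1] < mu[2]

    def test_recovery_on_modest_data(self, base_fit, truth_spec):
        e, t = base_fit.spec.emission, truth_spec.emission
        # modest data (4 x 400 steps): generous bands; the acceptance suite
        # checks the full-size recovery at tight tolerances
        mu_fit_d = e.mu_step[0] + e.beta_tide * 0.29
        assert mu_fit_d == pytest.approx(0.6305, rel=0.10)
        assert e.mu_step[1] == pytest.approx(t.mu_step[1], rel=0.10)
        assert e.mu_step[2] == pytest.approx(t.mu_step[2], rel=0.10)
        assert e.alpha2_olf == pytest.approx(t.alpha2_olf, abs=0.12)

    def test_aic_consistent_with_loglik(self, base_fit):
        assert base_fit.aic == pytest.approx(
            2 * base_fit.n_params - 2 * base_fit.loglik)

    def test_recovery_error_shrinks_with_track_length(self, wind_field,
                                                      tide_field,
                                                      truth_spec):
        def err_at(T, seed0):
            series, _ = simulate_annotated(truth_spec, wind_field, tide_field,
                                           n_tracks=1, T=T, seed0=seed0)
            f = fit_hmm(series, n_restarts=1, compute_hessian=False)
            e = f.spec.emission
            t = truth_spec.emission
            return np.abs(e.mu_step / t.mu_step - 1.0).sum() + \
                np.abs(e.sigma_step / t.sigma_step - 1.0).sum()

        small = err_at(300, 300)
        large = err_at(3000, 301)
        assert large < small * 1.2 + 0.05

    def test_multistart_is_stable(self, wind_field, tide_field, truth_spec):
        series, _ = simulate_annotated(truth_spec, wind_field, tide_field,
                                       n_tracks=2, T=250, seed0=500)
        f1 = fit_hmm(series, n_restarts=4, seed=1, compute_hessian=False)
        f2 = fit_hmm(series, n_restarts=4, seed=2, compute_hessian=False)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-3)


class TestDecode:
    def test_decode_appends_state_columns(self, sim_dataset, base_fit):
        from icebear.hmm import decode
        series, _ = sim_dataset
        out = decode(series[0], base_fit)
        assert np.array_equal(out.data["state"].to_numpy(),
                              viterbi(series[0], base_fit))
        assert set(out.data["state_name"]) <= {"D", "ARS", "OL", "OR"}
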