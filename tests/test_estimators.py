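"""Recovery, exactness and invariance properties of the estimators."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vfalin.data import SignalSet, VFASample, read_table, write_table
from vfalin.estimators import (batch_fit_line, conventional_fit,
                               dual_angle_fit, fit_line, multi_tr_fit,
                               nonlinear_fit_oracle)
from vfalin.exceptions import DegenerateFitError, InsufficientDataError
from vfalin.signal_model import algebraic_signal
from vfalin.simulate import agar_phantom, generate_vfa_signals, protocol_preset
from vfalin.transforms import (alpha_from_tau, rho1_from_relaxation,
                               tau_from_alpha)


def model_set(amplitude, rho1, alphas, tr):
    s = algebraic_signal(amplitude, tau_from_alpha(np.asarray(alphas, float)), rho1)
    return SignalSet(np.asarray(alphas, float), tr, s)


@pytest.mark.parametrize("estimator", [fit_line, conventional_fit, nonlinear_fit_oracle])
@pytest.mark.parametrize(
    "amplitude, rho1, alphas",
    [
        (1.0, 0.5, [10, 30, 53, 90, 140]),
        (3.2, 0.02, [2, 4, 7, 11, 15]),
        (0.7, 1.5, [20, 60, 100, 160]),
    ],
)
def test_noiseless_recovery_is_exact(estimator, amplitude, rho1, alphas):
    res = estimator(model_set(amplitude, rho1, alphas, 0.01))
    tol = 1e-6 if estimator is nonlinear_fit_oracle else 1e-10
    assert res.amplitude == pytest.approx(amplitude, rel=tol)
    assert res.rho1 == pytest.approx(rho1, rel=tol)


def test_short_t1_protocol_recovery():
    # MnCl2-like: T1 = 0.54 s, TR = 7 ms, 13 angles between 2 and 36 degrees
    tr, alphas = protocol_preset("exp3")
    rho1 = rho1_from_relaxation(tr, 0.54)
    res = fit_line(model_set(1.0, rho1, alphas, tr))
    assert res.t1 == pytest.approx(0.54, rel=1e-8)
    assert res.n_used == 13


def test_dual_angle_closed_form_at_optimal_ratios():
    # at u = tau/tau_E of (0.4142, 2.4142) both signals equal 0.35355*A
    rho1 = 0.5
    tau_e = 1.0
    u = np.array([np.sqrt(2) - 1, np.sqrt(2) + 1])
    alphas = alpha_from_tau(u * tau_e)
    s = algebraic_signal(1.0, u * tau_e, rho1)
    assert s == pytest.approx([0.35355, 0.35355], abs=1e-5)
    s1 = VFASample(alphas[0], 0.01, s[0])
    s2 = VFASample(alphas[1], 0.01, s[1])
    res = dual_angle_fit(s1, s2)
    assert res.rho1 == pytest.approx(0.5, rel=1e-12)
    assert res.amplitude == pytest.approx(1.0, rel=1e-12)
    # identical to the generic regression on the pair, and symmetric in order
    pair = fit_line(SignalSet.from_samples([s1, s2]))
    swapped = dual_angle_fit(s2, s1)
    assert res.rho1 == pair.rho1 and res.amplitude == pair.amplitude
    assert res.rho1 == swapped.rho1 and res.amplitude == swapped.amplitude


def test_monte_carlo_mean_matches_second_order_bias(rng):
    """The estimator mean equals truth plus the delta-method O(sigma^2) bias.

    The closed-form rho1 = -1/(2*slope) is a smooth nonlinear function of the
    signals, so its mean carries a second-order bias 0.5*sigma^2*sum of
    second partials; the Monte-Carlo mean must match that prediction (and
    the bias itself is small, ~0.1% of rho1 at sigma/A = 0.005).
    """
    amplitude, rho1, tr = 1.0, 0.5, 0.05
    alphas = np.array([15.0, 30.0, 53.0, 80.0, 110.0])
    tau = tau_from_alpha(alphas)
    s0 = algebraic_signal(amplitude, tau, rho1)
    sigma = 0.005

    def est(sig):
        return fit_line(SignalSet(alphas, tr, sig)).rho1

    bias = 0.0
    for i in range(len(tau)):
        h = 1e-4 * s0[i]
        up, dn = s0.copy(), s0.copy()
        up[i] += h
        dn[i] -= h
        bias += 0.5 * sigma**2 * (est(up) - 2 * est(s0) + est(dn)) / h**2
    assert abs(bias) < 0.002 * rho1

    reps = rng.normal(s0, sigma, size=(30_000, len(tau)))
    out = batch_fit_line(tau, reps, tr=tr)
    ok = out["valid"]
    se = np.std(out["rho1"][ok]) / np.sqrt(ok.sum())
    assert np.mean(out["rho1"][ok]) == pytest.approx(rho1 + bias, abs=3 * se)


def test_batch_matches_scalar_fit():
    ss = model_set(1.3, 0.4, [5, 20, 45, 90], 0.02)
    noisy = ss.signal * (1 + np.array([0.01, -0.02, 0.005, 0.0]))
    res = fit_line(SignalSet(ss.alpha_deg, ss.tr_s, noisy))
    out = batch_fit_line(ss.tau, noisy[None, :], tr=0.02)
    assert out["rho1"][0] == pytest.approx(res.rho1, rel=1e-12)
    assert out["amplitude"][0] == pytest.approx(res.amplitude, rel=1e-12)
    assert out["t1"][0] == pytest.approx(res.t1, rel=1e-12)


class TestMultiTR:
    def test_pooled_long_t1_phantom(self):
        # agar at TR 6/12/24/48 ms pooled into one regression
        phantom = agar_phantom()
        parts = [
            generate_vfa_signals(phantom, angles, tr)
            for tr, angles in protocol_preset("exp1")
        ]
        ss = SignalSet(
            np.concatenate([p.alpha_deg for p in parts]),
            np.concatenate([p.tr_s for p in parts]),
            np.concatenate([p.signal for p in parts]),
        )
        res = multi_tr_fit(ss)
        assert res.t1 == pytest.approx(2.41, rel=5e-4)
        assert res.tr_s is None and np.isnan(res.rho1)

    def test_single_tr_short_tr_approximation_error(self):
        # pooled mode differs from the exact fit by (TR/T1)^2/12 relative
        t1, tr = 1.0, 0.1
        rho1 = rho1_from_relaxation(tr, t1)
        ss = model_set(1.0, rho1, [4, 10, 18, 30], tr)
        res = multi_tr_fit(ss)
        x = tr / t1
        assert (res.t1 - t1) / t1 == pytest.approx(x * x / 12.0, rel=0.01)

    def test_bias_vanishes_quadratically_in_tr(self):
        t1 = 2.0
        errs = []
        for tr in (0.02, 0.04, 0.08):
            rho1 = rho1_from_relaxation(tr, t1)
            res = multi_tr_fit(model_set(1.0, rho1, [3, 8, 15, 25], tr))
            errs.append(abs(res.t1 - t1) / t1)
        assert errs[1] / errs[0] == pytest.approx(4.0, rel=0.1)
        assert errs[2] / errs[1] == pytest.approx(4.0, rel=0.1)

    def test_tr_scaling_consistency(self):
        t1 = 1.5
        for c in (1.0, 2.5):
            tr = 0.008 * c
            rho1 = rho1_from_relaxation(tr, t1)
            res = multi_tr_fit(model_set(1.0, rho1, [3, 7, 12, 20], tr))
            assert res.t1 == pytest.approx(t1, rel=1e-4)

    def test_warns_outside_short_tr_regime(self):
        t1 = 0.1
        tr = 0.05
        rho1 = rho1_from_relaxation(tr, t1)
        with pytest.warns(UserWarning, match="short-TR"):
            multi_tr_fit(model_set(1.0, rho1, [10, 30, 60, 100], tr))


class TestConventional:
    def test_slope_is_e1_intercept_a_times_one_minus_e1(self):
        tr = -np.log(0.6) * 1.0  # choose TR so that E1 = 0.6 at T1 = 1 s
        rho1 = rho1_from_relaxation(tr, 1.0)
        res = conventional_fit(model_set(1.0, rho1, [10, 25, 45, 70], tr))
        assert res.e1 == pytest.approx(0.6, rel=1e-10)
        assert res.amplitude * (1 - res.e1) == pytest.approx(0.4, rel=1e-9)

    def test_agrees_with_linear_form_on_model_data(self):
        ss = model_set(2.0, 0.3, [8, 20, 40, 70, 120], 0.015)
        r1 = fit_line(ss)
        r2 = conventional_fit(ss)
        assert r1.amplitude == pytest.approx(r2.amplitude, rel=1e-9)
        assert r1.t1 == pytest.approx(r2.t1, rel=1e-9)

    def test_fully_relaxed_limit(self):
        # E1 -> 0: slope -> 0, intercept -> A
        tr = 20.0
        rho1 = rho1_from_relaxation(tr, 1.0)  # TR >> T1
        res = conventional_fit(model_set(1.0, rho1, [20, 50, 80], tr))
        assert res.e1 == pytest.approx(np.exp(-20.0), abs=1e-6)
        assert res.amplitude == pytest.approx(1.0, rel=1e-6)


@given(st.floats(0.1, 50.0))
def test_scale_equivariance(c):
    ss = model_set(1.0, 0.5, [10, 30, 60, 100], 0.01)
    scaled = SignalSet(ss.alpha_deg, ss.tr_s, ss.signal * c)
    r0, r1 = fit_line(ss), fit_line(scaled)
    assert r1.amplitude == pytest.approx(c * r0.amplitude, rel=1e-10)
    assert r1.rho1 == pytest.approx(r0.rho1, rel=1e-10)


def test_permutation_invariance(rng):
    ss = model_set(1.0, 0.5, [10, 25, 40, 60, 90, 130], 0.01)
    noisy = ss.signal + rng.normal(0, 0.01, len(ss))
    perm = rng.permutation(len(ss))
    r0 = fit_line(SignalSet(ss.alpha_deg, ss.tr_s, noisy))
    r1 = fit_line(SignalSet(ss.alpha_deg[perm], ss.tr_s[perm], noisy[perm]))
    assert r1.rho1 == pytest.approx(r0.rho1, rel=1e-12)
    assert r1.amplitude == pytest.approx(r0.amplitude, rel=1e-12)


def test_model_weights_cannot_move_an_exact_line():
    ss = model_set(1.0, 0.7, [10, 30, 55, 85, 120], 0.01)
    r_plain = fit_line(ss)
    r_weighted = fit_line(ss, weights="model")
    assert r_weighted.rho1 == pytest.approx(r_plain.rho1, rel=1e-10)
    assert r_weighted.amplitude == pytest.approx(r_plain.amplitude, rel=1e-10)


def test_replicated_angles_are_legal():
    ss = model_set(1.0, 0.5, [20, 20, 60, 60], 0.01)
    res = fit_line(ss)
    assert res.rho1 == pytest.approx(0.5, rel=1e-10)


class TestOracle:
    def test_truth_start_converges_immediately(self):
        ss = model_set(1.0, 0.5, [10, 30, 60], 0.01)
        res = nonlinear_fit_oracle(ss, init=(1.0, 0.5))
        assert res.converged
        assert res.n_iter <= 5

    def test_noisy_efficiency_matches_weighted_linear_estimator(self, rng):
        """Signal-space least squares and the weighted linear fit agree.

        The Levenberg-Marquardt fit is maximum likelihood for Gaussian
        signal noise; to first order the linear fit matches it once the
        correlated-error weights cancel the tau-dependent residual scale
        (the unweighted fit is less efficient on designs spanning a wide
        tau range, here by ~20%).
        """
        amplitude, rho1, tr = 1.0, 0.5, 0.05
        alphas = np.array([15.0, 35.0, 53.0, 75.0, 105.0])
        tau = tau_from_alpha(alphas)
        s0 = algebraic_signal(amplitude, tau, rho1)
        reps = np.clip(rng.normal(s0, 0.01, size=(1500, len(tau))), 0.0, None)
        wl = np.array([
            fit_line(SignalSet(alphas, tr, r), weights="model").rho1 for r in reps
        ])
        nl = np.array([
            nonlinear_fit_oracle(SignalSet(alphas, tr, r)).rho1 for r in reps
        ])
        ok = np.isfinite(wl) & np.isfinite(nl)
        ratio = np.var(nl[ok]) / np.var(wl[ok])
        assert ratio == pytest.approx(1.0, abs=0.1)
        # and per-replicate estimates track each other closely
        assert np.corrcoef(wl[ok], nl[ok])[0, 1] > 0.99


class TestErrorsAndIO:
    def test_mixed_tr_directs_to_multi_tr(self):
        ss = SignalSet([10.0, 30.0], [0.01, 0.02], [0.1, 0.2])
        with pytest.raises(ValueError, match="multi_tr_fit"):
            fit_line(ss)

    def test_insufficient_distinct_angles(self):
        with pytest.raises(InsufficientDataError):
            fit_line(SignalSet([20.0, 20.0], 0.01, [0.1, 0.1]))

    def test_positive_slope_is_degenerate(self):
        # increasing y with x cannot arise from any physical relaxation term
        ss = SignalSet([10.0, 30.0, 60.0], 0.01, [0.01, 0.2, 1.5])
        with pytest.raises(DegenerateFitError):
            fit_line(ss)

    def test_nonpositive_signals_excluded_not_fatal(self, caplog):
        ss = model_set(1.0, 0.5, [10, 30, 60, 100], 0.01)
        sig = ss.signal.copy()
        sig[0] = 0.0
        with caplog.at_level("WARNING", logger="vfalin"):
            res = fit_line(SignalSet(ss.alpha_deg, ss.tr_s, sig))
        assert res.n_used == 3
        assert not res.included[0]
        assert "non-positive" in caplog.text

    def test_table_round_trip(self, tmp_path):
        ss = model_set(1.0, 0.5, [10, 30, 60], 0.01)
        path = tmp_path / "vfa.tsv"
        write_table(ss, path)
        back = read_table(path)
        assert np.allclose(back.signal, ss.signal)
        assert np.allclose(back.alpha_deg, ss.alpha_deg)

    def test_table_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("alpha_deg,signal\n10,0.1\n")
        with pytest.raises(ValueError, match="tr_s"):
            read_table(path)
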