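"""FCS model evaluation, fitting, correlator and diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quenchcal import synthetic as syn
from quenchcal.fcs import (
    CorrelationCurve,
    FCSModel,
    detect_extra_relaxation,
    fcs_eval,
    fit_fcs,
    global_fit_fcs,
    multiple_tau_autocorrelate,
    particle_number,
    triplet_power_trend,
)


class TestModelEvaluation:
    def test_zero_lag_limit(self):
        m = FCSModel(g0=0.1, tau_d_ms=0.24, triplet_fraction=0.2, tau_t_us=7.0)
        g = fcs_eval(m, np.array([1e-18]))
        assert g[0] == pytest.approx(0.1 / (1 - 0.2), rel=1e-12)

    def test_half_amplitude_at_diffusion_time(self):
        # with no triplet and s -> infinity the lateral factor alone remains
        m = FCSModel(g0=0.1, tau_d_ms=0.24, s=1e6, triplet_fraction=0.0)
        g = fcs_eval(m, np.array([0.24e-3]))
        assert g[0] == pytest.approx(0.05, rel=1e-6)

    def test_long_lag_limit_vanishes(self):
        m = syn.paper_fcs_model()
        assert fcs_eval(m, np.array([1e3]))[0] < 1e-6

    def test_monotone_non_increasing(self):
        m = FCSModel(g0=0.2, tau_d_ms=0.5, s=3.0,
                     triplet_fraction=0.3, tau_t_us=12.0)
        g = fcs_eval(m, np.geomspace(1e-9, 10.0, 2000))
        assert np.all(np.diff(g) <= 1e-15)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            FCSModel(g0=-0.1, tau_d_ms=0.24)
        with pytest.raises(ValueError):
            FCSModel(g0=0.1, tau_d_ms=0.24, triplet_fraction=1.0)
        with pytest.raises(ValueError):
            FCSModel(g0=0.1, tau_d_ms=0.24, s=0.5)


class TestFitting:
    def test_noiseless_round_trip(self):
        truth = FCSModel(g0=0.1, tau_d_ms=0.24, triplet_fraction=0.2, tau_t_us=7.0)
        curve = syn.generate_fcs_curve(truth, noise=0.0, seed=0).curve
        fit = fit_fcs(curve)
        assert fit.model.g0 == pytest.approx(0.1, rel=0.005)
        assert fit.model.tau_d_ms == pytest.approx(0.24, rel=0.005)
        assert fit.model.triplet_fraction == pytest.approx(0.2, abs=0.002)
        assert fit.model.tau_t_us == pytest.approx(7.0, rel=0.005)

    def test_pure_diffusion_gives_zero_triplet(self):
        truth = FCSModel(g0=0.1, tau_d_ms=0.24, triplet_fraction=0.0)
        curve = syn.generate_fcs_curve(truth, noise=0.0, seed=0).curve
        fit = fit_fcs(curve)
        assert fit.model.triplet_fraction < 1e-3

    @given(g0=st.floats(0.01, 1.0), tau_d=st.floats(0.05, 2.0),
           t=st.floats(0.0, 0.4), tau_t=st.floats(2.0, 30.0))
    @settings(derandomize=True, max_examples=15, deadline=None)
    def test_fit_eval_identity_over_parameter_space(self, g0, tau_d, t, tau_t):
        """Fitting noiseless model output recovers the generating
        parameters across random valid draws."""
        truth = FCSModel(g0=g0, tau_d_ms=tau_d, triplet_fraction=t, tau_t_us=tau_t)
        curve = CorrelationCurve(syn.default_lag_grid(), fcs_eval(
            truth, syn.default_lag_grid()))
        fit = fit_fcs(curve)
        assert fit.model.g0 == pytest.approx(g0, rel=0.02)
        assert fit.model.tau_d_ms == pytest.approx(tau_d, rel=0.02)

    def test_noisy_diffusion_time_recovery(self):
        truth = syn.paper_fcs_model()
        errs = []
        for seed in range(30):
            curve = syn.generate_fcs_curve(truth, noise=0.05, seed=seed).curve
            errs.append(abs(fit_fcs(curve).model.tau_d_ms / 0.24 - 1))
        assert np.median(errs) < 0.10

    def test_global_fit_shares_diffusion_time(self):
        curves = [
            syn.generate_fcs_curve(syn.paper_fcs_model(g0=g0), noise=0.02,
                                   seed=i).curve
            for i, g0 in enumerate((0.05, 0.1, 0.2))
        ]
        results = global_fit_fcs(curves)
        tau_ds = {r.model.tau_d_ms for r in results}
        assert len(tau_ds) == 1
        assert results[0].model.tau_d_ms == pytest.approx(0.24, rel=0.05)
        g0s = [r.model.g0 for r in results]
        assert g0s[0] < g0s[1] < g0s[2]

    def test_global_single_curve_equals_single_fit(self):
        curve = syn.generate_fcs_curve(syn.paper_fcs_model(), noise=0.01,
                                       seed=7).curve
        single = fit_fcs(curve)
        glob = global_fit_fcs([curve])[0]
        assert glob.model.tau_d_ms == pytest.approx(single.model.tau_d_ms,
                                                    rel=1e-6)

    def test_global_order_invariance(self):
        curves = [
            syn.generate_fcs_curve(syn.paper_fcs_model(g0=g0), noise=0.02,
                                   seed=50 + i).curve
            for i, g0 in enumerate((0.05, 0.1, 0.2))
        ]
        fwd = global_fit_fcs(curves)[0].model.tau_d_ms
        rev = global_fit_fcs(curves[::-1])[0].model.tau_d_ms
        assert fwd == pytest.approx(rev, rel=1e-6)



def binned_brute_force(trace, lag_bins, level):
    """Direct O(N^2) correlator evaluated on the level-times-halved trace,
    with the same symmetric normalisation the multiple-tau estimator uses."""
    cur = trace.astype(float)
    for _ in range(level):
        n_even = (cur.size // 2) * 2
        cur = cur[:n_even].reshape(-1, 2).mean(axis=1)
    left, right = cur[:-lag_bins], cur[lag_bins:]
    return (left * right).mean() / (left.mean() * right.mean()) - 1.0


class TestMultipleTau:
    def test_constant_trace_is_uncorrelated(self):
        curve = multiple_tau_autocorrelate(np.full(4000, 7.0), 1e-3)
        assert np.allclose(curve.g, 0.0, atol=1e-14)

    def test_agrees_with_brute_force_correlator(self):
        """Multiple-tau output equals the O(N^2) direct correlator of the
        correspondingly binned trace at every lag (exact oracle), and tracks
        the native-resolution correlator within binning tolerance for a
        slowly varying signal."""
        rng = np.random.default_rng(1)
        n = 10_000
        trace = rng.poisson(30.0, n).astype(float)
        trace *= 1.0 + 0.4 * np.sin(np.arange(n) / 600.0)
        m = 8
        curve = multiple_tau_autocorrelate(trace, 1e-4, m=m)

        # exact level-wise oracle
        i = 0
        level = 0
        while i < curve.g.size:
            ks = range(1, 2 * m + 1) if level == 0 else range(m + 1, 2 * m + 1)
            for k in ks:
                if i >= curve.g.size:
                    break
                if curve.lags_s[i] != pytest.approx(k * 1e-4 * 2**level):
                    continue
                assert curve.g[i] == pytest.approx(
                    binned_brute_force(trace, k, level), abs=1e-12)
                i += 1
            level += 1

        # approximate agreement with the unbinned direct correlator
        def brute(k):
            left, right = trace[:-k], trace[k:]
            return (left * right).mean() / (left.mean() * right.mean()) - 1.0

        amplitude = np.abs(curve.g).max()
        for i, lag in enumerate(curve.lags_s):
            k = int(round(lag / 1e-4))
            if k >= n // 4:
                break
            assert curve.g[i] == pytest.approx(brute(k), abs=0.05 * amplitude)

    def test_blinking_trace_relaxation_rate(self):
        """Telegraph blinking at rates (k_on, k_off) decays at k_on + k_off;
        the correlator-derived rate lands within 15%."""
        k_on = k_off = 40.0
        gen = syn.generate_blinking_trace(30, k_on, k_off, brightness_hz=5e4,
                                          duration_s=120.0, bin_width_s=5e-4,
                                          seed=3)
        curve = multiple_tau_autocorrelate(gen.intensity, gen.bin_width_s)
        sel = (curve.lags_s >= 1e-3) & (curve.lags_s <= 0.05) & (curve.g > 0)
        rate = -np.polyfit(curve.lags_s[sel], np.log(curve.g[sel]), 1)[0]
        assert rate == pytest.approx(k_on + k_off, rel=0.15)

    def test_zero_mean_trace_rejected(self):
        with pytest.raises(ValueError):
            multiple_tau_autocorrelate(np.zeros(100), 1e-3)


class TestDiagnostics:
    def test_particle_number_values(self):
        n_corr, n_raw = particle_number(FCSModel(g0=0.1, tau_d_ms=0.24))
        assert n_corr == n_raw == pytest.approx(10.0)
        half = particle_number(FCSModel(g0=0.05, tau_d_ms=0.24))[0]
        assert half == pytest.approx(20.0)

    def test_particle_number_triplet_correction(self):
        m = FCSModel(g0=0.1, tau_d_ms=0.24, triplet_fraction=0.25, tau_t_us=7.0)
        n_corr, n_raw = particle_number(m)
        assert n_corr == pytest.approx(7.5)
        assert n_raw == pytest.approx(10.0)

    def test_apparent_particles_drop_with_dark_fraction(self):
        """In the scenario generator shorter constructs have more dark
        (dimerised) molecules, so apparent N decreases 6P -> 0P."""
        config = syn.default_scenario()
        ns = {}
        for construct in config.constructs:
            model = config.fcs_models[construct.label]
            ns[construct.label] = particle_number(model)[0]
        assert ns["0P"] < ns["3P"] < ns["5P"] < ns["6P"]

    def test_extra_relaxation_detected_and_timed(self):
        truth = syn.paper_fcs_model()
        gen = syn.generate_fcs_curve(truth, noise=0.02, seed=8)
        extra = 1.0 + 0.5 * np.exp(-gen.curve.lags_s / 50e-6)
        curve = CorrelationCurve(gen.curve.lags_s, gen.curve.g * extra)
        base = fit_fcs(curve)
        bounds = detect_extra_relaxation(curve, base.model)
        assert bounds.verdict == "detected"
        assert bounds.tau_r_s == pytest.approx(50e-6, rel=0.35)

    def test_no_detection_on_pure_model_and_bounds_reported(self):
        truth = syn.paper_fcs_model()
        curve = syn.generate_fcs_curve(truth, noise=0.02, seed=9).curve
        base = fit_fcs(curve)
        bounds = detect_extra_relaxation(curve, base.model)
        assert bounds.verdict == "fast-or-slow-window"
        assert bounds.fast_bound_s == pytest.approx(100e-9)
        low, high = bounds.slow_window_s
        assert low == pytest.approx(0.24e-3, rel=0.15)
        assert high == pytest.approx(0.3)

    def test_augmented_fit_on_exact_base_data_not_significant(self):
        truth = syn.paper_fcs_model()
        curve = syn.generate_fcs_curve(truth, noise=0.0, seed=0).curve
        bounds = detect_extra_relaxation(curve, fit_fcs(curve).model)
        assert bounds.verdict == "fast-or-slow-window"

    def test_triplet_power_trend_verdicts(self):
        def model(t):
            return FCSModel(g0=0.1, tau_d_ms=0.24, triplet_fraction=t,
                            tau_t_us=7.0)

        tau, p, verdict = triplet_power_trend(
            [(1.0, model(0.05)), (2.0, model(0.15)), (4.0, model(0.30))])
        assert tau == pytest.approx(1.0)
        assert verdict == "triplet-consistent"

        tau0, _, verdict0 = triplet_power_trend(
            [(1.0, model(0.1)), (2.0, model(0.1)), (4.0, model(0.1))])
        assert tau0 == 0.0 and verdict0 == "not-confirmed"

    def test_triplet_trend_with_noise_mostly_confirmed(self):
        rng = np.random.default_rng(12)
        powers = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        t_true = np.array([0.05, 0.10, 0.17, 0.26, 0.35])
        confirmed = 0
        n_rep = 40
        for _ in range(n_rep):
            ts = np.clip(t_true * (1 + 0.10 * rng.normal(size=5)), 0.001, 0.9)
            fits = [(p, FCSModel(g0=0.1, tau_d_ms=0.24, triplet_fraction=t,
                                 tau_t_us=7.0))
                    for p, t in zip(powers, ts)]
            if triplet_power_trend(fits)[2] == "triplet-consistent":
                confirmed += 1
        assert confirmed >= 0.9 * n_rep
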