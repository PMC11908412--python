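"""Reconvolution lifetime fitting, global analysis and amplitude conversions."""

import numpy as np
import pytest

from quenchcal import synthetic as syn
from quenchcal.tcspc import (
    DecayHistogram,
    InstrumentResponse,
    MultiExpModel,
    fit_decay,
    fractional_intensities,
    fractional_populations,
    global_fit,
    reconvolve,
    select_component_count,
)


def delta_irf(n=512, width_ps=50.0):
    vals = np.zeros(n)
    vals[0] = 1.0
    return InstrumentResponse(channel_width_ps=width_ps, values=vals)


class TestReconvolve:
    def test_delta_irf_reproduces_pure_multiexponential(self):
        model = MultiExpModel(amplitudes=[100.0, 10.0], lifetimes=[0.5, 4.0])
        irf = delta_irf()
        t = (np.arange(512) + 0.5) * 0.05
        expected = 100 * np.exp(-t / 0.5) + 10 * np.exp(-t / 4.0)
        assert np.allclose(reconvolve(model, irf), expected, atol=1e-9)

    def test_linear_in_amplitudes(self):
        irf = syn.gaussian_irf(50.0, 512, fwhm_ps=100.0, centre_ns=1.0)
        m1 = MultiExpModel(amplitudes=[50.0], lifetimes=[2.2], background=3.0)
        m2 = MultiExpModel(amplitudes=[100.0], lifetimes=[2.2], background=3.0)
        y1 = reconvolve(m1, irf) - 3.0
        y2 = reconvolve(m2, irf) - 3.0
        assert np.allclose(y2, 2 * y1, rtol=1e-10)

    def test_late_time_log_slope_equals_lifetime(self):
        """After the IRF has decayed the log-slope of the curve is -1/tau."""
        tau = 2.2
        irf = syn.gaussian_irf(25.0, 2048, fwhm_ps=100.0, centre_ns=1.0)
        model = MultiExpModel(amplitudes=[1e5], lifetimes=[tau])
        y = reconvolve(model, irf)
        t = (np.arange(2048) + 0.5) * 0.025
        sel = (t > 5.0) & (t < 20.0)
        slope = np.polyfit(t[sel], np.log(y[sel]), 1)[0]
        assert slope == pytest.approx(-1.0 / tau, rel=0.005)

    def test_total_counts_closed_form(self):
        """Total expected counts match sum_i a_i (tau_i/dt)(1 - e^{-T/tau_i})
        within discretisation error."""
        dt_ns = 0.025
        model = MultiExpModel(amplitudes=[500.0, 80.0], lifetimes=[1.0, 4.0],
                              background=0.2)
        irf = delta_irf(n=4096, width_ps=25.0)
        total = reconvolve(model, irf).sum()
        window = 4096 * dt_ns
        closed = sum(a * (tau / dt_ns) * (1 - np.exp(-window / tau))
                     for a, tau in zip(model.amplitudes, model.lifetimes))
        closed += model.background * 4096
        assert total == pytest.approx(closed, rel=0.01)

    def test_invalid_lifetime_rejected(self):
        with pytest.raises(ValueError):
            MultiExpModel(amplitudes=[1.0], lifetimes=[-2.0])


class TestFitDecay:
    def test_noiseless_single_exponential_recovery(self):
        irf = syn.gaussian_irf(25.0, 2048, fwhm_ps=120.0, centre_ns=1.0)
        truth = MultiExpModel(amplitudes=[5000.0], lifetimes=[2.2], background=1.0)
        counts = np.clip(reconvolve(truth, irf), 0, None)
        hist = DecayHistogram(channel_width_ps=25.0, counts=counts)
        fit = fit_decay(hist, irf, 1)
        assert fit.model.lifetimes[0] == pytest.approx(2.2, rel=1e-3)

    def test_three_exponential_poisson_recovery(self):
        """Paper-preset three-exponential decay at 5e6 counts: every
        lifetime back within 10%."""
        gen = syn.generate_decay(syn.paper_decay_model(), 5e6, seed=11)
        fit = fit_decay(gen.histogram, gen.irf, 3)
        assert np.all(np.abs(fit.model.lifetimes / gen.truth.lifetimes - 1) < 0.10)

    def test_pure_background_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        irf = syn.gaussian_irf(50.0, 512, centre_ns=1.0)
        hist = DecayHistogram(channel_width_ps=50.0,
                              counts=rng.poisson(20.0, 512).astype(float))
        fit = fit_decay(hist, irf, 1)
        assert fit.degenerate
        assert fit.model.background == pytest.approx(20.0, rel=0.05)

    def test_component_count_bounds(self):
        gen = syn.generate_decay(syn.paper_decay_model(), 1e4, seed=0,
                                 n_channels=256)
        with pytest.raises(ValueError):
            fit_decay(gen.histogram, gen.irf, 5)


class TestGlobalFit:
    def test_single_histogram_matches_individual_fit(self):
        gen = syn.generate_decay(syn.paper_decay_model(), 1e6, seed=2)
        single = fit_decay(gen.histogram, gen.irf, 3)
        glob = global_fit([gen.histogram], gen.irf, 3)
        assert np.allclose(glob.lifetimes, single.model.lifetimes, rtol=0.02)

    def test_shared_lifetimes_and_per_curve_amplitudes(self):
        """Four curves sharing lifetimes but with different amplitude mixes:
        shared lifetimes within 10%, amplitude fractions within 15%."""
        taus = np.array([0.115, 2.2, 16.3])
        mixes = [(12000, 600, 1.0), (9000, 1200, 1.2),
                 (6000, 1800, 0.8), (4000, 2400, 1.0)]
        gens = [syn.generate_decay(MultiExpModel(amplitudes=np.array(m),
                                                 lifetimes=taus),
                                   1e6, seed=30 + i)
                for i, m in enumerate(mixes)]
        result = global_fit([g.histogram for g in gens], gens[0].irf, 3)
        assert np.all(np.abs(result.lifetimes / taus - 1) < 0.10)
        for gen, fitted in zip(gens, result.per_curve):
            truth_frac = gen.truth.amplitudes / gen.truth.amplitudes.sum()
            fit_frac = fitted.amplitudes / fitted.amplitudes.sum()
            # slowest component's fraction is ~1e-4; compare the two majors
            assert np.all(np.abs(fit_frac[:2] / truth_frac[:2] - 1) < 0.15)

    def test_order_invariance_of_shared_lifetimes(self):
        gens = [syn.generate_decay(syn.paper_decay_model(), 5e5, seed=40 + i,
                                   n_channels=2048)
                for i in range(3)]
        hists = [g.histogram for g in gens]
        fwd = global_fit(hists, gens[0].irf, 2)
        rev = global_fit(hists[::-1], gens[0].irf, 2)
        assert np.allclose(fwd.lifetimes, rev.lifetimes, rtol=0.01)

    def test_identical_copies_return_single_fit_lifetimes(self):
        gen = syn.generate_decay(syn.paper_decay_model(), 1e6, seed=5)
        single = fit_decay(gen.histogram, gen.irf, 3)
        glob = global_fit([gen.histogram] * 3, gen.irf, 3)
        assert np.allclose(glob.lifetimes, single.model.lifetimes, rtol=0.02)


class TestComponentCountSelection:
    def test_single_exponential_selected(self):
        truth = MultiExpModel(amplitudes=[3000.0], lifetimes=[2.2])
        gen = syn.generate_decay(truth, 1e6, seed=3, n_channels=2048)
        assert select_component_count(gen.histogram, gen.irf, max_n=3) == 1

    def test_three_exponentials_selected_and_fourth_rejected(self):
        gen = syn.generate_decay(syn.paper_decay_model(), 5e6, seed=4)
        n, details = select_component_count(gen.histogram, gen.irf,
                                            return_details=True)
        assert n == 3
        step_3_to_4 = [d for d in details if d["n"] == 3][0]
        assert not step_3_to_4["extra_component_significant"]


class TestAmplitudeConversions:
    def test_population_fractions(self):
        assert np.allclose(fractional_populations([2.0, 2.0]), [0.5, 0.5])
        pops = fractional_populations([10000.0, 1000.0, 1.0])
        assert pops[0] == pytest.approx(10000 / 11001)
        assert pops.sum() == pytest.approx(1.0)

    def test_population_scale_invariance(self):
        a = np.array([3.0, 5.0, 9.0])
        assert np.allclose(fractional_populations(a),
                           fractional_populations(1234.5 * a))

    def test_intensity_fractions_weight_by_lifetime(self):
        f = fractional_intensities([1.0, 1.0], [1.0, 3.0])
        assert np.allclose(f, [0.25, 0.75])
        # equal lifetimes: intensity fractions equal population fractions
        f_eq = fractional_intensities([2.0, 6.0], [4.0, 4.0])
        assert np.allclose(f_eq, fractional_populations([2.0, 6.0]))

    def test_permutation_equivariance(self):
        a, tau = np.array([5.0, 2.0, 1.0]), np.array([0.1, 2.0, 16.0])
        perm = [2, 0, 1]
        assert np.allclose(fractional_intensities(a, tau)[perm],
                           fractional_intensities(a[perm], tau[perm]))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fractional_populations([0.0, 0.0])
        with pytest.raises(ValueError):
            fractional_intensities([0.0], [2.0])
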