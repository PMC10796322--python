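"""Stopped-flow exponential fitting, rate summarization, kon and koff."""

import numpy as np
import pytest

from slimbind.simulate import gen_displacement_traces, gen_traces
from slimbind.stoppedflow import (KineticTrace, fit_exponential,
                                  koff_from_displacement, kon_from_kobs,
                                  rate_distribution)


def make_trace(rates, amps, baseline=0.1, noise=0.0, seed=0, n=200, t_end=1.0):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, t_end, n)
    y = np.full_like(t, baseline)
    for a, k in zip(amps, rates):
        y = y + a * np.exp(-k * t)
    if noise > 0:
        y = y + rng.normal(0, noise, size=y.shape)
    return KineticTrace(t, y)


class TestExponentialFit:
    def test_flat_trace_zero_amplitude(self):
        fit = fit_exponential(make_trace([], []), 1)
        assert abs(fit.amplitudes[0]) < 1e-6

    def test_single_exponential_recovery(self):
        fit = fit_exponential(make_trace([5.0], [1.0], noise=0.01, seed=1), 1)
        assert fit.rates[0] == pytest.approx(5.0, rel=0.02)

    def test_double_exponential_recovery(self):
        trace = make_trace([15.0, 3.0], [0.6, 0.4], noise=0.005, seed=2,
                           t_end=2.0, n=400)
        fit = fit_exponential(trace, 2)
        assert fit.rates[0] == pytest.approx(15.0, rel=0.05)
        assert fit.rates[1] == pytest.approx(3.0, rel=0.05)

    def test_rates_sorted_descending(self):
        fit = fit_exponential(make_trace([2.0, 20.0], [0.5, 0.5], t_end=2.0), 2)
        assert fit.rates[0] >= fit.rates[1]

    def test_biphasic_data_prefers_double_model(self):
        """A double-exponential synthetic fitted with one phase leaves
        systematically worse residuals than the two-phase fit."""
        trace = make_trace([20.0, 2.0], [0.5, 0.5], noise=0.002, seed=3,
                           t_end=3.0, n=500)
        single = fit_exponential(trace, 1)
        double = fit_exponential(trace, 2)
        assert single.rmsd > 3 * double.rmsd

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            KineticTrace(np.linspace(0, 1, 10), np.zeros(10))


class TestRateDistribution:
    def test_gaussian_sample_mean_recovered(self):
        rng = np.random.default_rng(7)
        rates = rng.normal(50.0, 5.0, size=100)
        rd = rate_distribution(rates)
        assert rd.mean == pytest.approx(np.mean(rates), abs=5.0 / np.sqrt(100) * 2)
        assert rd.sd == pytest.approx(5.0, rel=0.3)

    def test_identical_rates(self):
        rd = rate_distribution([4.2] * 10)
        assert rd.mean == 4.2
        assert rd.sd == 0.0

    def test_small_replicate_coverage(self):
        """With n=19 replicates the cumulative-Gaussian mean stays within
        2 SE of truth in ~95% of draws."""
        rng = np.random.default_rng(11)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            rates = rng.normal(30.0, 3.0, size=19)
            rd = rate_distribution(rates)
            hits += abs(rd.mean - 30.0) <= 2 * 3.0 / np.sqrt(19)
        assert hits / n_sim > 0.90


class TestKon:
    def test_exact_linear_slope(self):
        c = np.array([1.0, 2.0, 4.0, 8.0])       # uM
        kobs = 29.0 * c + 15.0
        res = kon_from_kobs(c, kobs)
        assert res.kon == pytest.approx(29.0, abs=1e-9)
        assert res.intercept == pytest.approx(15.0, abs=1e-9)
        assert not res.nonlinear

    def test_zero_slope_flagged_nonbinding(self):
        res = kon_from_kobs([1.0, 2.0, 4.0, 8.0], [5.0, 5.0, 5.0, 5.0])
        assert res.kon == pytest.approx(0.0, abs=1e-9)
        assert res.nonbinding

    def test_saturating_series_raises_nonlinearity_flag(self):
        c = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        kobs = 100.0 * c / (c + 4.0) + 5.0       # hyperbolic
        res = kon_from_kobs(c, kobs)
        assert res.nonlinear

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kon_from_kobs([1.0, 2.0], [2.0, 3.0])

    def test_full_pipeline_recovery(self):
        """Per-trace fits -> rate distributions -> weighted slope recovers
        the generating kon within 2%."""
        traces, truth = gen_traces(kon=29e6, koff=15.0, noise_sd=0.01, seed=4)
        c, m, s = [], [], []
        for conc, reps in traces.items():
            rates = [fit_exponential(t, 1).rates[0] for t in reps]
            rd = rate_distribution(rates)
            c.append(conc * 1e6)
            m.append(rd.mean)
            s.append(max(rd.sd, 1e-3))
        res = kon_from_kobs(c, m, s)
        assert res.kon == pytest.approx(29.0, rel=0.02)


class TestKoff:
    def test_constant_series(self):
        res = koff_from_displacement([1.0, 2.0, 4.0, 8.0], [12.0] * 4)
        assert res.koff == pytest.approx(12.0)
        assert res.amplitude == pytest.approx(0.0, abs=1e-9)

    def test_asymptote_recovery(self):
        c = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        kobs = 14.0 - 10.0 * np.exp(-c / 4.0)
        res = koff_from_displacement(c, kobs)
        assert res.koff == pytest.approx(14.0, rel=0.03)
        assert res.plateau_reached

    def test_no_plateau_warning(self):
        c = np.array([1.0, 2.0, 3.0, 4.0])
        kobs = 50.0 - 45.0 * np.exp(-c / 100.0)
        with pytest.warns(UserWarning, match="plateau"):
            res = koff_from_displacement(c, kobs)
        assert not res.plateau_reached

    def test_biphasic_displacement_recovery(self):
        """Two dissociation phases fitted per phase recover the generating
        koff pair within 3%."""
        disp, _ = gen_displacement_traces(koff_phases=(14.0, 3.0),
                                          amplitudes=(0.6, 0.4),
                                          noise_sd=0.005, seed=6)
        cc, fast, slow = [], [], []
        for conc, reps in disp.items():
            fits = [fit_exponential(t, 2) for t in reps]
            cc.append(conc)
            fast.append(np.median([f.rates[0] for f in fits]))
            slow.append(np.median([f.rates[1] for f in fits]))
        res_fast = koff_from_displacement(cc, fast)
        res_slow = koff_from_displacement(cc, slow)
        assert res_fast.koff == pytest.approx(14.0, rel=0.03)
        assert res_slow.koff == pytest.approx(3.0, rel=0.03)

    def test_kinetic_thermodynamic_consistency(self):
        """koff/kon from the default synthetic design reproduces the
        generating Kd."""
        traces, truth = gen_traces(kon=29e6, koff=14.8, noise_sd=0.005, seed=9)
        c, m = [], []
        for conc, reps in traces.items():
            rates = [fit_exponential(t, 1).rates[0] for t in reps]
            c.append(conc)
            m.append(rate_distribution(rates).mean)
        res = kon_from_kobs(c, m)
        kd = res.intercept / res.kon
        assert kd == pytest.approx(14.8 / 29e6, rel=0.05)
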