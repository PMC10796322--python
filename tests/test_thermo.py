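"""ITC forward model, isotherm fitting, dCp extraction and the
Spolar-Record decomposition."""

import numpy as np
import pytest

from slimbind.constants import R_GAS, T_REF
from slimbind.datasets import dreb2a_med25_thermo
from slimbind.simulate import gen_itc, gen_temperature_series
from slimbind.thermo import (DeltaCpModel, ITCExperiment, TemperatureSeries,
                             ThermoParams, dg_from_dh_tds, dg_from_kd, fit_dcp,
                             fit_itc, spolar_record_id, wiseman_isotherm)


class TestFreeEnergyIdentities:
    @pytest.mark.parametrize("kd, t, expected", [
        (540e-9, 298.15, -35.8),     # sub-micromolar bivalent fragment
        (6.0e-6, 298.15, -29.8),     # single-motif fragment
    ])
    def test_dg_from_kd_reference_values(self, kd, t, expected):
        assert dg_from_kd(kd, t) == pytest.approx(expected, abs=0.05)

    def test_molar_kd_gives_zero(self):
        assert dg_from_kd(1.0, 310.0) == 0.0

    @pytest.mark.parametrize("kd, t", [(-1e-9, 298.15), (0.0, 298.15),
                                       (1e-9, -5.0)])
    def test_domain_errors(self, kd, t):
        with pytest.raises(ValueError):
            dg_from_kd(kd, t)

    @pytest.mark.parametrize("dh, tds, expected", [
        (-52.3, 16.5, -35.8),
        (0.0, 0.0, 0.0),
        (-50.7, 14.8, -35.9),
    ])
    def test_dg_from_dh_tds(self, dh, tds, expected):
        assert dg_from_dh_tds(dh, tds) == pytest.approx(expected, abs=1e-12)

    def test_reference_table_thermodynamic_closure(self):
        """Every complete reference row satisfies dG = RT ln Kd and
        dG = dH - TdS within the reported precision."""
        table = dreb2a_med25_thermo()
        for _, row in table.iterrows():
            dg_kd = dg_from_kd(row.kd_nM * 1e-9, T_REF)
            tol_kd = R_GAS * T_REF * (row.kd_sd_nM / row.kd_nM) / 1000 + row.dg_sd + 0.05
            assert dg_kd == pytest.approx(row.dg, abs=tol_kd), row.fragment
            dg_cal = dg_from_dh_tds(row.dh, row.tds_neg)
            tol_cal = np.hypot(row.dh_sd, row.tds_neg_sd) + row.dg_sd + 0.1
            assert dg_cal == pytest.approx(row.dg, abs=tol_cal), row.fragment


def _experiment(cell=15e-6, syringe=150e-6, n_inj=18):
    volumes = np.concatenate([[0.5e-6], np.full(n_inj, 2.0e-6)])
    return ITCExperiment(cell_concentration=cell, syringe_concentration=syringe,
                         cell_volume=200e-6, injection_volumes=volumes)


class TestWisemanIsotherm:
    def test_zero_enthalpy_gives_pure_offset(self):
        p = ThermoParams(n_value=1.0, kd=500e-9, dh=0.0)
        heats = wiseman_isotherm(p, _experiment(), offset=2e-9)
        assert np.allclose(heats, 2e-9)

    def test_saturating_titration_mass_limit(self):
        """Cumulative heat approaches N * dH * V0 * [cell] when the titrant
        saturates all sites."""
        exp = _experiment(cell=15e-6, syringe=600e-6)
        p = ThermoParams(n_value=1.0, kd=1e-9, dh=-50.0)
        heats = wiseman_isotherm(p, exp, overflow=False)
        q_total = float(np.sum(heats))
        expected = p.n_value * p.dh * exp.cell_volume * exp.cell_concentration
        # dilution shrinks the cell concentration slightly; 5% window
        assert q_total == pytest.approx(expected, rel=0.05)

    @pytest.mark.parametrize("kd, n, dh", [
        (100e-9, 1.0, -50.0),
        (2e-6, 0.9, -30.0),
        (510e-9, 1.2, 20.0),
    ])
    def test_matches_bisection_equilibrium_oracle(self, kd, n, dh):
        """Per-injection heats agree with a brute-force bisection solve of
        the binding equilibrium at each titration step."""
        from scipy.optimize import brentq

        exp = _experiment()
        p = ThermoParams(n_value=n, kd=kd, dh=dh)
        heats = wiseman_isotherm(p, exp, overflow=True)

        v0 = exp.cell_volume
        dv = np.cumsum(exp.injection_volumes)
        mt = exp.cell_concentration * (1 - dv / (2 * v0)) / (1 + dv / (2 * v0))
        xt = exp.syringe_concentration * (dv / v0) / (1 + dv / (2 * v0))

        def bound(mtot, xtot):
            # bisection on free ligand: x_free + sites*x_free/(kd+x_free) = xtot
            def resid(xf):
                return xf + n * mtot * xf / (kd + xf) - xtot
            xf = brentq(resid, 0.0, xtot, xtol=1e-22, rtol=1e-15)
            return xtot - xf

        q = np.array([bound(m, x) for m, x in zip(mt, xt)]) * dh * v0
        q_prev = np.concatenate([[0.0], q[:-1]])
        oracle = q - q_prev + (exp.injection_volumes / v0) * (q + q_prev) / 2
        assert np.allclose(heats, oracle, rtol=1e-3, atol=1e-15)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            ITCExperiment(cell_concentration=-1e-6, syringe_concentration=1e-4,
                          cell_volume=2e-4, injection_volumes=[2e-6])


class TestITCFit:
    @pytest.mark.parametrize("kd", [3e-6, 510e-9, 30e-9])  # c ~ 5 .. 500
    def test_noiseless_round_trip(self, kd):
        exp, _ = gen_itc(kd=kd, n_value=0.98, dh=-50.7, noise_fraction=0.0)
        res = fit_itc(exp)
        assert res.params.n_value == pytest.approx(0.98, rel=5e-3)
        assert res.params.kd == pytest.approx(kd, rel=5e-3)
        assert res.params.dh == pytest.approx(-50.7, rel=5e-3)

    def test_round_trip_with_dilution_offset(self):
        exp, _ = gen_itc(noise_fraction=0.0, offset=-3e-10)
        res = fit_itc(exp)
        assert res.offset == pytest.approx(-3e-10, rel=1e-3)

    def test_zero_heats_flagged_unidentifiable(self):
        exp, _ = gen_itc(dh=0.0, noise_fraction=0.0)
        res = fit_itc(exp)
        assert res.unidentifiable
        assert abs(res.params.dh) < 0.5

    def test_c_value_warning(self):
        exp, _ = gen_itc(kd=50e-6, cell_concentration=15e-6,
                         syringe_concentration=150e-6, noise_fraction=0.0)
        res = fit_itc(exp)
        assert any("c-value" in w for w in res.warnings)

    def test_summary_mentions_kd(self):
        exp, _ = gen_itc(noise_fraction=0.01, seed=1)
        assert "Kd" in fit_itc(exp).summary()


class TestDeltaCp:
    def test_constant_dh_gives_zero_dcp(self):
        entries = [(t, ThermoParams(1.0, 500e-9, -50.0, temperature=t))
                   for t in (288.15, 293.15, 298.15, 303.15)]
        res = fit_dcp(TemperatureSeries(entries))
        assert res.dcp == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_linear_slope_exact(self):
        series, _ = gen_temperature_series(dcp=-2.0, dh_noise_sd=0.0)
        res = DeltaCpModel(series).fit()
        assert res.dcp == pytest.approx(-2.0, abs=1e-9)

    def test_two_temperatures_rejected(self):
        entries = [(t, ThermoParams(1.0, 5e-7, -50.0, temperature=t))
                   for t in (288.15, 298.15)]
        with pytest.raises(ValueError):
            fit_dcp(TemperatureSeries(entries))

    def test_ci_coverage_near_nominal(self):
        """95% CI of the slope covers the generating dCp ~95% of the time."""
        from scipy import stats as sps

        rng = np.random.default_rng(42)
        t = np.array([283.15, 288.15, 293.15, 298.15, 303.15])
        true = -2.0
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            dh = -50.0 + true * (t - T_REF) + rng.normal(0, 0.5, t.size)
            res = sps.linregress(t, dh)
            tcrit = sps.t.ppf(0.975, t.size - 2)
            lo, hi = res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr
            entries = [(tt, ThermoParams(1.0, 5e-7, d, temperature=tt))
                       for tt, d in zip(t, dh)]
            fitted = fit_dcp(TemperatureSeries(entries))
            assert fitted.dcp == pytest.approx(res.slope, abs=1e-12)
            hits += lo <= true <= hi
        assert 0.93 <= hits / n_sim <= 0.97


class TestSpolarRecord:
    def test_zero_conformational_entropy_gives_zero_residues(self):
        # choose ds_assoc so that ds_conf vanishes
        dcp = -2.0
        ds_he = 1.35 * dcp * 1000 * np.log(T_REF / 386.0)
        res = spolar_record_id(dcp, ds_he + (-209.0))
        assert res.ds_conf == pytest.approx(0.0, abs=1e-9)
        assert res.r_th_id == pytest.approx(0.0, abs=1e-9)

    def test_zero_input_errors_give_zero_sd(self):
        res = spolar_record_id(-2.0, -49.6)
        assert res.r_th_id_sd == 0.0

    def test_manual_spreadsheet_oracle(self):
        """Single evaluation agrees with independent step-by-step
        arithmetic at dCp = -2.0 kJ/mol/K, dS_assoc = -49.6 J/mol/K."""
        ds_he = 1.35 * (-2.0 * 1000.0) * np.log(298.15 / 386.0)   # = 697.42...
        ds_conf = -49.6 - ds_he - (-209.0)
        expected_r = ds_conf / (-23.4)
        res = spolar_record_id(-2.0, -49.6)
        assert res.ds_he == pytest.approx(697.25, abs=0.01)
        assert res.r_th_id == pytest.approx(expected_r, rel=1e-12)

    def test_missing_constant_named_in_error(self):
        with pytest.raises(ValueError, match="ds_rt"):
            spolar_record_id(-2.0, -49.6, ds_rt=None)

    def test_monte_carlo_reproducible_and_scales_with_errors(self):
        a = spolar_record_id(-2.0, -49.6, dcp_se=0.2, ds_assoc_se=3.0, seed=7)
        b = spolar_record_id(-2.0, -49.6, dcp_se=0.2, ds_assoc_se=3.0, seed=7)
        assert a.r_th_id_sd == b.r_th_id_sd
        half = spolar_record_id(-2.0, -49.6, dcp_se=0.1, ds_assoc_se=1.5, seed=7)
        assert half.r_th_id_sd == pytest.approx(a.r_th_id_sd / 2, rel=1e-6)
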