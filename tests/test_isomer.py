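"""Branched cis/trans isomer binding: populations, Keq, apparent-Kd
decomposition and the forward equilibrium solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slimbind.isomer import (BoundFractions, IsomerBindingSystem, apparent_kd,
                             decompose_kd, keq_from_population,
                             population_from_volumes, solve_equilibrium)


class TestPopulations:
    def test_mean_and_sd_over_pairs(self):
        cis = [3.0, 3.1, 2.9, 3.05, 2.95]
        trans = [7.0, 7.1, 6.9, 7.05, 6.95]
        f, sd = population_from_volumes(cis, trans)
        assert f == pytest.approx(0.30, abs=0.01)
        assert sd > 0

    def test_equal_volumes_give_half(self):
        f, sd = population_from_volumes([5.0, 2.0], [5.0, 2.0])
        assert f == 0.5
        assert sd == 0.0

    def test_single_pair_exact(self):
        f, sd = population_from_volumes([3.0], [7.0])
        assert f == pytest.approx(0.3, abs=1e-15)
        assert sd == 0.0

    def test_zero_total_pair_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            f, _ = population_from_volumes([3.0, 0.0], [7.0, 0.0])
        assert f == pytest.approx(0.3)

    @pytest.mark.parametrize("f, expected", [(0.30, 0.4286), (0.5, 1.0),
                                             (1e-6, 1e-6)])
    def test_keq_from_population(self, f, expected):
        assert keq_from_population(f) == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.1, 1.3])
    def test_keq_boundaries_rejected(self, f):
        with pytest.raises(ValueError):
            keq_from_population(f)


class TestApparentKd:
    def test_reference_decomposed_pair_recombines(self):
        assert apparent_kd(330e-9, 640e-9, 0.30) == pytest.approx(500e-9,
                                                                  rel=0.01)

    def test_identical_isomer_kds(self):
        assert apparent_kd(2e-6, 2e-6, 0.42) == pytest.approx(2e-6)

    @pytest.mark.parametrize("kc, kt, f", [
        (330e-9, 640e-9, 0.30), (1e-6, 5e-6, 0.1), (4e-9, 3e-6, 0.8),
    ])
    def test_matches_trace_receptor_mass_balance(self, kc, kt, f):
        """Kd_app equals the half-saturation ligand concentration of the
        full equilibrium solver in the trace-receptor limit."""
        keq = f / (1 - f)
        rt = 1e-12                      # trace receptor
        kd_app = apparent_kd(kc, kt, f)
        sys = IsomerBindingSystem(keq, kc, kt, total_ligand=kd_app,
                                  total_receptor=rt)
        state = solve_equilibrium(sys)
        bound = state.bound_cis + state.bound_trans
        assert bound / rt == pytest.approx(0.5, rel=1e-3)

    @given(kc=st.floats(1e-9, 1e-4), kt=st.floats(1e-9, 1e-4),
           f=st.floats(0.01, 0.99))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_apparent_lies_between_isomer_kds(self, kc, kt, f):
        ka = apparent_kd(kc, kt, f)
        assert min(kc, kt) <= ka * (1 + 1e-12)
        assert ka <= max(kc, kt) * (1 + 1e-12)


class TestDecomposeKd:
    def test_reference_decomposition(self):
        """Kd_app 500 nM with per-pool bound fractions 3.6% / 6.8% and 30%
        cis splits into 640 / 330 nM at two significant figures."""
        bound = BoundFractions(p_bound_cis=0.068, p_bound_trans=0.036)
        kd_t, kd_c, _, _ = decompose_kd(500e-9, 0.30, bound)
        assert round(kd_t * 1e9, -1) == 640
        assert round(kd_c * 1e9, -1) == 330

    def test_equal_bound_fractions_give_equal_kds(self):
        bound = BoundFractions(p_bound_cis=0.05, p_bound_trans=0.05)
        kd_t, kd_c, _, _ = decompose_kd(1e-6, 0.3, bound)
        assert kd_t == pytest.approx(1e-6)
        assert kd_c == pytest.approx(1e-6)

    @given(kd_app=st.floats(1e-8, 1e-5), f=st.floats(0.05, 0.95),
           pc=st.floats(0.01, 0.4), pt=st.floats(0.01, 0.4))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_round_trip_identity(self, kd_app, f, pc, pt):
        """apparent_kd(decompose_kd(x)) == x for all valid inputs."""
        bound = BoundFractions(p_bound_cis=pc, p_bound_trans=pt)
        kd_t, kd_c, _, _ = decompose_kd(kd_app, f, bound)
        assert apparent_kd(kd_c, kd_t, f) == pytest.approx(kd_app, rel=1e-9)

    def test_monte_carlo_sd_shrinks_with_input_sd(self):
        bound_big = BoundFractions(0.068, 0.036, 0.002, 0.002)
        bound_small = BoundFractions(0.068, 0.036, 0.0005, 0.0005)
        _, _, sd_t_big, _ = decompose_kd(500e-9, 0.30, bound_big,
                                         kd_app_sd=20e-9, f_cis_sd=0.01)
        _, _, sd_t_small, _ = decompose_kd(500e-9, 0.30, bound_small,
                                           kd_app_sd=5e-9, f_cis_sd=0.0025)
        assert 0 < sd_t_small < sd_t_big
        _, _, sd_zero, _ = decompose_kd(500e-9, 0.30,
                                        BoundFractions(0.068, 0.036))
        assert sd_zero == 0.0


class TestSolveEquilibrium:
    def _system(self, lt=500e-6, rt=25e-6):
        return IsomerBindingSystem(keq_trans_to_cis=0.42857, kd_cis=330e-9,
                                   kd_trans=640e-9, total_ligand=lt,
                                   total_receptor=rt)

    def test_zero_receptor_gives_no_bound_species(self):
        state = solve_equilibrium(self._system(rt=0.0))
        assert state.bound_cis == 0.0
        assert state.bound_trans == 0.0

    def test_equal_kds_split_by_free_pool_fractions(self):
        sys = IsomerBindingSystem(0.5, 1e-6, 1e-6, 100e-6, 10e-6)
        state = solve_equilibrium(sys)
        ratio = state.bound_cis / state.bound_trans
        assert ratio == pytest.approx(0.5 / 1.5 / (1 / 1.5), rel=1e-9)

    def test_mass_conservation(self):
        state = solve_equilibrium(self._system())
        lig = (state.ligand_cis_free + state.ligand_trans_free
               + state.bound_cis + state.bound_trans)
        rec = state.receptor_free + state.bound_cis + state.bound_trans
        assert lig == pytest.approx(500e-6, rel=1e-9)
        assert rec == pytest.approx(25e-6, rel=1e-9)

    def test_exchange_readout_cross_check(self):
        """At the saturation-transfer sample composition the solver's
        per-pool bound fractions sit near the measured 6.8% / 3.6% and
        their odds ratio equals the Kd ratio exactly."""
        state = solve_equilibrium(self._system())
        assert state.p_bound_cis == pytest.approx(0.068, abs=0.01)
        assert state.p_bound_trans == pytest.approx(0.036, abs=0.01)
        odds = lambda p: p / (1 - p)
        assert (odds(state.p_bound_cis) / odds(state.p_bound_trans)
                == pytest.approx(640 / 330, rel=1e-6))
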