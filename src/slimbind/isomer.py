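"""Branched cis/trans proline isomer binding equilibria.

A disordered ligand whose binding motif contains a proline populates two
slowly interconverting isomers, each binding the receptor with its own
dissociation constant:

    R + L_trans <-> RL_trans        Kd_trans
    R + L_cis   <-> RL_cis          Kd_cis
    L_trans     <-> L_cis           Keq (trans -> cis)

Interconversion between the two *bound* states is not modelled. When the
free pool equilibrates fast relative to the titration, a calorimetric
titration sees one apparent constant, the population-weighted harmonic
combination of the two isomer constants; saturation-transfer NMR resolves
the per-pool bound fractions, which fix the ratio of the two constants and
let the apparent constant be decomposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .constants import MC_DRAWS, MC_SEED

__all__ = [
    "IsomerBindingSystem",
    "BoundFractions",
    "EquilibriumState",
    "population_from_volumes",
    "keq_from_population",
    "apparent_kd",
    "decompose_kd",
    "solve_equilibrium",
]


@dataclass
class IsomerBindingSystem:
    """Parameters of the branched two-isomer binding equilibrium."""

    keq_trans_to_cis: float    # [cis]/[trans] in the free pool
    kd_cis: float              # molar
    kd_trans: float            # molar
    total_ligand: float        # molar
    total_receptor: float      # molar

    def __post_init__(self) -> None:
        if self.keq_trans_to_cis <= 0:
            raise ValueError("keq must be positive")
        if self.kd_cis <= 0 or self.kd_trans <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.total_ligand < 0 or self.total_receptor < 0:
            raise ValueError("totals must be non-negative")

    @property
    def f_cis_free(self) -> float:
        k = self.keq_trans_to_cis
        return k / (1.0 + k)


@dataclass
class BoundFractions:
    """Per-pool bound fractions: the fraction of all cis (trans) molecules
    that are receptor-bound, as read out per isomer by exchange NMR."""

    p_bound_cis: float
    p_bound_trans: float
    p_bound_cis_sd: float = 0.0
    p_bound_trans_sd: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.p_bound_cis, self.p_bound_trans):
            if not 0.0 < p < 1.0:
                raise ValueError("bound fractions must lie in (0, 1)")


@dataclass
class EquilibriumState:
    """Species concentrations (molar) of the branched equilibrium."""

    receptor_free: float
    ligand_cis_free: float
    ligand_trans_free: float
    bound_cis: float
    bound_trans: float

    @property
    def p_bound_cis(self) -> float:
        tot = self.ligand_cis_free + self.bound_cis
        return self.bound_cis / tot if tot > 0 else 0.0

    @property
    def p_bound_trans(self) -> float:
        tot = self.ligand_trans_free + self.bound_trans
        return self.bound_trans / tot if tot > 0 else 0.0


def population_from_volumes(cis_volumes, trans_volumes):
    """Cis fraction from paired cis/trans peak volumes.

    Each residue pair contributes V_cis / (V_cis + V_trans); returns the
    mean and SD over pairs (SD 0 for a single pair). Pairs with zero total
    volume are skipped with a warning.
    """
    import warnings

    cis = np.asarray(cis_volumes, dtype=float)
    trans = np.asarray(trans_volumes, dtype=float)
    if cis.shape != trans.shape or cis.size == 0:
        raise ValueError("need >= 1 paired cis/trans volumes")
    tot = cis + trans
    ok = tot > 0
    if not np.all(ok):
        warnings.warn(f"skipping {np.sum(~ok)} pair(s) with zero total volume")
    if not np.any(ok):
        raise ValueError("no usable volume pairs")
    frac = cis[ok] / tot[ok]
    sd = float(np.std(frac, ddof=1)) if frac.size > 1 else 0.0
    return float(np.mean(frac)), sd


def keq_from_population(f_cis: float) -> float:
    """Keq(trans->cis) = f_cis / (1 - f_cis)."""
    if not 0.0 < f_cis < 1.0:
        raise ValueError("f_cis must lie strictly in (0, 1)")
    return f_cis / (1.0 - f_cis)


def apparent_kd(kd_cis: float, kd_trans: float, f_cis_free: float) -> float:
    """Apparent dissociation constant of an equilibrated two-isomer pool.

    1/Kd_app = f_cis/Kd_cis + (1 - f_cis)/Kd_trans — exact when the free
    pool maintains its isomer ratio during the titration.
    """
    if kd_cis <= 0 or kd_trans <= 0:
        raise ValueError("dissociation constants must be positive")
    if not 0.0 < f_cis_free < 1.0:
        raise ValueError("f_cis_free must lie in (0, 1)")
    return 1.0 / (f_cis_free / kd_cis + (1.0 - f_cis_free) / kd_trans)


def decompose_kd(
    kd_app: float,
    f_cis_free: float,
    bound: BoundFractions,
    *,
    kd_app_sd: float = 0.0,
    f_cis_sd: float = 0.0,
    n_draws: int = MC_DRAWS,
    seed: int = MC_SEED,
):
    """Split an apparent Kd into isomer-specific constants.

    At a common free-receptor concentration [R], each pool obeys
    p_b / (1 - p_b) = [R] / Kd, so the per-pool bound-fraction odds fix the
    ratio Kd_trans / Kd_cis = odds_cis / odds_trans. Combining the ratio
    with the harmonic relation of :func:`apparent_kd` yields both constants.

    Returns ``(kd_trans, kd_cis, kd_trans_sd, kd_cis_sd)`` in the units of
    ``kd_app``; SDs from Monte Carlo propagation of the supplied SDs.
    """
    if kd_app <= 0:
        raise ValueError("kd_app must be positive")

    def solve(kd_a, f_c, p_c, p_t):
        odds_c = p_c / (1.0 - p_c)
        odds_t = p_t / (1.0 - p_t)
        ratio = odds_c / odds_t          # = Kd_trans / Kd_cis
        kd_cis = kd_a * (f_c + (1.0 - f_c) / ratio)
        return ratio * kd_cis, kd_cis

    kd_trans, kd_cis = solve(kd_app, f_cis_free,
                             bound.p_bound_cis, bound.p_bound_trans)
    if kd_trans <= 0 or kd_cis <= 0:
        raise ValueError("inputs admit no positive solution")

    sds = (kd_app_sd, f_cis_sd, bound.p_bound_cis_sd, bound.p_bound_trans_sd)
    if any(s > 0 for s in sds):
        rng = np.random.default_rng(seed)
        d_kd = rng.normal(kd_app, kd_app_sd, n_draws)
        d_f = np.clip(rng.normal(f_cis_free, f_cis_sd, n_draws), 1e-6, 1 - 1e-6)
        d_pc = np.clip(rng.normal(bound.p_bound_cis, bound.p_bound_cis_sd,
                                  n_draws), 1e-6, 1 - 1e-6)
        d_pt = np.clip(rng.normal(bound.p_bound_trans, bound.p_bound_trans_sd,
                                  n_draws), 1e-6, 1 - 1e-6)
        t_draws, c_draws = solve(d_kd, d_f, d_pc, d_pt)
        kd_trans_sd = float(np.std(t_draws, ddof=1))
        kd_cis_sd = float(np.std(c_draws, ddof=1))
    else:
        kd_trans_sd = kd_cis_sd = 0.0

    return float(kd_trans), float(kd_cis), kd_trans_sd, kd_cis_sd


def solve_equilibrium(system: IsomerBindingSystem) -> EquilibriumState:
    """Mass-balance solution of the branched equilibrium.

    The free-pool isomer ratio is pinned by Keq (free interconversion is
    fast relative to binding turnover); bound-state interconversion is
    excluded. Solved by bracketing the free-receptor concentration.
    """
    lt, rt = system.total_ligand, system.total_receptor
    if rt == 0 or lt == 0:
        f = system.f_cis_free
        return EquilibriumState(rt, lt * f, lt * (1 - f), 0.0, 0.0)

    f = system.f_cis_free
    kc, kt = system.kd_cis, system.kd_trans

    def free_ligand(r):
        # ligand balance: L_free * (1 + r*(f/kc + (1-f)/kt)) = lt
        return lt / (1.0 + r * (f / kc + (1.0 - f) / kt))

    def receptor_residual(r):
        lf = free_ligand(r)
        bound = r * lf * (f / kc + (1.0 - f) / kt)
        return r + bound - rt

    r = optimize.brentq(receptor_residual, 0.0, rt, xtol=1e-18, rtol=1e-14)
    lf = free_ligand(r)
    lc, ltr = f * lf, (1.0 - f) * lf
    return EquilibriumState(
        receptor_free=r,
        ligand_cis_free=lc,
        ligand_trans_free=ltr,
        bound_cis=r * lc / kc,
        bound_trans=r * ltr / kt,
    )
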