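"""ITC binding thermodynamics: the single-site (Wiseman) isotherm, isotherm
fitting, thermodynamic identities, heat-capacity extraction from temperature
series, and the Spolar-Record entropy decomposition adapted to disordered
ligands.

Conventions
-----------
Energies are kJ/mol, entropies J/mol/K, concentrations molar, volumes litres,
temperatures Kelvin, heats kJ. The dissociation constant ``kd`` is molar
against a 1 M standard state, so ``dG = R*T*ln(kd)`` is negative for
sub-molar affinities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .constants import (
    MC_DRAWS,
    MC_SEED,
    R_GAS,
    SR_DS_PER_RESIDUE,
    SR_DS_RT,
    SR_HE_COEFF,
    SR_T_ZERO_HE,
    T_REF,
)

__all__ = [
    "ThermoParams",
    "ITCExperiment",
    "TemperatureSeries",
    "SpolarRecordResult",
    "dg_from_kd",
    "dg_from_dh_tds",
    "wiseman_isotherm",
    "ITCModel",
    "ITCResults",
    "fit_itc",
    "DeltaCpModel",
    "DeltaCpResults",
    "fit_dcp",
    "spolar_record_id",
]


# ---------------------------------------------------------------------------
# thermodynamic identities
# ---------------------------------------------------------------------------

def dg_from_kd(kd: float, temperature: float = T_REF) -> float:
    """Binding free energy (kJ/mol) from a molar dissociation constant.

    dG = R*T*ln(kd / 1 M). Negative for kd < 1 M.
    """
    kd = np.asarray(kd, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    if np.any(kd <= 0):
        raise ValueError("kd must be positive (molar)")
    if np.any(temperature <= 0):
        raise ValueError("temperature must be positive (K)")
    return R_GAS * temperature * np.log(kd) / 1000.0


def dg_from_dh_tds(dh: float, tds_neg: float) -> float:
    """dG = dH + (-T*dS); both terms in kJ/mol."""
    return dh + tds_neg


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class ThermoParams:
    """Fitted single-site binding parameters at one temperature.

    ``tds_neg`` stores the entropic term as reported on isotherms, i.e.
    ``-T*dS`` in kJ/mol, so that ``dg = dh + tds_neg``.
    """

    n_value: float
    kd: float                      # molar
    dh: float                      # kJ/mol
    temperature: float = T_REF     # K
    n_value_sd: float = 0.0
    kd_sd: float = 0.0
    dh_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")

    @property
    def dg(self) -> float:
        return dg_from_kd(self.kd, self.temperature)

    @property
    def tds_neg(self) -> float:
        return self.dg - self.dh

    @property
    def dg_sd(self) -> float:
        return R_GAS * self.temperature * self.kd_sd / self.kd / 1000.0

    @property
    def tds_neg_sd(self) -> float:
        return float(np.hypot(self.dg_sd, self.dh_sd))


@dataclass
class ITCExperiment:
    """One titration: cell/syringe concentrations and per-injection heats.

    The customary design titrates ~10x syringe over cell and discards a small
    initial injection contaminated by diffusion across the syringe tip.
    """

    cell_concentration: float          # molar, binding partner in the cell
    syringe_concentration: float       # molar, titrant
    cell_volume: float                 # litres
    injection_volumes: np.ndarray      # litres, per injection
    measured_heats: np.ndarray | None = None  # kJ per injection
    temperature: float = T_REF
    discard_first: bool = True

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.measured_heats is not None:
            self.measured_heats = np.asarray(self.measured_heats, dtype=float)
        if self.cell_concentration <= 0 or self.syringe_concentration <= 0:
            raise ValueError("concentrations must be positive")
        if self.cell_volume <= 0 or np.any(self.injection_volumes <= 0):
            raise ValueError("volumes must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    def usable_slice(self) -> slice:
        return slice(1, None) if self.discard_first else slice(0, None)


@dataclass
class TemperatureSeries:
    """Binding parameters for one fragment across temperatures (for dCp)."""

    entries: list[tuple[float, ThermoParams]]
    label: str = ""

    def __post_init__(self) -> None:
        if len({round(t, 6) for t, _ in self.entries}) < len(self.entries):
            raise ValueError("duplicate temperatures in series")

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([t for t, _ in self.entries])


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _cell_concentrations(exp: ITCExperiment, overflow: bool = True):
    """Total macromolecule and titrant concentrations in the cell after each
    injection.

    ``overflow=True`` uses the perfusion bookkeeping of fixed-volume
    instruments, where each injection displaces an equal volume of (mixed)
    cell content out of the active volume; ``False`` simply grows the volume.
    """
    v0 = exp.cell_volume
    dv = np.cumsum(exp.injection_volumes)
    if overflow:
        mt = exp.cell_concentration * (1 - dv / (2 * v0)) / (1 + dv / (2 * v0))
        xt = exp.syringe_concentration * (dv / v0) / (1 + dv / (2 * v0))
    else:
        mt = exp.cell_concentration / (1 + dv / v0)
        xt = exp.syringe_concentration * (dv / v0) / (1 + dv / v0)
    return mt, xt


def _bound_concentration(n: float, kd: float, mt, xt):
    """Bound-titrant concentration from the single-site mass balance.

    Solves ``[RL]^2 - (n*Mt + Xt + Kd)[RL] + n*Mt*Xt = 0`` for the
    physical root.
    """
    s = n * mt + xt + kd
    disc = s * s - 4.0 * n * mt * xt
    return 0.5 * (s - np.sqrt(np.maximum(disc, 0.0)))


def wiseman_isotherm(
    params: ThermoParams,
    exp: ITCExperiment,
    offset: float = 0.0,
    overflow: bool = True,
) -> np.ndarray:
    """Per-injection heats (kJ) of the one-set-of-sites binding model.

    The heat of injection *i* is the change in total bound-state enthalpy in
    the cell, corrected for the heat carried out with displaced volume, plus
    a constant per-injection dilution-heat ``offset``.
    """
    if params.kd <= 0:
        raise ValueError("kd must be positive")
    mt, xt = _cell_concentrations(exp, overflow=overflow)
    v0 = exp.cell_volume
    bound = _bound_concentration(params.n_value, params.kd, mt, xt)
    if overflow:
        q = bound * params.dh * v0      # kJ, heat content of the active volume
        q_prev = np.concatenate([[0.0], q[:-1]])
        dv = exp.injection_volumes
        heats = q - q_prev + (dv / v0) * (q + q_prev) / 2.0
    else:
        # growing volume: heat content tracks total moles bound
        vol = v0 + np.cumsum(exp.injection_volumes)
        q = bound * params.dh * vol
        q_prev = np.concatenate([[0.0], q[:-1]])
        heats = q - q_prev
    return heats + offset


# ---------------------------------------------------------------------------
# isotherm fitting
# ---------------------------------------------------------------------------

@dataclass
class ITCResults:
    """Results of a single-site isotherm fit.

    ``params`` carries (N, Kd, dH) with standard errors from the fit
    covariance; ``offset`` is the constant dilution heat per injection.
    """

    params: ThermoParams
    offset: float
    offset_sd: float
    c_value: float
    residuals: np.ndarray
    converged: bool
    unidentifiable: bool
    warnings: list[str] = field(default_factory=list)
    cov: np.ndarray | None = None

    @property
    def rmsd(self) -> float:
        return float(np.sqrt(np.mean(self.residuals ** 2)))

    def summary(self) -> str:
        p = self.params
        lines = [
            "Single-site ITC fit",
            "-" * 46,
            f"  N       {p.n_value:10.3f} +/- {p.n_value_sd:.3f}",
            f"  Kd      {p.kd * 1e9:10.1f} +/- {p.kd_sd * 1e9:.1f} nM",
            f"  dH      {p.dh:10.2f} +/- {p.dh_sd:.2f} kJ/mol",
            f"  -TdS    {p.tds_neg:10.2f} +/- {p.tds_neg_sd:.2f} kJ/mol",
            f"  dG      {p.dg:10.2f} +/- {p.dg_sd:.2f} kJ/mol",
            f"  offset  {self.offset * 1e6:10.3f} uJ/injection",
            f"  c-value {self.c_value:10.1f}",
            f"  rmsd    {self.rmsd * 1e6:10.3f} uJ",
        ]
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)


class ITCModel:
    """Nonlinear least-squares model for a single-site ITC titration.

    Parameters
    ----------
    experiment : ITCExperiment
        Must carry ``measured_heats``.
    overflow : bool
        Injection-displacement bookkeeping of the forward model.
    """

    def __init__(self, experiment: ITCExperiment, overflow: bool = True):
        if experiment.measured_heats is None:
            raise ValueError("experiment carries no measured heats")
        self.experiment = experiment
        self.overflow = overflow
        self._sl = experiment.usable_slice()
        if len(experiment.measured_heats[self._sl]) < 8:
            raise ValueError("need at least 8 usable injections")

    def _predict(self, n, log10_kd, dh, offset):
        p = ThermoParams(n_value=n, kd=10.0 ** log10_kd, dh=dh,
                         temperature=self.experiment.temperature)
        return wiseman_isotherm(p, self.experiment, offset=offset,
                                overflow=self.overflow)[self._sl]

    def fit(self) -> ITCResults:
        exp = self.experiment
        y = exp.measured_heats[self._sl]
        warn: list[str] = []

        scale = np.max(np.abs(y)) or 1.0
        dh0 = np.sum(y) / (exp.cell_volume * exp.cell_concentration)

        def resid(theta):
            # residuals normalized by the heat scale so tolerances are
            # meaningful for uJ-scale injections
            return (self._predict(*theta) - y) / scale

        best = None
        for lk0 in (-8.0, -7.0, -6.0, -5.0, -4.0):
            theta0 = [1.0, lk0, dh0 if dh0 != 0 else -50.0, 0.0]
            try:
                sol = optimize.least_squares(
                    resid, theta0,
                    bounds=([1e-3, -12.0, -np.inf, -np.inf],
                            [10.0, 0.0, np.inf, np.inf]),
                    x_scale=[1.0, 1.0, max(abs(dh0), 10.0), scale],
                    ftol=1e-14, xtol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("isotherm fit failed from all starting points")

        n, log10_kd, dh, offset = best.x
        kd = 10.0 ** log10_kd
        converged = bool(best.success)
        if not converged:
            warn.append("optimizer did not report convergence")

        # covariance from the jacobian at the solution
        dof = max(len(y) - 4, 1)
        s2 = 2.0 * best.cost / dof
        jtj = best.jac.T @ best.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            cov = None
            se = np.full(4, np.nan)
            warn.append("singular fit covariance")

        ln10 = np.log(10.0)
        kd_sd = kd * ln10 * se[1]
        noise_kj = np.sqrt(s2) * scale   # residual SD back on the heat scale
        unident = bool(
            abs(dh) * exp.cell_volume * exp.cell_concentration < 3 * noise_kj
            or not np.isfinite(kd_sd)
            or kd_sd > 10 * kd
        )
        if unident:
            warn.append("Kd unidentifiable: signal indistinguishable from offset")

        c_value = exp.cell_concentration / kd
        if not 1.0 <= c_value <= 1000.0:
            warn.append(f"c-value {c_value:.3g} outside [1, 1000]; "
                        "Kd poorly constrained by this design")

        params = ThermoParams(
            n_value=n, kd=kd, dh=dh, temperature=exp.temperature,
            n_value_sd=se[0], kd_sd=kd_sd, dh_sd=se[2],
        )
        return ITCResults(
            params=params, offset=offset, offset_sd=se[3],
            c_value=c_value, residuals=best.fun * scale, converged=converged,
            unidentifiable=unident, warnings=warn, cov=cov,
        )


def fit_itc(experiment: ITCExperiment, overflow: bool = True) -> ITCResults:
    """Fit the single-site model to a titration; see :class:`ITCModel`."""
    return ITCModel(experiment, overflow=overflow).fit()


# ---------------------------------------------------------------------------
# heat-capacity change from a temperature series
# ---------------------------------------------------------------------------

@dataclass
class _LinFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_ci95: tuple[float, float]
    n: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class DeltaCpResults:
    """Linear temperature dependence of dH and -TdS.

    ``dcp`` (kJ/mol/K) is the slope of dH versus T.
    """

    dh_fit: _LinFit
    tds_fit: _LinFit
    label: str = ""

    @property
    def dcp(self) -> float:
        return self.dh_fit.slope

    @property
    def dcp_se(self) -> float:
        return self.dh_fit.slope_se

    def dh_at(self, temperature: float) -> tuple[float, float]:
        """Interpolated dH and its SE at a temperature."""
        return self.dh_fit.predict(temperature), self._pred_se(self.dh_fit, temperature)

    def tds_neg_at(self, temperature: float) -> tuple[float, float]:
        return self.tds_fit.predict(temperature), self._pred_se(self.tds_fit, temperature)

    def _pred_se(self, fit: _LinFit, t: float) -> float:
        # conservative: ignores slope/intercept covariance
        return float(np.hypot(fit.intercept_se, fit.slope_se * t))

    def summary(self) -> str:
        lo, hi = self.dh_fit.slope_ci95
        return (
            f"dCp fit{' (' + self.label + ')' if self.label else ''}\n"
            f"  dCp = {self.dcp:.3f} +/- {self.dcp_se:.3f} kJ/mol/K "
            f"(95% CI {lo:.3f} .. {hi:.3f})\n"
            f"  d(-TdS)/dT = {self.tds_fit.slope:.3f} +/- "
            f"{self.tds_fit.slope_se:.3f} kJ/mol/K"
        )


def _ols(x: np.ndarray, y: np.ndarray) -> _LinFit:
    n = len(x)
    res = stats.linregress(x, y)
    if n > 2:
        tcrit = stats.t.ppf(0.975, n - 2)
        se, ise = res.stderr, res.intercept_stderr
    else:  # exact 2-point line: no residual dof
        tcrit, se, ise = 0.0, 0.0, 0.0
    return _LinFit(
        slope=res.slope, intercept=res.intercept,
        slope_se=se, intercept_se=ise,
        slope_ci95=(res.slope - tcrit * se, res.slope + tcrit * se),
        n=n,
    )


class DeltaCpModel:
    """OLS model of dH(T) and -TdS(T) for a multi-temperature ITC series."""

    def __init__(self, series: TemperatureSeries):
        if len(series.entries) < 3:
            raise ValueError("dCp fitting needs parameters at >= 3 temperatures")
        self.series = series

    def fit(self) -> DeltaCpResults:
        t = self.series.temperatures
        dh = np.array([p.dh for _, p in self.series.entries])
        tds = np.array([p.tds_neg for _, p in self.series.entries])
        return DeltaCpResults(dh_fit=_ols(t, dh), tds_fit=_ols(t, tds),
                              label=self.series.label)


def fit_dcp(series: TemperatureSeries) -> DeltaCpResults:
    return DeltaCpModel(series).fit()


# ---------------------------------------------------------------------------
# Spolar-Record decomposition
# ---------------------------------------------------------------------------

@dataclass
class SpolarRecordResult:
    """Entropy decomposition and the residues-folding-on-binding estimate.

    All entropies in J/mol/K at the analysis temperature. ``r_th_id`` is the
    estimated number of residues folding upon binding; its SD comes from
    Monte Carlo resampling of dCp and dS_assoc under their standard errors.
    """

    dcp: float                 # kJ/mol/K
    dcp_se: float
    ds_assoc: float            # J/mol/K, total association entropy
    ds_he: float               # hydrophobic-effect term
    ds_rt: float               # rotational-translational term
    ds_conf: float             # conformational term (residual)
    r_th_id: float
    r_th_id_sd: float

    def summary(self) -> str:
        return (
            "Spolar-Record decomposition\n"
            f"  dS_assoc = {self.ds_assoc:8.1f} J/mol/K\n"
            f"  dS_HE    = {self.ds_he:8.1f} J/mol/K\n"
            f"  dS_RT    = {self.ds_rt:8.1f} J/mol/K\n"
            f"  dS_conf  = {self.ds_conf:8.1f} J/mol/K\n"
            f"  R_th,ID  = {self.r_th_id:8.1f} +/- {self.r_th_id_sd:.1f} residues"
        )


def spolar_record_id(
    dcp: float,
    ds_assoc: float,
    *,
    dcp_se: float = 0.0,
    ds_assoc_se: float = 0.0,
    temperature: float = T_REF,
    t_zero_he: float | None = SR_T_ZERO_HE,
    he_coeff: float | None = SR_HE_COEFF,
    ds_rt: float | None = SR_DS_RT,
    ds_per_residue: float | None = SR_DS_PER_RESIDUE,
    n_draws: int = MC_DRAWS,
    seed: int = MC_SEED,
) -> SpolarRecordResult:
    """Estimate residues folding upon binding from dCp and the association
    entropy.

    The hydrophobic-effect entropy is ``he_coeff * dCp * ln(T / t_zero_he)``
    (dCp converted to J/mol/K); the conformational entropy is the remainder
    after also subtracting the rigid-body term ``ds_rt``, and is divided by
    the per-residue conformational entropy to count folding residues.

    Parameters
    ----------
    dcp : float
        Heat-capacity change, kJ/mol/K (typically negative).
    ds_assoc : float
        Total association entropy dS at `temperature`, J/mol/K
        (``-(-T*dS)/T`` from an isotherm).
    dcp_se, ds_assoc_se : float
        Standard errors fed to the Monte Carlo error propagation.
    """
    for name, val in (("t_zero_he", t_zero_he), ("he_coeff", he_coeff),
                      ("ds_rt", ds_rt), ("ds_per_residue", ds_per_residue)):
        if val is None:
            raise ValueError(f"Spolar-Record constant '{name}' is not set")

    def decompose(dcp_kj, ds_tot):
        ds_he = he_coeff * dcp_kj * 1000.0 * np.log(temperature / t_zero_he)
        ds_conf = ds_tot - ds_he - ds_rt
        return ds_he, ds_conf, ds_conf / ds_per_residue

    ds_he, ds_conf, r = decompose(dcp, ds_assoc)

    if dcp_se > 0 or ds_assoc_se > 0:
        rng = np.random.default_rng(seed)
        draws_dcp = rng.normal(dcp, dcp_se, size=n_draws)
        draws_ds = rng.normal(ds_assoc, ds_assoc_se, size=n_draws)
        _, _, r_draws = decompose(draws_dcp, draws_ds)
        r_sd = float(np.std(r_draws, ddof=1))
    else:
        r_sd = 0.0

    return SpolarRecordResult(
        dcp=dcp, dcp_se=dcp_se, ds_assoc=ds_assoc,
        ds_he=float(ds_he), ds_rt=float(ds_rt), ds_conf=float(ds_conf),
        r_th_id=float(r), r_th_id_sd=r_sd,
    )
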