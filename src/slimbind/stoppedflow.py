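"""Stopped-flow fluorescence kinetics.

Association is measured under pseudo-first-order conditions (receptor in
large excess over the labelled ligand), so each trace relaxes exponentially
with kobs = kon*[R] + koff and kon is the slope of kobs versus [R].
Dissociation is measured by competitive displacement with excess unlabelled
ligand; the observed rate rises with competitor concentration to an
asymptote equal to koff. Traces are fitted individually; per-condition
rates are summarized by fitting a cumulative Gaussian to their empirical
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "KineticTrace",
    "RateDistribution",
    "ExponentialFit",
    "fit_exponential",
    "rate_distribution",
    "kon_from_kobs",
    "koff_from_displacement",
    "KonResult",
    "KoffResult",
]

#: instrument dead time removed from the start of each trace, seconds.
DEAD_TIME_S = 0.002


@dataclass
class KineticTrace:
    """One time-resolved fluorescence trace at one titrant concentration."""

    time: np.ndarray           # s, strictly increasing
    fluorescence: np.ndarray   # arbitrary units
    condition: float = 0.0     # molar concentration of the titrant

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.shape != self.fluorescence.shape:
            raise ValueError("time and fluorescence must align")
        if len(self.time) < 20:
            raise ValueError("trace must have >= 20 points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def truncated(self, dead_time: float = DEAD_TIME_S) -> "KineticTrace":
        keep = self.time >= dead_time
        if keep.sum() < 20:
            return self
        return KineticTrace(self.time[keep], self.fluorescence[keep],
                            self.condition)


@dataclass
class ExponentialFit:
    """baseline + sum_i A_i * exp(-k_i * t); rates sorted descending."""

    amplitudes: np.ndarray
    rates: np.ndarray           # s^-1
    baseline: float
    rates_se: np.ndarray
    rmsd: float
    converged: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def n_phases(self) -> int:
        return len(self.rates)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.baseline)
        for a, k in zip(self.amplitudes, self.rates):
            y = y + a * np.exp(-k * t)
        return y


def fit_exponential(trace: KineticTrace, n_phases: int = 1,
                    dead_time: float | None = DEAD_TIME_S) -> ExponentialFit:
    """Least-squares single- or double-exponential fit of one trace.

    The first ``dead_time`` seconds are discarded (mixing artefact); pass
    ``None`` to keep the full trace.
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    if dead_time is not None:
        trace = trace.truncated(dead_time)
    t, y = trace.time, trace.fluorescence
    t0 = t[0]
    ts = t - t0   # shift origin for conditioning; amplitudes refer to t0

    span = y[0] - y[-1]
    k0 = 1.0 / max(ts[-1] / 3.0, 1e-9)
    warn: list[str] = []

    if n_phases == 1:
        def f(tt, a, k, c):
            return c + a * np.exp(-k * tt)
        p0 = [span if span != 0 else 1.0, k0, y[-1]]
    else:
        def f(tt, a1, k1, a2, k2, c):
            return c + a1 * np.exp(-k1 * tt) + a2 * np.exp(-k2 * tt)
        p0 = [0.7 * span if span != 0 else 1.0, 3.0 * k0,
              0.3 * span if span != 0 else 0.5, 0.3 * k0, y[-1]]

    try:
        with warnings.catch_warnings():
            # degenerate traces (e.g. flat) have unidentifiable rates; the
            # covariance warning is recorded on the result instead
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(f, ts, y, p0=p0, maxfev=20000)
        converged = True
        if not np.all(np.isfinite(pcov)):
            warn.append("parameter covariance could not be estimated")
    except RuntimeError:
        popt, pcov = np.asarray(p0, dtype=float), np.full((len(p0),) * 2, np.nan)
        converged = False
        warn.append("exponential fit did not converge")

    if n_phases == 1:
        amps, rates, base = np.array([popt[0]]), np.array([popt[1]]), popt[2]
        rates_se = np.array([np.sqrt(pcov[1, 1])])
    else:
        amps = np.array([popt[0], popt[2]])
        rates = np.array([popt[1], popt[3]])
        base = popt[4]
        rates_se = np.sqrt(np.array([pcov[1, 1], pcov[3, 3]]))
        if rates.max() > 0 and rates.min() / rates.max() > 0.5:
            warn.append("degenerate rates: phases differ by less than 2-fold")

    order = np.argsort(rates)[::-1]
    resid = y - f(ts, *popt)
    return ExponentialFit(
        amplitudes=amps[order], rates=np.abs(rates[order]), baseline=base,
        rates_se=rates_se[order], rmsd=float(np.sqrt(np.mean(resid ** 2))),
        converged=converged, warnings=warn,
    )


@dataclass
class RateDistribution:
    """Mean and SD of replicate observed rates from a cumulative-Gaussian
    fit to their empirical distribution."""

    rates: np.ndarray
    mean: float
    sd: float

    def summary(self) -> str:
        return (f"kobs = {self.mean:.4g} +/- {self.sd:.3g} s^-1 "
                f"(n = {len(self.rates)})")


def rate_distribution(rates) -> RateDistribution:
    """Fit Phi((x - mu) / sigma) to the empirical CDF of observed rates."""
    rates = np.sort(np.asarray(rates, dtype=float))
    if len(rates) < 5:
        raise ValueError("need >= 5 rates")
    if np.ptp(rates) == 0:
        return RateDistribution(rates, float(rates[0]), 0.0)
    ecdf = (np.arange(len(rates)) + 0.5) / len(rates)

    def f(x, mu, sigma):
        return stats.norm.cdf((x - mu) / sigma)

    p0 = [float(np.mean(rates)), float(np.std(rates, ddof=1))]
    popt, _ = optimize.curve_fit(f, rates, ecdf, p0=p0, maxfev=10000)
    return RateDistribution(rates, float(popt[0]), float(abs(popt[1])))


@dataclass
class KonResult:
    kon: float                  # per (concentration unit) per s
    kon_se: float
    intercept: float            # s^-1, extrapolated kobs at zero titrant
    intercept_se: float
    nonlinear: bool             # lack-of-fit flag
    nonbinding: bool
    lof_pvalue: float | None = None

    def summary(self) -> str:
        s = (f"kon = {self.kon:.4g} +/- {self.kon_se:.2g} per conc per s; "
             f"intercept = {self.intercept:.4g} s^-1")
        if self.nonlinear:
            s += "  [non-linear concentration dependence: kon unreliable]"
        if self.nonbinding:
            s += "  [zero slope: no binding detected]"
        return s


def kon_from_kobs(concentrations, kobs, kobs_sd=None) -> KonResult:
    """Association rate constant as the slope of kobs versus concentration.

    Weighted linear fit (weights 1/sd^2 when SDs are given). A quadratic
    lack-of-fit test flags saturating/non-linear series, for which a slope
    is not a valid kon.
    """
    c = np.asarray(concentrations, dtype=float)
    k = np.asarray(kobs, dtype=float)
    if len(c) < 3:
        raise ValueError("need >= 3 concentrations")
    w = None
    if kobs_sd is not None:
        sd = np.asarray(kobs_sd, dtype=float)
        w = 1.0 / np.maximum(sd, 1e-12) ** 2

    # weighted least squares, design [1, c]
    x = np.column_stack([np.ones_like(c), c])
    ww = np.ones_like(c) if w is None else w
    xtwx = x.T @ (ww[:, None] * x)
    beta = np.linalg.solve(xtwx, x.T @ (ww * k))
    resid = k - x @ beta
    dof = len(c) - 2
    s2 = float(np.sum(ww * resid ** 2) / dof) if dof > 0 else 0.0
    cov = np.linalg.inv(xtwx) * (s2 if w is None else max(s2, 1.0))
    se = np.sqrt(np.diag(cov))

    # lack of fit: does a quadratic term significantly improve the fit?
    nonlinear, lof_p = False, None
    if len(c) >= 4:
        x2 = np.column_stack([x, c ** 2])
        beta2, *_ = np.linalg.lstsq(np.sqrt(ww)[:, None] * x2,
                                    np.sqrt(ww) * k, rcond=None)
        rss1 = float(np.sum(ww * resid ** 2))
        rss2 = float(np.sum(ww * (k - x2 @ beta2) ** 2))
        dof2 = len(c) - 3
        if dof2 > 0 and rss2 > 0:
            fstat = (rss1 - rss2) / (rss2 / dof2)
            lof_p = float(stats.f.sf(fstat, 1, dof2))
            nonlinear = lof_p < 0.05
        elif dof2 >= 0 and rss2 == 0 and rss1 > 0:
            nonlinear, lof_p = True, 0.0

    # zero-slope (non-binding) flag: slope negligible on the data's scale
    tiny = 1e-9 * np.max(np.abs(k)) / max(np.ptp(c), 1e-30)
    nonbinding = abs(beta[1]) < tiny or (se[1] > 0 and abs(beta[1]) < 2 * se[1])
    return KonResult(kon=float(beta[1]), kon_se=float(se[1]),
                     intercept=float(beta[0]), intercept_se=float(se[0]),
                     nonlinear=nonlinear, nonbinding=bool(nonbinding),
                     lof_pvalue=lof_p)


@dataclass
class KoffResult:
    koff: float
    koff_se: float
    amplitude: float
    c0: float
    plateau_reached: bool

    def summary(self) -> str:
        s = f"koff = {self.koff:.4g} +/- {self.koff_se:.2g} s^-1"
        if not self.plateau_reached:
            s += "  [warning: plateau not reached within the titrated range]"
        return s


def koff_from_displacement(concentrations, kobs) -> KoffResult:
    """Dissociation rate from the asymptote of kobs versus competitor.

    Fits ``kobs(c) = koff - A * exp(-c / c0)`` and reports the asymptote.
    A fitted decay constant far beyond the titrated range triggers a
    no-plateau warning. For biphasic dissociation apply per phase.
    """
    c = np.asarray(concentrations, dtype=float)
    k = np.asarray(kobs, dtype=float)
    if len(c) < 4:
        raise ValueError("need >= 4 competitor concentrations")
    kmax = float(np.max(k))
    spread = float(np.ptp(k))
    if spread < 1e-12 * max(abs(kmax), 1.0):
        return KoffResult(koff=float(np.mean(k)), koff_se=float(np.std(k) / np.sqrt(len(k))),
                          amplitude=0.0, c0=np.inf, plateau_reached=True)

    def f(cc, koff, a, c0):
        return koff - a * np.exp(-cc / c0)

    p0 = [kmax, spread, float(np.median(c))]
    popt, pcov = optimize.curve_fit(f, c, k, p0=p0, maxfev=20000)
    koff, a, c0 = popt
    plateau = c0 < float(np.max(c))
    if not plateau:
        warnings.warn("displacement series does not reach its plateau; "
                      "koff is an extrapolation")
    return KoffResult(koff=float(koff), koff_se=float(np.sqrt(pcov[0, 0])),
                      amplitude=float(a), c0=float(c0), plateau_reached=plateau)
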