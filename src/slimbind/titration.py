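"""NMR titration analysis: combined chemical-shift perturbations,
per-residue binding-isotherm fits with ligand depletion, affinity-regime
classification and relative peak-intensity tracing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .constants import CSP_N15_WEIGHT

__all__ = [
    "TitrationSeries",
    "ResidueKdFit",
    "csp",
    "bound_fraction",
    "fit_residue_kd",
    "TitrationModel",
    "classify_regimes",
    "intensity_trace",
    "csp_significance_map",
]


def csp(dH, dN, n_weight: float = CSP_N15_WEIGHT):
    """Combined 1H/15N shift perturbation: sqrt(dH^2 + (w*dN)^2)."""
    dH = np.asarray(dH, dtype=float)
    dN = np.asarray(dN, dtype=float)
    return np.sqrt(dH ** 2 + (n_weight * dN) ** 2)


def bound_fraction(ligand_total, receptor_total, kd):
    """Receptor bound fraction from the single-site quadratic with ligand
    depletion (no free~total approximation)."""
    lt = np.asarray(ligand_total, dtype=float)
    p = np.asarray(receptor_total, dtype=float)
    s = p + lt + kd
    disc = s * s - 4.0 * p * lt
    bound = 0.5 * (s - np.sqrt(np.maximum(disc, 0.0)))
    return np.where(p > 0, bound / np.where(p > 0, p, 1.0), 0.0)


@dataclass
class TitrationSeries:
    """HSQC titration at constant receptor with increasing ligand.

    ``data`` columns: residue, point_index, ligand_total (molar),
    dh_ppm, dn_ppm (shift differences from the zero-ligand reference),
    intensity (optional). Point 0 is the zero-ligand reference.
    """

    data: pd.DataFrame
    receptor_total: float       # molar, constant across points

    def __post_init__(self) -> None:
        required = {"residue", "point_index", "ligand_total", "dh_ppm", "dn_ppm"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"titration table missing columns: {sorted(missing)}")
        ref = self.data[self.data["point_index"] == 0]
        if ref.empty or not np.allclose(ref["ligand_total"], 0.0):
            raise ValueError("series must include a zero-ligand reference point")
        if self.receptor_total <= 0:
            raise ValueError("receptor concentration must be positive")

    @property
    def residues(self) -> list:
        return sorted(self.data["residue"].unique())

    def residue_csp(self, residue) -> tuple[np.ndarray, np.ndarray]:
        """(ligand totals, combined CSPs) for one residue, point order."""
        sub = self.data[self.data["residue"] == residue].sort_values("point_index")
        return (sub["ligand_total"].to_numpy(dtype=float),
                csp(sub["dh_ppm"].to_numpy(), sub["dn_ppm"].to_numpy()))


@dataclass
class ResidueKdFit:
    residue: object
    kd: float
    kd_se: float
    csp_max: float
    csp_max_se: float
    unbound: bool
    regime: str = ""     # filled by classify_regimes

    def summary(self) -> str:
        if self.unbound:
            return f"residue {self.residue}: no binding detected"
        return (f"residue {self.residue}: Kd = {self.kd * 1e6:.3g} uM "
                f"+/- {self.kd_se * 1e6:.2g}, CSPmax = {self.csp_max:.3f} ppm")


def fit_residue_kd(series: TitrationSeries, residue,
                   min_csp: float = 0.01) -> ResidueKdFit:
    """Fit CSP(L) = CSPmax * bound_fraction(L; Kd) for one residue.

    The exact single-site quadratic is used because receptor and ligand
    concentrations are comparable. Residues whose CSP never rises above
    ``min_csp`` ppm are flagged unbound rather than fitted.
    """
    lig, y = series.residue_csp(residue)
    if len(lig) < 4:
        raise ValueError("need >= 4 titration points")
    if np.max(y) < min_csp:
        return ResidueKdFit(residue, np.inf, np.inf, 0.0, 0.0, unbound=True)

    p = series.receptor_total

    def f(l, log10_kd, csp_max):
        return csp_max * bound_fraction(l, p, 10.0 ** log10_kd)

    # half-saturation ligand concentration as a Kd guess
    half = np.interp(0.5 * np.max(y), y, lig)
    p0 = [np.log10(max(half, 1e-9)), float(np.max(y))]
    popt, pcov = optimize.curve_fit(f, lig, y, p0=p0, maxfev=20000,
                                    bounds=([-12, 0], [3, 10 * np.max(y)]))
    kd = 10.0 ** popt[0]
    kd_se = kd * np.log(10.0) * np.sqrt(pcov[0, 0])
    return ResidueKdFit(residue, float(kd), float(kd_se),
                        float(popt[1]), float(np.sqrt(pcov[1, 1])),
                        unbound=False)


def classify_regimes(fits: list[ResidueKdFit]) -> list[ResidueKdFit]:
    """Two-regime split of per-residue affinities.

    Exact 1-D two-means clustering on log10(Kd) (best split of the sorted
    values); the lower-Kd group is labelled "high-affinity", the other
    "low-affinity". Unbound residues keep an empty regime. Modifies and
    returns the input fits.
    """
    bound = [f for f in fits if not f.unbound]
    if len(bound) < 2:
        for f in bound:
            f.regime = "high-affinity"
        return fits
    logk = np.array([np.log10(f.kd) for f in bound])
    order = np.argsort(logk)
    x = logk[order]
    best_cut, best_cost = 1, np.inf
    for cut in range(1, len(x)):
        cost = (np.sum((x[:cut] - x[:cut].mean()) ** 2)
                + np.sum((x[cut:] - x[cut:].mean()) ** 2))
        if cost < best_cost:
            best_cut, best_cost = cut, cost
    low_group = set(order[:best_cut])
    for idx, f in enumerate(bound):
        f.regime = "high-affinity" if idx in low_group else "low-affinity"
    return fits


class TitrationModel:
    """Per-residue Kd fits plus regime classification for a full series."""

    def __init__(self, series: TitrationSeries):
        self.series = series

    def fit(self) -> pd.DataFrame:
        fits = []
        for res in self.series.residues:
            try:
                fits.append(fit_residue_kd(self.series, res))
            except (ValueError, RuntimeError) as err:
                warnings.warn(f"residue {res}: fit failed ({err})")
        classify_regimes(fits)
        return pd.DataFrame([{
            "residue": f.residue, "kd": f.kd, "kd_se": f.kd_se,
            "csp_max": f.csp_max, "unbound": f.unbound, "regime": f.regime,
        } for f in fits])


def intensity_trace(series: TitrationSeries,
                    threshold: float = 0.3) -> pd.DataFrame:
    """Relative peak intensities I/I0 per residue per titration point.

    Residues whose final relative intensity drops below ``threshold`` are
    flagged ``attenuated`` (binding-affected through exchange broadening).
    Residues with zero reference intensity are excluded with a warning.
    """
    if "intensity" not in series.data.columns:
        raise ValueError("series carries no intensities")
    frames = []
    for res, grp in series.data.groupby("residue"):
        grp = grp.sort_values("point_index")
        i0 = float(grp[grp["point_index"] == 0]["intensity"].iloc[0])
        if i0 == 0:
            warnings.warn(f"residue {res}: zero reference intensity, excluded")
            continue
        rel = grp["intensity"].to_numpy(dtype=float) / i0
        frames.append(pd.DataFrame({
            "residue": res,
            "point_index": grp["point_index"].to_numpy(),
            "ligand_total": grp["ligand_total"].to_numpy(),
            "relative_intensity": rel,
            "attenuated": rel[-1] < threshold,
        }))
    if not frames:
        return pd.DataFrame(columns=["residue", "point_index", "ligand_total",
                                     "relative_intensity", "attenuated"])
    return pd.concat(frames, ignore_index=True)


def csp_significance_map(csps: dict | pd.Series,
                         thresholds: tuple[float, float] = (0.1, 0.2)
                         ) -> pd.DataFrame:
    """Tiered CSP classification: none (< lo), moderate (>= lo), strong
    (>= hi); thresholds in ppm."""
    lo, hi = thresholds
    if lo > hi:
        raise ValueError("thresholds must be (low, high)")
    items = csps.items() if hasattr(csps, "items") else enumerate(csps)
    rows = []
    for res, val in items:
        tier = "strong" if val >= hi else ("moderate" if val >= lo else "none")
        rows.append({"residue": res, "csp_ppm": float(val), "tier": tier})
    return pd.DataFrame(rows)
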