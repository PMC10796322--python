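"""Bloch-McConnell simulation and fitting of CEST profiles.

Chemical exchange saturation transfer detects sparsely populated bound
states of an observed free species: a weak B1 field is stepped across the
spectrum during a saturation delay, and whenever it touches the resonance
of an exchanging minor state the observed major-state intensity dips.

The simulator propagates the full transverse+longitudinal magnetization of
every state under the combined relaxation / exchange / RF generator by
matrix exponentiation. Exchange topologies are restricted to pairs
connected to the observed (free) state — bound states do not interconvert
directly — and rates obey detailed balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import expm

__all__ = [
    "ExchangeState",
    "ExchangeModel",
    "CESTProfile",
    "CESTFitResult",
    "simulate_cest",
    "CESTModel",
    "fit_cest",
    "extract_csp",
    "bound_state_shifts",
]

#: default CEST CSP significance threshold for 15N, ppm.
CSP_SIGNIFICANCE_PPM = 2.2


@dataclass
class ExchangeState:
    label: str
    population: float
    offset_ppm: float
    r1: float = 1.5      # s^-1
    r2: float = 10.0     # s^-1


@dataclass
class ExchangeModel:
    """N-state exchange system. ``exchange_rates`` maps state-index pairs
    (i, j) to the pair exchange rate kex = k_ij + k_ji; detailed balance
    splits kex between the directions according to the populations."""

    states: list[ExchangeState]
    exchange_rates: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pops = np.array([s.population for s in self.states])
        if np.any(pops < 0) or abs(pops.sum() - 1.0) > 1e-8:
            raise ValueError("state populations must be non-negative and sum to 1")
        for (i, j), kex in self.exchange_rates.items():
            if kex < 0:
                raise ValueError("exchange rates must be non-negative")
            if i == j or not (0 <= i < len(self.states)) or not (0 <= j < len(self.states)):
                raise ValueError(f"invalid exchange pair ({i}, {j})")
            if len(self.states) > 2 and 0 not in (i, j):
                raise ValueError("exchange topology must be a star on state 0; "
                                 "bound-bound exchange is not modelled")

    @property
    def populations(self) -> np.ndarray:
        return np.array([s.population for s in self.states])

    def rate_matrix(self) -> np.ndarray:
        """K[i, j] = rate of j -> i flux (off-diagonal); columns sum to 0."""
        n = len(self.states)
        p = self.populations
        k = np.zeros((n, n))
        for (i, j), kex in self.exchange_rates.items():
            ptot = p[i] + p[j]
            if ptot == 0:
                continue
            k_ij = kex * p[j] / ptot     # i -> j
            k_ji = kex * p[i] / ptot     # j -> i
            k[j, i] += k_ij
            k[i, i] -= k_ij
            k[i, j] += k_ji
            k[j, j] -= k_ji
        return k


@dataclass
class CESTProfile:
    """One residue's intensity-ratio profile at one B1 field."""

    b1_hz: float
    t_sat: float                    # s
    offsets_ppm: np.ndarray
    intensity_ratio: np.ndarray
    spectrometer_mhz: float = 81.08   # 15N at 18.8 T
    residue: str = ""
    isomer_tag: str = ""

    def __post_init__(self) -> None:
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.intensity_ratio = np.asarray(self.intensity_ratio, dtype=float)
        if self.offsets_ppm.shape != self.intensity_ratio.shape:
            raise ValueError("offsets and intensities must align")
        if np.any(np.diff(self.offsets_ppm) <= 0):
            raise ValueError("offsets must be strictly increasing")

    def noise_sd(self) -> float:
        """Robust noise estimate from successive differences."""
        d = np.diff(self.intensity_ratio)
        return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _generator(model: ExchangeModel, carrier_ppm: float, b1_hz: float,
               spectrometer_mhz: float) -> np.ndarray:
    """Augmented (3N+1)-dim generator for [Mx.., My.., Mz.., 1]."""
    n = len(model.states)
    k = model.rate_matrix()
    w1 = 2.0 * np.pi * b1_hz
    a = np.zeros((3 * n + 1, 3 * n + 1))
    for blk in range(3):
        a[blk * n:(blk + 1) * n, blk * n:(blk + 1) * n] += k
    for i, st in enumerate(model.states):
        dw = 2.0 * np.pi * (st.offset_ppm - carrier_ppm) * spectrometer_mhz
        a[i, i] += -st.r2
        a[i, n + i] += -dw
        a[n + i, i] += dw
        a[n + i, n + i] += -st.r2
        a[n + i, 2 * n + i] += w1
        a[2 * n + i, n + i] += -w1
        a[2 * n + i, 2 * n + i] += -st.r1
        a[2 * n + i, 3 * n] += st.r1 * st.population   # recovery toward equilibrium
    return a


def simulate_cest(
    model: ExchangeModel,
    b1_hz: float,
    offsets_ppm,
    t_sat: float,
    spectrometer_mhz: float = 81.08,
    observed_state: int = 0,
    residue: str = "",
    isomer_tag: str = "",
) -> CESTProfile:
    """Simulate an intensity-ratio profile I/I0 over carrier offsets.

    Magnetization starts at thermal equilibrium (Mz_i = p_i); the observed
    state's Mz after the saturation period, divided by its equilibrium
    value, gives I/I0 at each carrier position.
    """
    if t_sat <= 0:
        raise ValueError("saturation time must be positive")
    offsets_ppm = np.asarray(offsets_ppm, dtype=float)
    n = len(model.states)
    v0 = np.zeros(3 * n + 1)
    v0[2 * n:3 * n] = model.populations
    v0[-1] = 1.0
    p_obs = model.states[observed_state].population
    ratios = np.empty(len(offsets_ppm))
    for idx, carrier in enumerate(offsets_ppm):
        a = _generator(model, carrier, b1_hz, spectrometer_mhz)
        v = expm(a * t_sat) @ v0
        ratios[idx] = v[2 * n + observed_state] / p_obs
    return CESTProfile(
        b1_hz=b1_hz, t_sat=t_sat, offsets_ppm=offsets_ppm,
        intensity_ratio=ratios, spectrometer_mhz=spectrometer_mhz,
        residue=residue, isomer_tag=isomer_tag,
    )


def simulate_cest_ode(model: ExchangeModel, b1_hz: float, offsets_ppm,
                      t_sat: float, spectrometer_mhz: float = 81.08,
                      observed_state: int = 0, rtol: float = 1e-10,
                      atol: float = 1e-12) -> np.ndarray:
    """Step-wise ODE-integration reference for :func:`simulate_cest`.

    Kept as an independent cross-check of the matrix-exponential
    propagation; orders of magnitude slower.
    """
    from scipy.integrate import solve_ivp

    offsets_ppm = np.asarray(offsets_ppm, dtype=float)
    n = len(model.states)
    v0 = np.zeros(3 * n + 1)
    v0[2 * n:3 * n] = model.populations
    v0[-1] = 1.0
    p_obs = model.states[observed_state].population
    out = np.empty(len(offsets_ppm))
    for idx, carrier in enumerate(offsets_ppm):
        a = _generator(model, carrier, b1_hz, spectrometer_mhz)
        sol = solve_ivp(lambda t, y: a @ y, (0.0, t_sat), v0,
                        method="LSODA", rtol=rtol, atol=atol)
        out[idx] = sol.y[2 * n + observed_state, -1] / p_obs
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class CESTFitResult:
    """Global fit of grouped CEST profiles.

    Minor-state populations and exchange rates are shared across the residue
    group; each residue carries its own bound-state shift difference(s)
    ``domega`` (ppm, relative to the observed state).
    """

    n_states: int
    populations: np.ndarray            # minor-state populations
    populations_se: np.ndarray
    kex: np.ndarray                    # per free<->minor edge, s^-1
    kex_se: np.ndarray
    shifts: pd.DataFrame               # residue, state, domega_ppm, omega_major_ppm
    rchi2: float
    excluded: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    converged: bool = True

    def summary(self) -> str:
        lines = [f"CEST global fit ({self.n_states}-state)", "-" * 46]
        for m in range(len(self.populations)):
            lines.append(
                f"  p_minor[{m}] = {100 * self.populations[m]:.2f} "
                f"+/- {100 * self.populations_se[m]:.2f} %   "
                f"kex[{m}] = {self.kex[m]:.1f} +/- {self.kex_se[m]:.1f} s^-1"
            )
        lines.append(f"  reduced chi2 = {self.rchi2:.3f}")
        for f in self.flags:
            lines.append(f"  flag: {f}")
        if self.excluded:
            lines.append(f"  excluded (no exchange): {', '.join(self.excluded)}")
        return "\n".join(lines)


def _find_dips(profile: CESTProfile, n_dips: int) -> list[float]:
    """Crude dip-position guesses: deepest points, masking +-1.5 ppm around
    each accepted dip."""
    x, y = profile.offsets_ppm, profile.intensity_ratio.copy()
    found = []
    for _ in range(n_dips):
        i = int(np.argmin(y))
        found.append(float(x[i]))
        y[np.abs(x - x[i]) < 1.5] = np.inf
        if not np.isfinite(y).any():
            break
    return found


class CESTModel:
    """Global two- or three-state fit of a residue group's CEST profiles.

    All profiles in the group share minor-state populations and exchange
    rates; shift differences are per residue. Relaxation rates are shared
    nuisance constants (``r1``, ``r2``), fitted only when
    ``vary_relaxation`` is set.

    Parameters
    ----------
    profiles : list of CESTProfile
        Multiple B1 fields per residue strongly aid identifiability.
    n_states : 2 or 3
        Three-state models use a star topology on the observed free state.
    noise_sd : float, optional
        Intensity-ratio noise; estimated per profile when omitted.
    fix_minor_ratio : float, optional
        For three-state fits, constrain p_minor2 / p_minor1 to this value
        (e.g. from an independently measured isomer equilibrium constant).
    """

    def __init__(self, profiles: list[CESTProfile], n_states: int = 2,
                 r1: float = 1.5, r2: float = 10.0, noise_sd: float | None = None,
                 vary_relaxation: bool = False,
                 fix_minor_ratio: float | None = None,
                 exclusion_factor: float = 3.0):
        if n_states not in (2, 3):
            raise ValueError("n_states must be 2 or 3")
        if not profiles:
            raise ValueError("no profiles supplied")
        self.n_states = n_states
        self.r1, self.r2 = r1, r2
        self.noise_sd = noise_sd
        self.vary_relaxation = vary_relaxation
        self.fix_minor_ratio = fix_minor_ratio
        self.exclusion_factor = exclusion_factor
        self.profiles, self.excluded = self._screen(profiles)

    def _screen(self, profiles):
        """Drop profiles showing no exchange.

        A profile carries an exchange signature when, after light
        smoothing, it shows at least two dips whose prominence exceeds
        ``exclusion_factor`` times the noise SD — the major-state dip plus
        at least one minor-state dip. Direct-saturation tails of the major
        dip do not create prominence, so wide dips at strong B1 are handled
        correctly.
        """
        from scipy.signal import find_peaks

        keep, excluded = [], []
        kernel = np.ones(3) / 3.0
        for p in profiles:
            sd = self.noise_sd if self.noise_sd is not None else p.noise_sd()
            y = np.convolve(p.intensity_ratio, kernel, mode="same")
            peaks, _ = find_peaks(-y, prominence=self.exclusion_factor * sd)
            if len(peaks) >= 2:
                keep.append(p)
            else:
                excluded.append(f"{p.residue}@{p.b1_hz:g}Hz")
        return keep, excluded

    # parameter vector: [logit-ish pops..., log10 kex..., (r1, r2)?,
    #                    per residue: omega_major, domega...]
    def _unpack(self, theta, residues):
        m = self.n_states - 1
        pos = 0
        if self.fix_minor_ratio is not None and self.n_states == 3:
            p1 = theta[pos]; pos += 1
            pops = np.array([p1, p1 * self.fix_minor_ratio])
        else:
            pops = np.array(theta[pos:pos + m]); pos += m
        kex = 10.0 ** np.array(theta[pos:pos + m]); pos += m
        if self.vary_relaxation:
            r1, r2 = theta[pos], theta[pos + 1]; pos += 2
        else:
            r1, r2 = self.r1, self.r2
        shifts = {}
        for res in residues:
            omega_major = theta[pos]; pos += 1
            domega = np.array(theta[pos:pos + m]); pos += m
            shifts[res] = (omega_major, domega)
        return pops, kex, r1, r2, shifts

    def _model_for(self, pops, kex, r1, r2, omega_major, domega):
        p_free = 1.0 - float(np.sum(pops))
        states = [ExchangeState("free", p_free, omega_major, r1, r2)]
        rates = {}
        for m in range(len(pops)):
            states.append(ExchangeState(f"bound{m + 1}", float(pops[m]),
                                        omega_major + float(domega[m]), r1, r2))
            rates[(0, m + 1)] = float(kex[m])
        return ExchangeModel(states, rates)

    def _residuals(self, theta, residues, sigmas):
        pops, kex, r1, r2, shifts = self._unpack(theta, residues)
        res = []
        for p, sig in zip(self.profiles, sigmas):
            omega_major, domega = shifts[p.residue]
            model = self._model_for(pops, kex, r1, r2, omega_major, domega)
            sim = simulate_cest(model, p.b1_hz, p.offsets_ppm, p.t_sat,
                                p.spectrometer_mhz)
            res.append((sim.intensity_ratio - p.intensity_ratio) / sig)
        return np.concatenate(res)

    def fit(self, p0: float = 0.05, kex0: float = 50.0) -> CESTFitResult:
        if not self.profiles:
            raise ValueError("all profiles excluded as showing no exchange")
        m = self.n_states - 1
        residues = sorted({p.residue for p in self.profiles})
        sigmas = [self.noise_sd if self.noise_sd is not None
                  else max(p.noise_sd(), 1e-4) for p in self.profiles]

        # initial shift guesses from dip positions of the lowest-B1 profile
        theta0, lo, hi = [], [], []
        n_free_pops = 1 if (self.fix_minor_ratio is not None and m == 2) else m
        theta0 += [p0] * n_free_pops
        lo += [1e-4] * n_free_pops
        hi += [0.45] * n_free_pops
        theta0 += [np.log10(kex0)] * m
        lo += [-1.0] * m
        hi += [4.0] * m
        if self.vary_relaxation:
            theta0 += [self.r1, self.r2]
            lo += [0.01, 0.1]
            hi += [20.0, 200.0]
        for res in residues:
            prof = min((p for p in self.profiles if p.residue == res),
                       key=lambda p: p.b1_hz)
            dips = _find_dips(prof, self.n_states)
            major = dips[0]
            theta0.append(major)
            lo.append(major - 3.0)
            hi.append(major + 3.0)
            guesses = dips[1:] + [major + 3.0] * (m - len(dips) + 1)
            for g in guesses[:m]:
                theta0.append(g - major)
                lo.append(-40.0)
                hi.append(40.0)

        sol = optimize.least_squares(
            self._residuals, theta0, bounds=(lo, hi), args=(residues, sigmas),
            x_scale="jac",
        )
        pops, kex, _, _, shifts = self._unpack(sol.x, residues)

        n_obs = sum(len(p.offsets_ppm) for p in self.profiles)
        dof = max(n_obs - len(sol.x), 1)
        rchi2 = float(2.0 * sol.cost / dof)

        # standard errors via jacobian covariance
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * max(rchi2, 1.0)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(len(sol.x), np.nan)
        n_free_pops = 1 if (self.fix_minor_ratio is not None and m == 2) else m
        pops_se = se[:n_free_pops]
        if self.fix_minor_ratio is not None and m == 2:
            pops_se = np.array([pops_se[0], pops_se[0] * self.fix_minor_ratio])
        kex_se = 10.0 ** np.array(sol.x[n_free_pops:n_free_pops + m]) \
            * np.log(10.0) * se[n_free_pops:n_free_pops + m]

        flags = []
        if not sol.success:
            flags.append("optimizer did not report convergence")
        depth_scale = float(np.min([p.intensity_ratio.min() for p in self.profiles]))
        if np.all(pops < 2e-4) or depth_scale > 0.98:
            flags.append("unidentifiable: profiles carry no exchange signature")

        rows = []
        for res in residues:
            omega_major, domega = shifts[res]
            for s in range(m):
                rows.append({"residue": res, "state": s + 1,
                             "omega_major_ppm": omega_major,
                             "domega_ppm": float(domega[s])})
        shifts_df = pd.DataFrame(rows)

        return CESTFitResult(
            n_states=self.n_states, populations=pops, populations_se=pops_se,
            kex=kex, kex_se=np.asarray(kex_se), shifts=shifts_df,
            rchi2=rchi2, excluded=self.excluded, flags=flags,
            converged=bool(sol.success),
        )


def fit_cest(profiles: list[CESTProfile], n_states: int = 2,
             **kwargs) -> CESTFitResult:
    """Global fit of a residue group's profiles; see :class:`CESTModel`."""
    return CESTModel(profiles, n_states=n_states, **kwargs).fit()


def extract_csp(fit: CESTFitResult,
                significance: float = CSP_SIGNIFICANCE_PPM) -> pd.DataFrame:
    """Per-residue |domega| with a significance mask.

    Returns a frame with residue, state, csp_ppm and ``significant``
    (|domega| > threshold; the customary 15N threshold is 2.2 ppm).
    """
    out = fit.shifts.copy()
    out["csp_ppm"] = out["domega_ppm"].abs()
    out["significant"] = out["csp_ppm"] > significance
    return out[["residue", "state", "csp_ppm", "significant"]]


def bound_state_shifts(shift_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Partition per-residue bound-state shifts into minimum- and
    maximum-perturbation sets across nuclei.

    ``shift_tables`` maps a nucleus label (e.g. "N", "CA", "CO") to a frame
    with columns residue and domega_ppm (one row per detected bound state).
    For each residue and nucleus the smallest-|domega| value goes to the
    minimum set (trans-assigned) and the largest to the maximum set
    (cis-assigned); residues with a single detected bound state contribute
    the same value to both and are flagged ``degenerate``. Missing nuclei
    are simply absent rows.
    """
    rows = []
    for nucleus, table in shift_tables.items():
        for res, grp in table.groupby("residue"):
            vals = grp["domega_ppm"].to_numpy(dtype=float)
            i_min = int(np.argmin(np.abs(vals)))
            i_max = int(np.argmax(np.abs(vals)))
            rows.append({
                "residue": res, "nucleus": nucleus,
                "trans_shift_ppm": float(vals[i_min]),
                "cis_shift_ppm": float(vals[i_max]),
                "degenerate": len(vals) < 2,
            })
    return pd.DataFrame(rows).sort_values(["nucleus", "residue"],
                                          ignore_index=True)
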