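"""Synthetic-data generators for every input kind the analysis stages
consume, each with a serializable ground truth and a deterministic seed.

Defaults emulate the real experimental designs: an 18 x 2 uL titration with
a discarded 0.5 uL initial injection at ~15 uM cell and 10x syringe
concentration; CEST at three B1 fields (25, 12.5, 6.25 Hz); stopped-flow
with >= 20 replicate traces per condition; HSQC titrations at constant
receptor; and a multinomial sorted tiling screen with 40/10 windows.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .cest import CESTProfile, ExchangeModel, ExchangeState, simulate_cest
from .constants import T_REF
from .stoppedflow import KineticTrace
from .thermo import ITCExperiment, TemperatureSeries, ThermoParams, wiseman_isotherm
from .tiling import TileScreen, tile_sequence
from .titration import TitrationSeries, bound_fraction, csp

__all__ = [
    "GroundTruth",
    "gen_itc",
    "gen_temperature_series",
    "gen_cest",
    "gen_traces",
    "gen_displacement_traces",
    "gen_titration",
    "gen_tilescreen",
]


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic dataset."""

    kind: str
    params: dict
    noise: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=_jsonable)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

def gen_itc(
    n_value: float = 0.98,
    kd: float = 510e-9,
    dh: float = -50.7,
    *,
    cell_concentration: float = 15e-6,
    syringe_concentration: float = 150e-6,
    cell_volume: float = 200e-6,
    n_injections: int = 18,
    injection_volume: float = 2.0e-6,          # 2.0 uL in litres
    first_injection_volume: float = 0.5e-6,
    offset: float = 0.0,
    temperature: float = T_REF,
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[ITCExperiment, GroundTruth]:
    """Synthetic single-site titration with Gaussian heat noise.

    ``noise_fraction`` scales the noise SD relative to the largest
    noiseless injection heat. Default binding parameters correspond to a
    sub-micromolar bivalent-fragment interaction (Kd 510 nM, dH -50.7
    kJ/mol, N 0.98).
    """
    volumes = np.concatenate([[first_injection_volume],
                              np.full(n_injections, injection_volume)])
    exp = ITCExperiment(
        cell_concentration=cell_concentration,
        syringe_concentration=syringe_concentration,
        cell_volume=cell_volume,
        injection_volumes=volumes,
        temperature=temperature,
        discard_first=True,
    )
    params = ThermoParams(n_value=n_value, kd=kd, dh=dh, temperature=temperature)
    heats = wiseman_isotherm(params, exp, offset=offset)
    noise_sd = noise_fraction * float(np.max(np.abs(heats)))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    exp.measured_heats = heats
    truth = GroundTruth(
        kind="itc",
        params={"n_value": n_value, "kd": kd, "dh": dh, "offset": offset,
                "temperature": temperature},
        noise={"heat_sd_kJ": noise_sd, "fraction": noise_fraction},
        seed=seed,
    )
    return exp, truth


def gen_temperature_series(
    dh_ref: float = -50.7,
    tds_neg_ref: float = 14.8,
    dcp: float = -2.0,
    *,
    temperatures=(283.15, 288.15, 293.15, 298.15, 303.15),
    t_ref: float = T_REF,
    n_value: float = 1.0,
    dh_noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "synthetic",
) -> tuple[TemperatureSeries, GroundTruth]:
    """Thermodynamically consistent multi-temperature parameter series.

    dH(T) is linear with slope ``dcp`` (kJ/mol/K); dS(T) follows
    dS_ref + dCp*ln(T/T_ref) so the derived Kd stays consistent. Gaussian
    noise (``dh_noise_sd`` kJ/mol) is applied to dH and -TdS independently.
    """
    from .constants import R_GAS

    rng = np.random.default_rng(seed)
    ds_ref = -(tds_neg_ref * 1000.0) / t_ref   # J/mol/K
    entries = []
    for t in temperatures:
        dh_t = dh_ref + dcp * (t - t_ref)
        ds_t = ds_ref + dcp * 1000.0 * np.log(t / t_ref)
        dg_t = dh_t - t * ds_t / 1000.0
        if dh_noise_sd > 0:
            dh_t += rng.normal(0.0, dh_noise_sd)
            dg_t += rng.normal(0.0, dh_noise_sd / 3.0)
        kd_t = float(np.exp(dg_t * 1000.0 / (R_GAS * t)))
        entries.append((t, ThermoParams(n_value=n_value, kd=kd_t, dh=dh_t,
                                        temperature=t)))
    series = TemperatureSeries(entries=entries, label=label)
    truth = GroundTruth(
        kind="temperature_series",
        params={"dh_ref": dh_ref, "tds_neg_ref": tds_neg_ref, "dcp": dcp,
                "t_ref": t_ref, "temperatures": list(temperatures)},
        noise={"dh_sd": dh_noise_sd}, seed=seed,
    )
    return series, truth


# ---------------------------------------------------------------------------
# CEST
# ---------------------------------------------------------------------------

def gen_cest(
    residue_domegas: dict[str, tuple[float, ...]],
    populations: tuple[float, ...] = (0.036,),
    kex: tuple[float, ...] = (60.0,),
    *,
    b1_fields=(25.0, 12.5, 6.25),
    offsets=None,
    t_sat: float = 0.4,
    r1: float = 1.5,
    r2: float = 10.0,
    spectrometer_mhz: float = 81.08,
    noise_sd: float = 0.0,
    seed: int = 0,
    isomer_tag: str = "",
) -> tuple[list[CESTProfile], GroundTruth]:
    """Synthetic CEST profiles for a residue group sharing kinetics.

    ``residue_domegas`` maps residue labels to bound-state shift
    differences (ppm, one per minor state); populations and kex are shared
    across the group. Gaussian noise is added to the intensity ratios.
    """
    if offsets is None:
        offsets = np.linspace(-12.0, 12.0, 81)
    offsets = np.asarray(offsets, dtype=float)
    rng = np.random.default_rng(seed)
    p_free = 1.0 - float(np.sum(populations))
    profiles = []
    for res, domegas in residue_domegas.items():
        if len(domegas) != len(populations):
            raise ValueError("one shift per minor state per residue")
        states = [ExchangeState("free", p_free, 0.0, r1, r2)]
        rates = {}
        for m, (p, kx, dw) in enumerate(zip(populations, kex, domegas)):
            states.append(ExchangeState(f"bound{m + 1}", p, dw, r1, r2))
            rates[(0, m + 1)] = kx
        model = ExchangeModel(states, rates)
        for b1 in b1_fields:
            prof = simulate_cest(model, b1, offsets, t_sat, spectrometer_mhz,
                                 residue=res, isomer_tag=isomer_tag)
            if noise_sd > 0:
                prof.intensity_ratio = prof.intensity_ratio + rng.normal(
                    0.0, noise_sd, size=prof.intensity_ratio.shape)
            profiles.append(prof)
    truth = GroundTruth(
        kind="cest",
        params={"residue_domegas": {k: list(v) for k, v in residue_domegas.items()},
                "populations": list(populations), "kex": list(kex),
                "b1_fields": list(b1_fields), "t_sat": t_sat,
                "r1": r1, "r2": r2},
        noise={"intensity_sd": noise_sd}, seed=seed,
    )
    return profiles, truth


# ---------------------------------------------------------------------------
# stopped-flow
# ---------------------------------------------------------------------------

def gen_traces(
    kon: float = 29e6,          # M^-1 s^-1
    koff: float = 15.0,         # s^-1
    *,
    concentrations=(0.5e-6, 1e-6, 1.5e-6, 2e-6, 2.5e-6, 3e-6),
    n_replicates: int = 20,
    n_points: int = 200,
    amplitude: float = 1.0,
    baseline: float = 0.2,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[dict[float, list[KineticTrace]], GroundTruth]:
    """Pseudo-first-order association traces, kobs = kon*[R] + koff.

    Returns {receptor concentration: replicate traces}. Trace duration
    spans ~5 relaxation times of the slowest condition.
    """
    rng = np.random.default_rng(seed)
    kobs_min = kon * min(concentrations) + koff
    t_end = 5.0 / kobs_min
    time = np.linspace(0.0, t_end, n_points)
    out: dict[float, list[KineticTrace]] = {}
    for c in concentrations:
        kobs = kon * c + koff
        traces = []
        for _ in range(n_replicates):
            y = baseline + amplitude * np.exp(-kobs * time)
            y = y + rng.normal(0.0, noise_sd * amplitude, size=y.shape)
            traces.append(KineticTrace(time, y, condition=c))
        out[c] = traces
    truth = GroundTruth(
        kind="association_traces",
        params={"kon": kon, "koff": koff,
                "concentrations": list(concentrations),
                "amplitude": amplitude, "baseline": baseline},
        noise={"fluorescence_sd": noise_sd * amplitude}, seed=seed,
    )
    return out, truth


def gen_displacement_traces(
    koff_phases=(14.0,),
    amplitudes=(1.0,),
    *,
    competitor_concentrations=(2e-6, 5e-6, 10e-6, 20e-6, 40e-6, 80e-6),
    c0: float = 5e-6,
    n_replicates: int = 20,
    n_points: int = 300,
    baseline: float = 0.1,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[dict[float, list[KineticTrace]], GroundTruth]:
    """Competitive-displacement traces, mono- or biphasic.

    Each phase's observed rate approaches its koff with competitor
    concentration as ``koff * (1 - exp(-c/c0))``-style saturation (encoded
    as the asymptotic form koff - koff*exp(-c/c0)); pass two phases for a
    bivalent construct.
    """
    rng = np.random.default_rng(seed)
    koff_phases = tuple(koff_phases)
    amplitudes = tuple(amplitudes)
    if len(koff_phases) != len(amplitudes):
        raise ValueError("one amplitude per phase")
    k_slowest = min(k * (1.0 - np.exp(-min(competitor_concentrations) / c0))
                    for k in koff_phases)
    t_end = 5.0 / max(k_slowest, 1e-3)
    time = np.linspace(0.0, t_end, n_points)
    out: dict[float, list[KineticTrace]] = {}
    for c in competitor_concentrations:
        rates = [k * (1.0 - np.exp(-c / c0)) for k in koff_phases]
        traces = []
        for _ in range(n_replicates):
            y = np.full_like(time, baseline)
            for a, k in zip(amplitudes, rates):
                y = y + a * np.exp(-k * time)
            y = y + rng.normal(0.0, noise_sd * sum(amplitudes), size=y.shape)
            traces.append(KineticTrace(time, y, condition=c))
        out[c] = traces
    truth = GroundTruth(
        kind="displacement_traces",
        params={"koff_phases": list(koff_phases), "amplitudes": list(amplitudes),
                "c0": c0,
                "competitor_concentrations": list(competitor_concentrations)},
        noise={"fluorescence_sd": noise_sd * sum(amplitudes)}, seed=seed,
    )
    return out, truth


# ---------------------------------------------------------------------------
# titration
# ---------------------------------------------------------------------------

def gen_titration(
    residue_truth: dict | None = None,
    *,
    receptor_total: float = 125e-6,
    ligand_totals=(0.0, 50e-6, 125e-6, 250e-6, 500e-6, 1e-3, 2e-3, 4e-3, 8e-3),
    shift_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[TitrationSeries, GroundTruth]:
    """Synthetic HSQC titration with per-residue single-site isotherms.

    ``residue_truth`` maps residue id to (kd molar, max dH ppm, max dN ppm);
    the default emulates two affinity regimes (hundreds of uM at one site,
    a few mM at the other). Gaussian noise is applied to each shift axis.
    """
    if residue_truth is None:
        residue_truth = {}
        for i, res in enumerate(range(500, 510)):
            residue_truth[res] = (300e-6, 0.12 + 0.01 * i, 0.6 + 0.05 * i)
        for i, res in enumerate(range(600, 610)):
            residue_truth[res] = (4.5e-3, 0.10 + 0.01 * i, 0.5 + 0.05 * i)
    rng = np.random.default_rng(seed)
    rows = []
    for res, (kd, max_h, max_n) in residue_truth.items():
        for pt, lig in enumerate(ligand_totals):
            fb = 0.0 if lig == 0 else float(
                bound_fraction(lig, receptor_total, kd))
            dh = max_h * fb
            dn = max_n * fb
            if shift_noise_sd > 0 and pt > 0:
                dh += rng.normal(0.0, shift_noise_sd)
                dn += rng.normal(0.0, shift_noise_sd / 0.154)
            rows.append({"residue": res, "point_index": pt,
                         "ligand_total": lig, "dh_ppm": dh, "dn_ppm": dn,
                         "intensity": 1.0})
    series = TitrationSeries(pd.DataFrame(rows), receptor_total=receptor_total)
    truth = GroundTruth(
        kind="titration",
        params={"residue_truth": {str(k): list(v)
                                  for k, v in residue_truth.items()},
                "receptor_total": receptor_total,
                "ligand_totals": list(ligand_totals)},
        noise={"shift_sd_ppm": shift_noise_sd}, seed=seed,
    )
    return series, truth


# ---------------------------------------------------------------------------
# tiling screen
# ---------------------------------------------------------------------------

def gen_tilescreen(
    activity=None,
    *,
    sequence_length: int = 335,
    window: int = 40,
    step: int = 10,
    n_bins: int = 8,
    depth: int = 2000,
    bin_medians=None,
    seed: int = 0,
) -> tuple[TileScreen, GroundTruth]:
    """Multinomial sorted-screen counts with bin probabilities monotone in
    true activity.

    ``activity`` is a per-residue activity profile (array of length
    ``sequence_length``, arbitrary scale in [0, 1]); a tile's activity is
    its residues' mean. Each tile's reads are multinomial over bins with a
    Gaussian kernel centred proportionally to activity, so more active
    tiles concentrate in higher-fluorescence bins.
    """
    if activity is None:
        activity = np.zeros(sequence_length)
        activity[249:270] = 1.0    # residues 250-270
        activity[319:335] = 0.9    # residues 320-335
    activity = np.asarray(activity, dtype=float)
    if len(activity) != sequence_length:
        raise ValueError("activity profile must cover the sequence")
    if bin_medians is None:
        bin_medians = np.linspace(0.2, 4.0, n_bins)
    bin_medians = np.asarray(bin_medians, dtype=float)

    tiles = tile_sequence(sequence_length, window=window, step=step)
    rng = np.random.default_rng(seed)
    centers = np.arange(n_bins)
    counts = np.zeros((len(tiles), n_bins), dtype=float)
    tile_activity = []
    for i, (s, e) in enumerate(tiles):
        a = float(np.mean(activity[s - 1:e]))
        tile_activity.append(a)
        mu = a * (n_bins - 1)
        probs = np.exp(-0.5 * ((centers - mu) / 1.2) ** 2)
        probs /= probs.sum()
        counts[i] = rng.multinomial(depth, probs)
    screen = TileScreen(tiles=tiles, counts=counts, bin_medians=bin_medians,
                        sequence_length=sequence_length)
    truth = GroundTruth(
        kind="tilescreen",
        params={"tile_activity": tile_activity, "sequence_length": sequence_length,
                "window": window, "step": step, "depth": depth,
                "bin_medians": bin_medians.tolist()},
        seed=seed,
    )
    return screen, truth
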