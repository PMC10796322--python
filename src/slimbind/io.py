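"""Plain-text readers and writers for the tabular dialects the analysis
stages consume.

All files are CSV. Experiment-level metadata (concentrations, volumes,
temperature) travels in ``# key: value`` comment lines at the top of the
file, so a dataset is one self-contained text file.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .cest import CESTProfile
from .stoppedflow import KineticTrace
from .thermo import ITCExperiment
from .tiling import TileScreen
from .titration import TitrationSeries

__all__ = [
    "read_itc_csv", "write_itc_csv",
    "read_cest_csv", "write_cest_csv",
    "read_traces_csv", "write_traces_csv",
    "read_titration_csv", "write_titration_csv",
    "read_tilescreen_csv", "write_tilescreen_csv",
]


def _read_header(path) -> tuple[dict, str]:
    meta: dict[str, str] = {}
    body = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
        else:
            body.append(line)
    return meta, "\n".join(body)


def _write(path, meta: dict, frame: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        frame.to_csv(fh, index=False)


# --- ITC -------------------------------------------------------------------

def read_itc_csv(path) -> ITCExperiment:
    """Columns injection_index, volume_uL, heat_uJ; header keys cell_uM,
    syringe_uM, cell_volume_mL, temperature_C, discard_first."""
    meta, body = _read_header(path)
    df = pd.read_csv(_io.StringIO(body)).sort_values("injection_index")
    return ITCExperiment(
        cell_concentration=float(meta["cell_uM"]) * 1e-6,
        syringe_concentration=float(meta["syringe_uM"]) * 1e-6,
        cell_volume=float(meta["cell_volume_mL"]) * 1e-3,
        injection_volumes=df["volume_uL"].to_numpy() * 1e-6,
        measured_heats=df["heat_uJ"].to_numpy() * 1e-9,   # uJ -> kJ
        temperature=float(meta.get("temperature_C", 25.0)) + 273.15,
        discard_first=meta.get("discard_first", "true").lower() != "false",
    )


def write_itc_csv(path, exp: ITCExperiment) -> None:
    frame = pd.DataFrame({
        "injection_index": np.arange(1, exp.n_injections + 1),
        "volume_uL": exp.injection_volumes * 1e6,
        "heat_uJ": (exp.measured_heats * 1e9
                    if exp.measured_heats is not None
                    else np.full(exp.n_injections, np.nan)),
    })
    _write(path, {
        "cell_uM": exp.cell_concentration * 1e6,
        "syringe_uM": exp.syringe_concentration * 1e6,
        "cell_volume_mL": exp.cell_volume * 1e3,
        "temperature_C": exp.temperature - 273.15,
        "discard_first": exp.discard_first,
    }, frame)


# --- CEST ------------------------------------------------------------------

def read_cest_csv(path) -> list[CESTProfile]:
    """Columns residue, isomer_tag, b1_hz, offset_ppm, intensity_ratio;
    header keys t_sat_s, spectrometer_mhz."""
    meta, body = _read_header(path)
    df = pd.read_csv(_io.StringIO(body), keep_default_na=False)
    t_sat = float(meta.get("t_sat_s", 0.4))
    mhz = float(meta.get("spectrometer_mhz", 81.08))
    profiles = []
    for (res, tag, b1), grp in df.groupby(["residue", "isomer_tag", "b1_hz"]):
        grp = grp.sort_values("offset_ppm")
        profiles.append(CESTProfile(
            b1_hz=float(b1), t_sat=t_sat,
            offsets_ppm=grp["offset_ppm"].to_numpy(),
            intensity_ratio=grp["intensity_ratio"].to_numpy(),
            spectrometer_mhz=mhz, residue=str(res), isomer_tag=str(tag),
        ))
    return profiles


def write_cest_csv(path, profiles: list[CESTProfile]) -> None:
    frames = []
    for p in profiles:
        frames.append(pd.DataFrame({
            "residue": p.residue, "isomer_tag": p.isomer_tag,
            "b1_hz": p.b1_hz, "offset_ppm": p.offsets_ppm,
            "intensity_ratio": p.intensity_ratio,
        }))
    _write(path, {
        "t_sat_s": profiles[0].t_sat,
        "spectrometer_mhz": profiles[0].spectrometer_mhz,
    }, pd.concat(frames, ignore_index=True))


# --- stopped-flow ----------------------------------------------------------

def read_traces_csv(path) -> list[KineticTrace]:
    """Columns trace_id, time_s, fluorescence, condition_uM."""
    _, body = _read_header(path)
    df = pd.read_csv(_io.StringIO(body))
    traces = []
    for _, grp in df.groupby("trace_id"):
        grp = grp.sort_values("time_s")
        traces.append(KineticTrace(
            time=grp["time_s"].to_numpy(),
            fluorescence=grp["fluorescence"].to_numpy(),
            condition=float(grp["condition_uM"].iloc[0]) * 1e-6,
        ))
    return traces


def write_traces_csv(path, traces: list[KineticTrace]) -> None:
    frames = []
    for i, t in enumerate(traces):
        frames.append(pd.DataFrame({
            "trace_id": i, "time_s": t.time, "fluorescence": t.fluorescence,
            "condition_uM": t.condition * 1e6,
        }))
    _write(path, {}, pd.concat(frames, ignore_index=True))


# --- titration -------------------------------------------------------------

def read_titration_csv(path) -> TitrationSeries:
    """Columns residue, point_index, ligand_uM, dH_ppm, dN_ppm[, intensity];
    header key receptor_uM."""
    meta, body = _read_header(path)
    df = pd.read_csv(_io.StringIO(body))
    df = df.rename(columns={"ligand_uM": "ligand_total",
                            "dH_ppm": "dh_ppm", "dN_ppm": "dn_ppm"})
    df["ligand_total"] = df["ligand_total"] * 1e-6
    return TitrationSeries(df, receptor_total=float(meta["receptor_uM"]) * 1e-6)


def write_titration_csv(path, series: TitrationSeries) -> None:
    df = series.data.copy()
    df["ligand_uM"] = df.pop("ligand_total") * 1e6
    df = df.rename(columns={"dh_ppm": "dH_ppm", "dn_ppm": "dN_ppm"})
    _write(path, {"receptor_uM": series.receptor_total * 1e6}, df)


# --- tiling screen ---------------------------------------------------------

def read_tilescreen_csv(path) -> TileScreen:
    """Columns tile_id, start, end, bin_1..bin_K; header key bin_medians
    (comma-separated)."""
    meta, body = _read_header(path)
    df = pd.read_csv(_io.StringIO(body)).sort_values("tile_id")
    bin_cols = [c for c in df.columns if c.startswith("bin_")]
    medians = np.array([float(x) for x in meta["bin_medians"].split(",")])
    seq_len = int(meta["sequence_length"]) if "sequence_length" in meta else None
    return TileScreen(
        tiles=[(int(s), int(e)) for s, e in zip(df["start"], df["end"])],
        counts=df[bin_cols].to_numpy(),
        bin_medians=medians,
        sequence_length=seq_len,
    )


def write_tilescreen_csv(path, screen: TileScreen) -> None:
    n_bins = screen.counts.shape[1]
    frame = pd.DataFrame({
        "tile_id": np.arange(len(screen.tiles)),
        "start": [s for s, _ in screen.tiles],
        "end": [e for _, e in screen.tiles],
    })
    for b in range(n_bins):
        frame[f"bin_{b + 1}"] = screen.counts[:, b].astype(int)
    meta = {"bin_medians": ",".join(f"{m:g}" for m in screen.bin_medians)}
    if screen.sequence_length is not None:
        meta["sequence_length"] = screen.sequence_length
    _write(path, meta, frame)
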