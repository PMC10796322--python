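"""Activation-domain tiling-screen scoring.

A protein sequence is tiled into overlapping windows (40 residues, step
10), each tile drives a reporter in a sorted dual-fluorescence screen, and
the sorting-bin abundance profile of each tile is collapsed to an
activation (AD) score: the abundance-weighted mean of the bin fluorescence
ratios, z-normalized across tiles. Residue-level scores average all
covering tiles, and AD regions are runs of residues whose *every* covering
tile clears a threshold.

Coordinates are 1-based inclusive throughout, matching residue numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TileScreen",
    "tile_sequence",
    "ad_score",
    "residue_scores",
    "call_ad_regions",
]


def tile_sequence(sequence_length: int, window: int = 40,
                  step: int = 10) -> list[tuple[int, int]]:
    """Tile coordinates (1-based inclusive) over a sequence.

    Tiles start at 1, 1+step, ... . When the last regular tile does not
    reach the C-terminus, a final tile anchored at the C-terminus is added
    so every residue is covered. A sequence shorter than the window yields
    one full-length tile with a warning.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if sequence_length < window:
        warnings.warn("sequence shorter than the tiling window; "
                      "returning a single full-length tile")
        return [(1, sequence_length)]
    starts = list(range(1, sequence_length - window + 2, step))
    tiles = [(s, s + window - 1) for s in starts]
    if tiles[-1][1] < sequence_length:
        tiles.append((sequence_length - window + 1, sequence_length))
    return tiles


@dataclass
class TileScreen:
    """Per-tile sorting-bin abundances and bin fluorescence medians.

    ``counts``: tiles x bins abundance matrix (reads); ``bin_medians``:
    median reporter ratio (e.g. GFP:mCherry) of each sorting bin;
    ``tiles``: 1-based inclusive (start, end) per row of ``counts``.
    """

    tiles: list[tuple[int, int]]
    counts: np.ndarray
    bin_medians: np.ndarray
    sequence_length: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.bin_medians = np.asarray(self.bin_medians, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.tiles):
            raise ValueError("counts must be (n_tiles, n_bins)")
        if self.counts.shape[1] != len(self.bin_medians):
            raise ValueError("bin medians must match the bin count")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def ad_score(screen: TileScreen) -> np.ndarray:
    """Per-tile z-scored activation scores.

    Counts are normalized to fractions within each tile (depth
    normalization), dotted with the bin medians, then z-scored across
    tiles. Tiles with zero total counts get NaN and are excluded from the
    z-normalization.
    """
    totals = screen.counts.sum(axis=1)
    raw = np.full(len(totals), np.nan)
    ok = totals > 0
    fractions = screen.counts[ok] / totals[ok, None]
    raw[ok] = fractions @ screen.bin_medians
    mu = np.nanmean(raw)
    sd = np.nanstd(raw, ddof=0)
    if sd == 0:
        z = np.where(np.isnan(raw), np.nan, 0.0)
    else:
        z = (raw - mu) / sd
    return z


def residue_scores(tile_scores: np.ndarray,
                   tiles: list[tuple[int, int]]) -> pd.Series:
    """Per-residue score: mean of all covering tiles' scores.

    Residues covered by no tile (or only NaN-scored tiles) are absent from
    the result, not zero.
    """
    tile_scores = np.asarray(tile_scores, dtype=float)
    acc: dict[int, list[float]] = {}
    for (start, end), s in zip(tiles, tile_scores):
        if np.isnan(s):
            continue
        for r in range(start, end + 1):
            acc.setdefault(r, []).append(s)
    idx = sorted(acc)
    return pd.Series([float(np.mean(acc[r])) for r in idx], index=idx,
                     name="ad_score")


def call_ad_regions(tile_scores: np.ndarray, tiles: list[tuple[int, int]],
                    threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of residues for which every covering tile scores above
    ``threshold`` (1-based inclusive)."""
    tile_scores = np.asarray(tile_scores, dtype=float)
    covered: dict[int, bool] = {}
    for (start, end), s in zip(tiles, tile_scores):
        if np.isnan(s):
            continue
        ok = s > threshold
        for r in range(start, end + 1):
            covered[r] = covered.get(r, True) and ok
    qualifying = sorted(r for r, all_above in covered.items() if all_above)
    regions: list[tuple[int, int]] = []
    for r in qualifying:
        if regions and r == regions[-1][1] + 1:
            regions[-1] = (regions[-1][0], r)
        else:
            regions.append((r, r))
    return regions
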