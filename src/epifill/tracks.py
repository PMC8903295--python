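"""Population-averaged occupancy tracks and their binarization.

ChIP-style modification data is a population average: each nucleosome has
an occupancy level between full presence and full absence of the mark
across the cell population.  To feed such a track into the single-cell
model it is normalized to [0, 1] and then binarized into an ensemble of
single-cell-like realizations, drawing each position as modified with
probability equal to its normalized occupancy (independently per position
and realization — the minimal randomized discretization whose ensemble
average reproduces the track).  Markov parameters of the underlying mark
can then be estimated from the realizations.

Tracks are read from bedGraph (chrom, start, end, value; 0-based
half-open) or two-column TSV (index, value); intervals map to consecutive
nucleosome indices in file order and strand is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .markov import MarkovParams, estimate_params

__all__ = [
    "OccupancyTrack",
    "read_track",
    "normalize_track",
    "discretize",
    "estimate_from_track",
]


@dataclass(frozen=True)
class OccupancyTrack:
    """Ordered per-nucleosome occupancy values (arbitrary nonnegative units)."""

    values: np.ndarray
    positions: np.ndarray | None = None  # optional genomic/nucleosome labels

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("track values must be a nonempty 1-D array")
        if np.any(vals < 0):
            raise ValueError("occupancy values must be nonnegative")
        object.__setattr__(self, "values", vals)
        if self.positions is not None:
            pos = np.asarray(self.positions)
            if pos.size != vals.size:
                raise ValueError("positions and values must align")
            object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return int(self.values.size)


def read_track(path) -> OccupancyTrack:
    """Read a bedGraph (4 columns) or two-column TSV track.

    Malformed rows are reported with their line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise ValueError(f"{path}: cannot parse track: {exc}") from exc
    if df.shape[1] == 4:
        starts, values = df[1], df[3]
        bad = values.isna() | pd.to_numeric(values, errors="coerce").isna()
        if bad.any():
            raise ValueError(f"{path}: malformed value at line {int(bad.idxmax()) + 1}")
        return OccupancyTrack(values.to_numpy(float), positions=starts.to_numpy())
    if df.shape[1] == 2:
        values = pd.to_numeric(df[1], errors="coerce")
        if values.isna().any():
            raise ValueError(
                f"{path}: malformed value at line {int(values.isna().idxmax()) + 1}"
            )
        return OccupancyTrack(values.to_numpy(float), positions=df[0].to_numpy())
    raise ValueError(f"{path}: expected 2 (TSV) or 4 (bedGraph) columns, got {df.shape[1]}")


def normalize_track(track: OccupancyTrack, saturation: float | None = None) -> OccupancyTrack:
    """Scale occupancies into [0, 1].

    Divides by the track maximum, or by ``saturation`` if given; values
    above the saturation level are clipped to 1.  All-zero tracks cannot
    be normalized.
    """
    scale = float(track.values.max()) if saturation is None else float(saturation)
    if scale <= 0:
        raise ValueError("cannot normalize: track maximum / saturation is not positive")
    return OccupancyTrack(np.clip(track.values / scale, 0.0, 1.0), positions=track.positions)


def discretize(track: OccupancyTrack, n_realizations: int, seed) -> list[np.ndarray]:
    """Binarize a normalized track into single-cell-like realizations.

    Position i of each realization is 1 with probability ``values[i]``,
    independently across positions and realizations, so the ensemble
    occupancy profile converges to the track itself.
    """
    vals = track.values
    if vals.max() > 1.0:
        raise ValueError("track must be normalized to [0, 1] before discretization")
    if n_realizations < 1:
        raise ValueError(f"n_realizations must be >= 1, got {n_realizations}")
    rng = np.random.default_rng(seed)
    draws = rng.random((n_realizations, vals.size)) < vals
    return [row.astype(np.int8) for row in draws]


def estimate_from_track(track: OccupancyTrack, n_realizations: int, seed) -> MarkovParams:
    """Estimate (alpha, beta) of the mark from a normalized track by
    discretizing and pooling transition counts over the realizations.

    The realizations carry no positional correlation beyond the track
    itself, so the estimates reflect the track's island structure.
    """
    return estimate_params(discretize(track, n_realizations, seed))
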