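"""Synthetic inputs for tests and offline experiments.

Everything downstream of raw ChIP processing can be emulated here:
ternary mothers carrying two antagonistic marks, bistable cell
populations, and island-structured occupancy tracks standing in for
population-averaged experimental data.  Every generator is fully
determined by its parameters and seed.
"""

from __future__ import annotations

import numpy as np

from .channel import replicate
from .markov import MarkovParams, generate_mother
from .tracks import OccupancyTrack

__all__ = [
    "make_ternary_mother",
    "make_bistable_ensemble",
    "make_two_level_track",
]


def make_ternary_mother(
    params: MarkovParams,
    n: int,
    seed,
    gap_params: MarkovParams | None = None,
) -> np.ndarray:
    """Mother with two spatially distinct antagonistic marks (1 and 2).

    A binary chain at (alpha, beta) is relabelled so that its 1-runs carry
    mark 1 and its 0-runs carry mark 2, giving long alternating stretches
    of the two marks with every nucleosome modified.  If ``gap_params`` is
    given, a second independent chain at those parameters punches genuinely
    unmodified (0) stretches into the mother where it is 0 — a non-default
    variant for mothers that are not fully covered.
    """
    base = generate_mother(params, n, seed)
    mother = np.where(base == 1, 1, 2).astype(np.int8)
    if gap_params is not None:
        child = np.random.SeedSequence(seed).spawn(1)[0]
        cover = generate_mother(gap_params, n, child)
        mother = np.where(cover == 1, mother, 0).astype(np.int8)
    return mother


def make_bistable_ensemble(
    n_cells: int,
    n: int,
    high_params: MarkovParams,
    low_params: MarkovParams,
    seed,
) -> list[np.ndarray]:
    """Ensemble emulating a bistable cell population.

    Half the mothers come from a high-occupancy chain and half from a
    low-occupancy chain, so the per-cell mean-modification histogram is
    bimodal; replication plus correction should preserve that bimodality.
    """
    if n_cells % 2 != 0:
        raise ValueError(f"n_cells must be even, got {n_cells}")
    streams = np.random.SeedSequence(seed).spawn(n_cells)
    half = n_cells // 2
    return [
        generate_mother(high_params if i < half else low_params, n, streams[i])
        for i in range(n_cells)
    ]


def make_two_level_track(
    n: int, island_len: int, gap_len: int, high: float, low: float
) -> OccupancyTrack:
    """Deterministic island/gap occupancy track.

    A synthetic stand-in for a population-averaged modification track
    (e.g. an H3K27me3 profile): alternating islands of occupancy ``high``
    (length ``island_len``) and gaps of occupancy ``low`` (length
    ``gap_len``), truncated at ``n`` positions.
    """
    if not (high > low >= 0):
        raise ValueError("need high > low >= 0")
    if island_len < 1 or gap_len < 1 or n < 1:
        raise ValueError("n, island_len and gap_len must be >= 1")
    period = np.concatenate(
        [np.full(island_len, float(high)), np.full(gap_len, float(low))]
    )
    reps = int(np.ceil(n / period.size))
    return OccupancyTrack(np.tile(period, reps)[:n])


def replicate_ensemble(mothers, spec, seed) -> list[np.ndarray]:
    """Replicate each mother once with an element-wise reproducible
    child stream per mother."""
    streams = np.random.SeedSequence(seed).spawn(len(mothers))
    return [replicate(m, spec, s) for m, s in zip(mothers, streams)]
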