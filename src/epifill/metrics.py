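"""Reconstruction-fidelity metrics.

The basic deviation between a mother M and a reconstruction M-hat is the
per-position mismatch fraction Δ = (1/N) Σ (m_i - m̂_i)² — the bit error
rate (BER).  For ternary (two-mark) sequences any symbol mismatch counts
as one error.  Block error coarse-grains the comparison: positions are cut
into consecutive blocks and per-block modification densities are compared,
which forgives position-level shuffling within a block; at block size 1 it
is exactly the BER.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markov import as_sequence

__all__ = ["ErrorReport", "ber", "mean_ensemble_error", "block_error", "occupancy_profile"]


@dataclass(frozen=True)
class ErrorReport:
    """Ensemble-averaged reconstruction error."""

    ber: float
    n_sequences: int
    se: float
    block_errors: dict[int, float] = field(default_factory=dict)


def ber(mother, estimate) -> float:
    """Bit error rate: fraction of positions whose symbol differs."""
    m = as_sequence(mother, alphabet=3)
    e = as_sequence(estimate, alphabet=3)
    if m.size != e.size:
        raise ValueError(f"length mismatch: {m.size} vs {e.size}")
    return float(np.mean(m != e))


def mean_ensemble_error(mothers, estimates) -> ErrorReport:
    """Mean BER over paired (mother, estimate) sequences, with its SE."""
    errors = np.array([ber(m, e) for m, e in zip(mothers, estimates, strict=True)])
    if errors.size == 0:
        raise ValueError("empty ensemble")
    se = float(errors.std(ddof=1) / np.sqrt(errors.size)) if errors.size > 1 else 0.0
    return ErrorReport(ber=float(errors.mean()), n_sequences=int(errors.size), se=se)


def block_error(mother, estimate, block: int) -> float:
    """Mean absolute per-block density difference.

    Blocks are consecutive, the trailing block may be shorter and is
    averaged with its true length.  ``block=1`` reduces exactly to BER.
    """
    if block < 1:
        raise ValueError(f"block must be >= 1, got {block}")
    m = as_sequence(mother, alphabet=3).astype(float)
    e = as_sequence(estimate, alphabet=3).astype(float)
    if m.size != e.size:
        raise ValueError(f"length mismatch: {m.size} vs {e.size}")
    if block == 1:
        return ber(mother, estimate)
    diffs = [
        abs(m[i : i + block].mean() - e[i : i + block].mean())
        for i in range(0, m.size, block)
    ]
    return float(np.mean(diffs))


def occupancy_profile(ensemble) -> np.ndarray:
    """Per-position mean modification level across an ensemble of
    equal-length binary sequences (the population-averaged occupancy)."""
    seqs = [as_sequence(s) for s in ensemble]
    if not seqs:
        raise ValueError("empty ensemble")
    lengths = {s.size for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length")
    return np.mean(np.stack(seqs), axis=0)
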