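"""Enzyme-implementable decoders: the threshold-k filling rule.

For a flanked run ``(1, 0_k, 1)`` the SMAP decoder reduces to comparing
the all-ones candidate path against the all-zeros one.  The metric
difference

    g_k(alpha, beta) = (alpha/2)^(k+1) - (1/2)(1-alpha) beta^(k-1) (1-beta)

(at retention 1/2) is positive exactly when filling the run is the more
probable reconstruction.  Treating k as real, ``g_k = 0`` has the unique
root

    k* = log((1-alpha)(1-beta) / (alpha^2/2)) / log(alpha / (2 beta)) + 1,

and ``g_k > 0`` for every integer ``k <= k*`` when ``g_1 > 0`` and
``alpha < 2 beta``.  This turns exact Bayesian decoding into a rule an
enzyme could plausibly execute: fill every unmodified island of length at
most ``floor(k*)`` between two modified nucleosomes, leave longer islands
alone.  The (alpha, beta) unit square splits into four regimes:

* ``a`` (g_1 > 0, alpha >= 2 beta): fill every flanked island (Type-I
  enzyme, unbounded threshold);
* ``b`` (g_1 > 0, alpha < 2 beta): threshold-k filling with finite k*
  (Type-II enzyme) — the biologically realistic regime where both
  persistence parameters are close to 1;
* ``c`` (g_1 <= 0, alpha <= 2 beta): fill nothing;
* ``d`` (g_1 <= 0, alpha > 2 beta): intermediate filling, only the full
  SMAP decoder applies.

Boundary curves are assigned to the non-filling side; on alpha == 2 beta
the sign of g_k is k-independent, so the line belongs with region a when
g_1 > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .markov import MarkovParams, as_sequence
from .trellis import segment_decompose

__all__ = [
    "ThresholdRule",
    "g_k",
    "k_star",
    "classify_region",
    "optimal_threshold",
    "threshold_fill",
    "fill_all",
    "antagonistic_fill",
]

FILL_ALL = math.inf  # sentinel threshold: fill every flanked island


@dataclass(frozen=True)
class ThresholdRule:
    """Fill flanked zero-runs of length at most ``k_t``.

    ``k_t = 0`` fills nothing; ``k_t = math.inf`` (the ``FILL_ALL``
    sentinel) fills every flanked run.
    """

    k_t: float

    def __post_init__(self) -> None:
        if self.k_t < 0:
            raise ValueError(f"k_t must be >= 0, got {self.k_t}")


def g_k(params: MarkovParams, k: int | float) -> float:
    """Path-metric margin of all-ones over all-zeros for ``(1, 0_k, 1)``."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    a, b = params.alpha, params.beta
    return (a / 2.0) ** (k + 1) - 0.5 * (1.0 - a) * b ** (k - 1) * (1.0 - b)


def k_star(params: MarkovParams) -> float:
    """Closed-form real root of ``g_k = 0``.

    Only meaningful as a filling threshold in region b; raises
    ``ValueError`` when ``alpha == 2 beta`` (no finite root) or when
    ``g_1 <= 0`` (no island is worth filling).
    """
    a, b = params.alpha, params.beta
    if not (0.0 < a < 1.0 and 0.0 < b < 1.0):
        raise ValueError("k* requires 0 < alpha < 1 and 0 < beta < 1")
    if a == 2.0 * b:
        raise ValueError("alpha = 2*beta: g_k never crosses zero (no finite root)")
    if g_k(params, 1) <= 0.0:
        raise ValueError("g_1 <= 0: region not threshold-fillable")
    return math.log((1.0 - a) * (1.0 - b) / (a * a / 2.0)) / math.log(a / (2.0 * b)) + 1.0


def classify_region(params: MarkovParams) -> str:
    """Regime label 'a'/'b'/'c'/'d' of an interior (alpha, beta) point."""
    a, b = params.alpha, params.beta
    if not (0.0 < a < 1.0 and 0.0 < b < 1.0):
        raise ValueError("classification requires 0 < alpha, beta < 1")
    pos = g_k(params, 1) > 0.0
    if pos:
        return "a" if a >= 2.0 * b else "b"
    return "d" if a > 2.0 * b else "c"


def optimal_threshold(params: MarkovParams) -> ThresholdRule:
    """The SMAP-equivalent filling threshold for the point's regime:
    ``floor(k*)`` in region b, unbounded in region a, 0 in c and d."""
    region = classify_region(params)
    if region == "a":
        return ThresholdRule(FILL_ALL)
    if region == "b":
        return ThresholdRule(math.floor(k_star(params)))
    return ThresholdRule(0)


def threshold_fill(daughter, rule: ThresholdRule) -> np.ndarray:
    """Fill every flanked zero-run of length ``<= rule.k_t`` with 1s."""
    d = as_sequence(daughter)
    out = d.copy()
    for seg in segment_decompose(d):
        if seg.k <= rule.k_t:
            out[seg.start + 1 : seg.end] = 1
    return out


def fill_all(daughter) -> np.ndarray:
    """Type-I enzyme: fill every flanked zero-run regardless of length."""
    return threshold_fill(daughter, ThresholdRule(FILL_ALL))


def antagonistic_fill(daughter, rule: ThresholdRule) -> np.ndarray:
    """Threshold filling for two antagonistic marks coded 1 and 2.

    Each mark's enzyme sees the other mark as absence: a zero-run of
    length ``<= k_t`` flanked on both sides by the *same* mark v is filled
    with v; discordantly flanked runs stay unfilled.  Both fills are read
    off the original daughter, so the two enzymes commute and can never
    claim the same position.
    """
    d = as_sequence(daughter, alphabet=3)
    out = d.copy()
    for mark in (1, 2):
        own = (d == mark).astype(np.int8)
        for seg in segment_decompose(own):
            # flanked by `mark` on both sides; fill only if the gap is
            # genuinely unmodified (the other mark blocks the enzyme)
            gap = d[seg.start + 1 : seg.end]
            if seg.k <= rule.k_t and np.all(gap == 0):
                assert np.all(out[seg.start + 1 : seg.end] == 0)
                out[seg.start + 1 : seg.end] = mark
    return out
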