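"""Sequence-MAP reconstruction of the mother chromatin by trellis decoding.

Given a daughter ``D`` produced by the dilution channel, the sequence-MAP
(SMAP) estimate is the mother maximizing the posterior

    P(M | D)  ∝  Π_i P(m_i | m_{i-1}) · P(d_i | m_i),

i.e. the product over positions of the Markov transition probability and
the channel likelihood.  Because the channel never creates marks, every
observed 1 pins ``m_i = 1``, and the global maximization factorizes over
the runs of zeros flanked by observed 1s: each flanked run ``(1, 0_k, 1)``
is decoded independently on a two-state trellis by the Viterbi algorithm.
Zero-runs touching a sequence boundary have no flanking evidence on one
side and are left unfilled.

``brute_force_map`` provides an exhaustive-enumeration oracle that scores
candidate mothers by the same posterior without any trellis machinery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from math import inf, log

import numpy as np

from .markov import DegenerateChainError, MarkovParams, as_sequence, stationary_distribution

__all__ = [
    "TrellisSegment",
    "branch_metric",
    "segment_decompose",
    "decode_segment",
    "smap_decode",
    "brute_force_map",
]


def _log(p: float) -> float:
    return log(p) if p > 0.0 else -inf


# Distinct candidate paths can have mathematically identical posterior
# products (permutations of the same transition multiset, or coincidences
# like alpha*(1-retention) == beta), and float log-sums then disagree at
# the last ulp depending on summation order.  Scores closer than this are
# re-compared in exact rational arithmetic so that the deterministic
# lexicographic tie-break (prefer 0, from the left) is applied to true
# ties only, identically in the trellis and in the enumeration oracle.
_TIE_TOL = 1e-9


def _exact_branch(params: MarkovParams, retention: float):
    """Branch metrics P(m, d | m_prev) as exact rationals, [m_prev][m][d]."""
    a, b, r = (Fraction(x) for x in (params.alpha, params.beta, retention))
    one = Fraction(1)
    trans = {(0, 0): b, (0, 1): one - b, (1, 0): one - a, (1, 1): a}
    emit = {(0, 0): one, (0, 1): Fraction(0), (1, 0): one - r, (1, 1): r}
    return {
        (mp, m, d): trans[(mp, m)] * emit[(m, d)]
        for mp in (0, 1)
        for m in (0, 1)
        for d in (0, 1)
    }


def _exact_segment_score(
    params: MarkovParams, retention: float, path, close: bool
) -> Fraction:
    """Exact posterior product of an interior path (left flank state 1;
    the final transition into the right flank included when ``close``)."""
    branch = _exact_branch(params, retention)
    score = Fraction(1)
    prev = 1
    for m in path:
        score *= branch[(prev, m, 0)]
        prev = m
    if close:
        score *= branch[(prev, 1, 1)]
    return score


def _prefer(score_a, path_a, score_b, path_b, exact_fn) -> bool:
    """True if candidate a beats incumbent b (exact-tie-aware)."""
    both_impossible = score_a == -inf and score_b == -inf
    if not both_impossible:
        if score_a > score_b + _TIE_TOL:
            return True
        if score_b > score_a + _TIE_TOL:
            return False
    ea, eb = exact_fn(path_a), exact_fn(path_b)
    if ea != eb:
        return ea > eb
    return path_a < path_b


@dataclass(frozen=True)
class TrellisSegment:
    """A flanked zero-run in the daughter: observed 1s at ``start`` and
    ``end`` (0-based), with ``k = end - start - 1 >= 1`` zeros strictly
    between them."""

    start: int
    end: int

    @property
    def k(self) -> int:
        return self.end - self.start - 1


def branch_metric(
    params: MarkovParams, m_prev: int, m: int, d: int, retention: float = 0.5
) -> float:
    """Per-transition trellis weight ``P(m, d | m_prev)``.

    Factorizes as ``P(m | m_prev) * P(d | m)`` with the channel law
    ``P(d=1|m=1) = retention``, ``P(d=0|m=1) = 1 - retention``,
    ``P(d=0|m=0) = 1`` and ``P(d=1|m=0) = 0`` (marks are never created).
    """
    trans = params.transition_matrix[m_prev, m]
    if m == 1:
        emit = retention if d == 1 else 1.0 - retention
    else:
        emit = 0.0 if d == 1 else 1.0
    return trans * emit


def segment_decompose(daughter) -> list[TrellisSegment]:
    """Maximal interior zero-runs flanked by observed 1s, left to right.

    Leading/trailing zero-runs are excluded (no flanking evidence); an
    all-zero or all-one daughter yields an empty list.
    """
    d = as_sequence(daughter)
    ones = np.flatnonzero(d == 1)
    segments = []
    for left, right in zip(ones[:-1], ones[1:]):
        if right - left > 1:
            segments.append(TrellisSegment(int(left), int(right)))
    return segments


_SEGMENT_CACHE: dict[tuple[float, float, float, int], np.ndarray] = {}


def decode_segment(params: MarkovParams, k: int, retention: float = 0.5) -> np.ndarray:
    """Viterbi-decode the interior of a flanked run ``(1, 0_k, 1)``.

    Runs the two-state Viterbi recursion over the ``k`` interior stages
    (all with observation ``d = 0``) plus the final transition into the
    right flank (``d = 1``), and returns the argmax interior path over all
    ``2^k`` candidates.  Metric ties are broken toward the lexicographically
    smallest path (0 before 1, from the left), i.e. toward fewer fills.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    key = (params.alpha, params.beta, retention, k)
    cached = _SEGMENT_CACHE.get(key)
    if cached is not None:
        return cached.copy()

    # log branch metrics for interior stages (d = 0), indexed [prev][cur]
    lb = [
        [_log(branch_metric(params, 0, 0, 0, retention)),
         _log(branch_metric(params, 0, 1, 0, retention))],
        [_log(branch_metric(params, 1, 0, 0, retention)),
         _log(branch_metric(params, 1, 1, 0, retention))],
    ]
    # final transition into the observed right-flank 1 (d = 1)
    fin = [_log(branch_metric(params, 0, 1, 1, retention)),
           _log(branch_metric(params, 1, 1, 1, retention))]

    def exact_open(path):
        return _exact_segment_score(params, retention, path, close=False)

    def exact_closed(path):
        return _exact_segment_score(params, retention, path, close=True)

    # survivor per state: (log score, path tuple); left flank is state 1
    best: list[tuple[float, tuple[int, ...]] | None] = [None, (0.0, ())]
    for _ in range(k):
        new: list[tuple[float, tuple[int, ...]] | None] = [None, None]
        for cur in (0, 1):
            for prev in (0, 1):
                if best[prev] is None:
                    continue
                score = best[prev][0] + lb[prev][cur]
                path = best[prev][1] + (cur,)
                if new[cur] is None or _prefer(score, path, new[cur][0], new[cur][1], exact_open):
                    new[cur] = (score, path)
        best = new
    final: tuple[float, tuple[int, ...]] | None = None
    for prev in (0, 1):
        if best[prev] is None:
            continue
        score = best[prev][0] + fin[prev]
        path = best[prev][1]
        if final is None or _prefer(score, path, final[0], final[1], exact_closed):
            final = (score, path)
    assert final is not None
    path_arr = np.array(final[1], dtype=np.int8)
    _SEGMENT_CACHE[key] = path_arr
    return path_arr.copy()


def smap_decode(params: MarkovParams, daughter, retention: float = 0.5) -> np.ndarray:
    """Sequence-MAP mother estimate for a whole daughter sequence.

    Observed 1s are kept, each flanked zero-run is replaced by its
    Viterbi-decoded interior, and boundary zero-runs stay unfilled.
    """
    d = as_sequence(daughter)
    out = d.copy()
    for seg in segment_decompose(d):
        out[seg.start + 1 : seg.end] = decode_segment(params, seg.k, retention)
    return out


def brute_force_map(
    params: MarkovParams,
    daughter,
    retention: float = 0.5,
    fill_boundary: bool = False,
) -> np.ndarray:
    """Exhaustive-enumeration MAP oracle (no trellis).

    Scores candidate mothers by the full posterior product — the
    stationary prior on ``m_1`` followed by transition and channel terms —
    and returns the maximizer, ties broken toward the lexicographically
    smallest mother.  By default candidates range over the decoder's
    hypothesis class: mothers agreeing with the daughter everywhere except
    on flanked interior zero-runs, which are enumerated jointly.  With
    ``fill_boundary=True`` every zero position is free (the unconstrained
    sequence MAP, which may also fill boundary runs).

    Refuses more than 20 free positions (2^20 enumeration).
    """
    d = as_sequence(daughter)
    if fill_boundary:
        free = np.flatnonzero(d == 0)
    else:
        spans = [np.arange(s.start + 1, s.end) for s in segment_decompose(d)]
        free = np.concatenate(spans) if spans else np.array([], dtype=int)
    if free.size > 20:
        raise ValueError(f"{free.size} free positions: enumeration refused (> 20)")

    try:
        p0, p1 = stationary_distribution(params)
    except DegenerateChainError:
        p0 = p1 = 0.5
    log_prior = np.array([_log(p0), _log(p1)])
    log_trans = np.array(
        [[_log(x) for x in row] for row in params.transition_matrix]
    )
    # channel log-likelihood indexed [m, d]
    log_emit = np.array(
        [[0.0, -inf], [_log(1.0 - retention), _log(retention)]]
    )

    if free.size == 0:
        return d.copy()
    cands = np.array(list(itertools.product((0, 1), repeat=free.size)), dtype=np.int8)
    mothers = np.broadcast_to(d, (cands.shape[0], d.size)).copy()
    mothers[:, free] = cands
    scores = log_prior[mothers[:, 0]] + log_emit[mothers[:, 0], d[0]]
    for i in range(1, d.size):
        scores = scores + log_trans[mothers[:, i - 1], mothers[:, i]]
        scores = scores + log_emit[mothers[:, i], d[i]]

    # resolve near-ties exactly (see _TIE_TOL): among candidates whose
    # float log-score is within tolerance of the maximum, maximize the
    # exact rational posterior; candidates are in lexicographic order, so
    # the first exact maximizer is the lex-smallest.
    top = float(scores.max())
    if top == -inf:
        return mothers[0].copy()
    contenders = np.flatnonzero(scores >= top - _TIE_TOL)
    if contenders.size == 1:
        return mothers[int(contenders[0])].copy()
    branch = _exact_branch(params, retention)
    a, b = Fraction(params.alpha), Fraction(params.beta)
    denom = 2 - a - b
    prior = {0: Fraction(1, 2), 1: Fraction(1, 2)} if denom == 0 else {
        0: (1 - a) / denom, 1: (1 - b) / denom
    }
    emit_exact = {
        (0, 0): Fraction(1), (0, 1): Fraction(0),
        (1, 0): 1 - Fraction(retention), (1, 1): Fraction(retention),
    }
    best_idx, best_exact = None, None
    for idx in contenders:
        m = mothers[idx]
        exact = prior[int(m[0])] * emit_exact[(int(m[0]), int(d[0]))]
        for i in range(1, d.size):
            exact *= branch[(int(m[i - 1]), int(m[i]), int(d[i]))]
        if best_exact is None or exact > best_exact:
            best_idx, best_exact = idx, exact
    return mothers[int(best_idx)].copy()
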