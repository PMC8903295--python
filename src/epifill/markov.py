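"""First-order Markov model of a histone-modification pattern.

A stretch of chromatin is modelled as a binary sequence ``m_1 .. m_N``
(1 = nucleosome carries the mark, 0 = it does not) generated by a
homogeneous first-order Markov chain with two persistence parameters:

* ``alpha`` — probability that a modified nucleosome is followed by a
  modified one, ``P(m_i = 1 | m_{i-1} = 1)``;
* ``beta`` — probability that an unmodified nucleosome is followed by an
  unmodified one, ``P(m_i = 0 | m_{i-1} = 0)``.

High ``alpha`` and ``beta`` produce the long modified domains separated by
long unmodified gaps that are typical of repressive marks such as H3K27me3.
The mean contiguous run lengths are ``1/(1-alpha)`` (modified) and
``1/(1-beta)`` (unmodified), so the pair is directly estimable from data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MarkovParams",
    "DegenerateChainError",
    "InestimableParameterError",
    "stationary_distribution",
    "generate_mother",
    "estimate_params",
    "mean_run_lengths",
    "as_sequence",
]


class DegenerateChainError(ValueError):
    """The chain has no unique stationary law (alpha = beta = 1)."""


class InestimableParameterError(ValueError):
    """No transition out of a state was observed, so its persistence
    probability cannot be estimated.

    The parameter that *was* estimable (if any) is attached as the
    ``alpha`` / ``beta`` attribute.
    """

    def __init__(self, message: str, alpha: float | None = None, beta: float | None = None):
        super().__init__(message)
        self.alpha = alpha
        self.beta = beta


@dataclass(frozen=True)
class MarkovParams:
    """Persistence probabilities of the two-state mother chain."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")

    @property
    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic matrix ``T[prev, next]`` over states (0, 1)."""
        return np.array(
            [[self.beta, 1.0 - self.beta], [1.0 - self.alpha, self.alpha]]
        )


def as_sequence(values, alphabet: int = 2) -> np.ndarray:
    """Coerce ``values`` to an int8 array over ``{0 .. alphabet-1}``.

    Raises ``ValueError`` on out-of-alphabet symbols or empty input.
    """
    arr = np.asarray(values, dtype=np.int8)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("sequence must be a nonempty 1-D array")
    if arr.min() < 0 or arr.max() >= alphabet:
        raise ValueError(f"symbols must lie in 0..{alphabet - 1}")
    return arr


def stationary_distribution(params: MarkovParams) -> tuple[float, float]:
    """Stationary law ``(P(0), P(1))`` of the mother chain.

    For a chain with persistence ``(alpha, beta)`` the unique stationary
    distribution is ``((1-alpha)/(2-alpha-beta), (1-beta)/(2-alpha-beta))``,
    provided not both states are absorbing.
    """
    denom = 2.0 - params.alpha - params.beta
    if denom == 0.0:
        raise DegenerateChainError(
            "alpha = beta = 1: both states absorbing, no unique stationary law"
        )
    p0 = (1.0 - params.alpha) / denom
    return (p0, 1.0 - p0)


def generate_mother(params: MarkovParams, n: int, seed) -> np.ndarray:
    """Draw a mother sequence of ``n`` nucleosomes.

    The first state is drawn from the stationary law (uniform in the
    degenerate alpha = beta = 1 case) so that single-site statistics are
    position-invariant; subsequent states follow the transition law.
    The same seed always yields the same sequence.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    try:
        _, p1 = stationary_distribution(params)
    except DegenerateChainError:
        p1 = 0.5
    u = rng.random(n)
    out = np.empty(n, dtype=np.int8)
    out[0] = u[0] < p1
    # P(next=1 | prev): alpha if prev==1 else 1-beta
    p_one = np.array([1.0 - params.beta, params.alpha])
    for i in range(1, n):
        out[i] = u[i] < p_one[out[i - 1]]
    return out


def estimate_params(sequences) -> MarkovParams:
    """Maximum-likelihood ``(alpha, beta)`` pooled over sequences.

    ``alpha_hat = n11 / (n11 + n10)`` and ``beta_hat = n00 / (n00 + n01)``
    where ``n_xy`` counts transitions from state x to state y; transitions
    never cross sequence boundaries.

    Raises ``InestimableParameterError`` if a state has no outgoing
    transitions anywhere in the pool.
    """
    if isinstance(sequences, np.ndarray) and sequences.ndim == 1:
        sequences = [sequences]
    from_one = 0
    one_one = 0
    from_zero = 0
    zero_zero = 0
    for seq in sequences:
        s = as_sequence(seq)
        prev, nxt = s[:-1], s[1:]
        from_one += int((prev == 1).sum())
        one_one += int(((prev == 1) & (nxt == 1)).sum())
        from_zero += int((prev == 0).sum())
        zero_zero += int(((prev == 0) & (nxt == 0)).sum())
    if from_one == 0:
        beta_hat = zero_zero / from_zero if from_zero else None
        raise InestimableParameterError(
            "no transitions out of state 1: alpha inestimable", beta=beta_hat
        )
    if from_zero == 0:
        raise InestimableParameterError(
            "no transitions out of state 0: beta inestimable", alpha=one_one / from_one
        )
    return MarkovParams(one_one / from_one, zero_zero / from_zero)


def mean_run_lengths(params: MarkovParams) -> tuple[float, float]:
    """Mean contiguous run lengths ``(1/(1-alpha), 1/(1-beta))``.

    Run lengths are geometric under the chain, so the means diverge as a
    persistence probability approaches 1; ``alpha == 1`` or ``beta == 1``
    raises ``ValueError`` (infinite runs).
    """
    if params.alpha >= 1.0 or params.beta >= 1.0:
        raise ValueError("alpha = 1 or beta = 1 gives infinite mean runs")
    return (1.0 / (1.0 - params.alpha), 1.0 / (1.0 - params.beta))
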