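import itertools

import numpy as np
import pytest

from epifill import MarkovParams


@pytest.fixture(scope="session")
def realistic_params() -> MarkovParams:
    """High-persistence regime typical of repressive marks."""
    return MarkovParams(0.9, 0.9)


def all_binary_sequences(n: int):
    """Every binary sequence of length n, lexicographic order."""
    for bits in itertools.product((0, 1), repeat=n):
        yield np.array(bits, dtype=np.int8)


def numeric_k_root(params, brentq) -> float:
    """Numeric root of g_k = 0, treating k as real.

    Solved on the log-margin (log of the all-ones metric minus log of the
    all-zeros metric), which has the same unique root as g_k but stays
    well-scaled when the root is large and both metric terms underflow.
    """
    import math

    a, b = params.alpha, params.beta

    def log_margin(k: float) -> float:
        return (
            (k + 1) * math.log(a / 2)
            - math.log(0.5 * (1 - a) * (1 - b))
            - (k - 1) * math.log(b)
        )

    hi = 2.0
    while log_margin(hi) > 0:
        hi *= 2.0
    return brentq(log_margin, 1.0, hi, xtol=1e-12)


def region_b_pairs(rng: np.random.Generator, count: int):
    """Random (alpha, beta) pairs with g_1 > 0 and alpha < 2*beta."""
    from epifill import g_k

    pairs = []
    while len(pairs) < count:
        a, b = rng.uniform(0.05, 0.99, 2)
        p = MarkovParams(a, b)
        if a < 2 * b and g_k(p, 1) > 0:
            pairs.append(p)
    return pairs
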