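"""The replication "dilution channel".

At the replication fork each parental nucleosome, with its (H3-H4)2
tetramer assumed symmetrically modified, lands on the tracked daughter
strand with probability ``retention`` (one coin per nucleosome); otherwise
the position receives a fresh, unmodified nucleosome.  The daughter is
therefore ``d_i = m_i * z_i`` with ``z_i`` IID Bernoulli(retention): marks
can be lost but never created, a memoryless asymmetric channel.  The
biological retention probability is 1/2; it is kept configurable for
sensitivity analyses of unequal strand partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import as_sequence

__all__ = ["ChannelSpec", "replicate", "replicate_ternary", "iterate_generations"]


@dataclass(frozen=True)
class ChannelSpec:
    """Per-nucleosome probability that the parental mark is retained."""

    retention: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.retention <= 1.0):
            raise ValueError(f"retention must be in [0, 1], got {self.retention}")


def replicate(mother, spec: ChannelSpec = ChannelSpec(), seed=None) -> np.ndarray:
    """One round of replication: ``d = m AND z``, z IID Bernoulli(retention)."""
    m = as_sequence(mother)
    rng = np.random.default_rng(seed)
    z = rng.random(m.size) < spec.retention
    return (m & z).astype(np.int8)


def replicate_ternary(mother, spec: ChannelSpec = ChannelSpec(), seed=None) -> np.ndarray:
    """Replication for two antagonistic marks coded 1 and 2.

    Each nonzero symbol survives independently with probability
    ``retention``; lost nucleosomes become 0 (fresh histones carry neither
    mark). Zeros pass through unchanged.
    """
    m = as_sequence(mother, alphabet=3)
    rng = np.random.default_rng(seed)
    keep = rng.random(m.size) < spec.retention
    return np.where(keep, m, 0).astype(np.int8)


def iterate_generations(
    mother,
    spec: ChannelSpec,
    corrector,
    generations: int,
    seed,
) -> list[np.ndarray]:
    """Propagate a lineage through repeated replication + correction.

    Generation g replicates the corrected sequence of generation g-1
    (generation 1 replicates the mother itself), then applies
    ``corrector`` (any map from daughter to mother-like sequence; pass
    ``lambda d: d`` for no correction).  Returns the corrected sequence of
    each generation, in order; errors are conventionally measured against
    the original mother.

    Per-generation child seeds are spawned deterministically from ``seed``.
    """
    if generations < 1:
        raise ValueError(f"generations must be >= 1, got {generations}")
    parent = as_sequence(mother)
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = root.spawn(generations)
    lineage: list[np.ndarray] = []
    for g in range(generations):
        daughter = replicate(parent, spec, seed=streams[g])
        parent = as_sequence(corrector(daughter))
        lineage.append(parent)
    return lineage
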