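# epifill

Information-theoretic modelling of histone-modification inheritance.

During DNA replication each daughter chromatin inherits only about half of
the parental nucleosomes, and with them only about half of the parental
histone marks (H3K27me3, H3K9me3, …).  Yet modification patterns are
re-established with high fidelity.  `epifill` treats this as a
communication problem: the parental pattern is a message, replication is a
noisy channel that deletes marks, and the cell's read–write enzymes are a
decoder.  The package is aimed at computational chromatin biologists and
modellers who want to simulate this process, decode diluted patterns
optimally, and ask what rule a realistic enzyme would have to implement to
match the optimal decoder.

## Model

* **Mother chain.**  The parental pattern `M = (m_1 … m_N)`, `m_i ∈ {0,1}`,
  is a first-order homogeneous Markov chain with persistence parameters
  `α = P(m_i = 1 | m_{i−1} = 1)` and `β = P(m_i = 0 | m_{i−1} = 0)`.
  Mean modified / unmodified run lengths are `1/(1−α)` and `1/(1−β)`.
* **Replication channel.**  `d_i = m_i · z_i` with `z_i` IID
  Bernoulli(½): marks are lost, never created (an asymmetric deletion
  channel; the retention probability is configurable).
* **Sequence-MAP decoding.**  The reconstruction `M̂ = argmax P(M | D)`
  with `P(M|D) ∝ Π_i P(m_i|m_{i−1}) P(d_i|m_i)` factorizes over runs of
  zeros flanked by observed ones and is computed exactly by a two-state
  Viterbi recursion per flanked run (`smap_decode`), validated against an
  exhaustive enumeration oracle (`brute_force_map`).
* **Threshold-k filling.**  For a flanked island `(1, 0_k, 1)` the margin
  `g_k(α,β) = (α/2)^{k+1} − ½(1−α)β^{k−1}(1−β)` is positive exactly when
  filling wins; its real root is
  `k* = log[(1−α)(1−β)/(α²/2)] / log[α/(2β)] + 1`.
  Where `g_1 > 0` and `α < 2β` — the biologically realistic regime —
  SMAP decoding reduces to the enzyme-implementable rule *fill every
  flanked unmodified island of length ≤ floor(k*)* (`threshold_fill`,
  `k_star`, `classify_region`).
* **Fidelity metrics.**  Bit error rate `Δ = (1/N) Σ (m_i − m̂_i)²`,
  block error (per-block density differences), and ensemble occupancy
  profiles (`epifill.metrics`).
* **Data arm.**  Population-averaged occupancy tracks (bedGraph / TSV)
  are normalized, binarized into single-cell-like realizations, and fed
  through the same pipeline (`epifill.tracks`); ternary sequences model
  two spatially distinct antagonistic marks corrected by independent
  enzymes (`antagonistic_fill`).

## Worked example

```python
import math
from epifill import (MarkovParams, ChannelSpec, ThresholdRule, generate_mother,
                     replicate, smap_decode, threshold_fill, k_star, ber)

params = MarkovParams(0.9, 0.9)          # realistic repressive-mark regime
print(round(k_star(params), 3))          # 6.34  -> integer threshold 6

mother   = generate_mother(params, n=500, seed=1)
daughter = replicate(mother, ChannelSpec(0.5), seed=2)
smap     = smap_decode(params, daughter)
filled   = threshold_fill(daughter, ThresholdRule(math.floor(k_star(params))))

print(round(ber(mother, daughter), 3))   # 0.262  raw post-replication error
print(round(ber(mother, smap), 3))       # 0.120  after exact SMAP decoding
print(bool((smap == filled).all()))      # True   threshold-6 = SMAP, position by position
```

About a quarter of the positions are wrong straight after replication
(half of the ~50% modified positions lose their mark); exact Bayesian
decoding cuts this to ~12%, and the simple filling rule achieves the
identical reconstruction.  The `examples/` directory holds one short
script per capability (generation/replication, decoding, threshold
sweeps, occupancy tracks, antagonistic marks, multi-generation
propagation); each prints the numbers it computes and what they mean.

A thin CLI mirrors the experiment layer:

```bash
epifill threshold-sweep --alpha 0.9 --beta 0.9 --out sweep.tsv
epifill antagonistic --n 500 --k-t 6 --out panel.txt
```

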