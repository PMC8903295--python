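# Methods

## The model and its assumptions

`epifill` models one histone modification at a time along a region of
`N` nucleosomes.  Three ingredients define the model:

1. **Mother chain.**  The parental pattern is a stationary first-order
   two-state Markov chain with persistence probabilities `alpha`
   (modified → modified) and `beta` (unmodified → unmodified).  This
   encodes the nearest-neighbour character of read–write enzyme activity
   and matches the observed island structure of marks such as H3K27me3:
   both parameters close to 1 give long modified domains separated by
   long gaps.  The chain is homogeneous; higher-order or position-
   dependent laws are out of scope.  The first nucleosome is drawn from
   the stationary law `P(1) = (1−β)/(2−α−β)` so single-site statistics
   are position-invariant (in the doubly absorbing case `α = β = 1` the
   initial state is drawn uniformly).
2. **Replication channel.**  Each nucleosome, with its (H3−H4)₂ tetramer
   assumed symmetrically modified, is inherited by the tracked daughter
   strand with probability `retention` (default ½, one coin per
   nucleosome, not per histone copy); otherwise the position receives an
   unmarked nucleosome.  Hence `d_i = m_i · z_i` — a memoryless deletion
   channel that never creates marks.  Only one daughter strand is
   materialized; leading/lagging-strand asymmetry is not modelled, but
   `retention` is exposed for sensitivity analyses.
3. **Decoders.**  The sequence-MAP estimate maximizes
   `P(M|D) ∝ Π P(m_i|m_{i−1}) P(d_i|m_i)`.  Because `P(d=1|m=0) = 0`,
   every observed 1 pins the mother, and the maximization factorizes over
   maximal zero-runs flanked by observed ones; each run `(1, 0_k, 1)` is
   decoded by a two-state Viterbi recursion in `O(k)`.  Zero-runs touching
   a sequence boundary carry no flanking evidence on one side and are left
   unfilled — a posterior for them would hinge on an initial law the
   decoder has no business assuming.  The enzyme-style reduction fills a
   flanked island iff `k ≤ k_t`; with `k_t = floor(k*)` it coincides with
   SMAP in the threshold-fillable regime.

## Parameter regimes

The `(α, β)` unit square splits along the curves `g_1(α,β) = 0` and
`α = 2β` into four regimes (`classify_region`):

| regime | condition | optimal behaviour |
|---|---|---|
| a | `g_1 > 0`, `α ≥ 2β` | fill every flanked island (Type-I enzyme) |
| b | `g_1 > 0`, `α < 2β` | threshold-k filling, `k_t = floor(k*)` (Type-II) |
| c | `g_1 ≤ 0`, `α ≤ 2β` | fill nothing |
| d | `g_1 ≤ 0`, `α > 2β` | intermediate filling; only full SMAP applies |

Boundary curves are assigned to the non-filling side, except the line
`α = 2β` with `g_1 > 0`, where `g_k = β^{k−1} g_1` has a k-independent
sign and fill-all is optimal, so the line belongs with regime a.
`floor(k*)` is the right integer threshold because `g_k > 0` exactly for
integers `k ≤ k*` when `g_1 > 0` (the root is unique).

## Tunable parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `alpha`, `beta` | persistence probabilities (per nucleosome step) | 0.9, 0.9 in experiments | mean island length 10; the realistic repressive-mark regime (regime b; per-nucleosome ChIP data gives ≈ 0.81/0.815 for H3K27me3) |
| `retention` | per-nucleosome inheritance probability | 0.5 | random tetramer segregation between daughter strands |
| `k_t` | fill threshold (0 = nothing, ∞ = everything) | `floor(k*)` = 6 at (0.9, 0.9) | SMAP-equivalent in regime b |
| `n` | region length in nucleosomes | 500–2000 | long enough that boundary runs (~1 nucleosome per end) are negligible |
| ensemble sizes | mothers × daughters per grid point | 30 × 20 desk scale, 300 × 200 full scale | SE of the mean error ≤ 1e−3 at desk scale; `full_scale=True` restores published-quality ensembles |

## Numerical choices

* All path metrics are compared in log space; underflow is impossible for
  the lengths considered.
* **Exact tie-breaking.**  Distinct candidate mothers can have
  mathematically identical posteriors (permutations of the same
  transition multiset, or coincidences such as `α(1−r) = β`), and float
  log-sums then differ at the last ulp depending on summation order.
  Scores within `1e−9` of each other are re-compared in exact rational
  arithmetic (`fractions.Fraction` built from the same float parameters),
  and true ties are broken toward the lexicographically smallest mother
  (prefer unmodified, from the left).  The Viterbi decoder and the
  enumeration oracle share this rule, so their agreement is exact rather
  than rounding-dependent.
* `k*` is evaluated in closed form; the cross-validation root-finder
  works on the log-margin `(k+1)log(α/2) − log(½(1−α)(1−β)) − (k−1)log β`,
  which has the same unique root but stays well-scaled where the raw
  `g_k` underflows (roots beyond ~700 at high persistence).  Near the
  `α = 2β` boundary the root diverges and agreement is asserted in
  relative terms.
* `brute_force_map` enumerates, by default, the decoder's hypothesis
  class (mothers equal to the daughter outside flanked interior
  zero-runs); `fill_boundary=True` frees every zero position, giving the
  unconstrained sequence MAP, which can also fill boundary runs — the two
  conventions coincide on daughters that begin and end with an observed 1.
  Enumeration refuses more than 20 free positions.
* Degenerate inputs: an all-zero daughter decodes to itself; estimating
  `(α, β)` from an ensemble with no transitions out of a state raises an
  `InestimableParameterError` carrying whichever parameter was estimable;
  block error averages a short trailing block with its true length.
* RNG: every experiment takes one seed; per-mother / per-daughter /
  per-generation streams are spawned deterministically
  (`numpy.random.SeedSequence`), so ensembles are reproducible
  element-wise and bit-identical across runs.

## The synthetic-data generators

The generators emulate everything downstream of raw ChIP processing:

* `make_two_level_track` — a deterministic island/gap occupancy profile
  standing in for per-nucleosome population-averaged data (islands of
  occupancy 0.9, gaps of 0.05, period 20 by default in the examples).
* `discretize` — independent Bernoulli sampling per position, the
  minimal randomized binarization whose ensemble average reproduces the
  track.  Its realizations carry **no positional correlation beyond the
  track itself**; parameters estimated from them reflect the track's
  island structure, not any single-cell chain that may have produced the
  average.  In particular a flat track yields `α̂ ≈ β̂ ≈ level`
  regardless of provenance — the tests assert this caveat explicitly.
* `make_ternary_mother` — relabels a binary chain so 1-runs carry mark 1
  and 0-runs carry mark 2, giving a fully covered mother with long
  alternating stretches; this is what makes the uncorrected two-mark
  daughter error ≈ ½ (every position carries a destructible symbol).  A
  non-default `gap_params` variant punches genuinely unmodified
  stretches.
* `make_bistable_ensemble` — half high-occupancy, half low-occupancy
  mothers, emulating a bistable cell population at the ensemble level.

What passing tests on these fixtures do *not* show: robustness to ChIP
noise, to nucleosome-positioning uncertainty, or to replication-coupled
processes (boundary elements, DNA methylation) outside the channel model.

## Design choices made where the design was open

* **Bistable correction threshold.**  Preserving ensemble bimodality
  requires a biologically plausible finite threshold: with the high-state
  parameters (0.95, 0.5), `floor(k*) = 57` and an enzyme filling 57-wide
  gaps floods the sparse low-state cells (their mean rises from ~0.07 to
  ~0.58 and the modes merge), while `k_t = 6` leaves the two modes at
  ~0.07 and ~0.92.  The bistability test therefore corrects with
  `k_t = 6`.
* **Multi-generation propagation.**  Generation `g` replicates the
  corrected output of generation `g−1`; errors are always measured
  against the original mother.  At (0.9, 0.9) with `k_t = 6` the BER
  grows roughly linearly (~0.11, 0.17, 0.21, 0.25, 0.29 over five
  generations at the default seeds) as island edges erode — far below
  the uncorrected ~0.5 level but not negligible.  Block error decreases
  with block size; the block-error ≤ BER inequality is exact per lineage
  only when the block size divides the region length (an unweighted mean
  over blocks over-weights a short trailing block).
* **Antagonistic filling** reads both marks' flanks from the original
  daughter, so the two enzymes commute and can never claim the same
  position; filling only proceeds into genuinely unmodified gaps.
* **Desk-scale problem sizes.**  Default experiment ensembles
  (30 × 20 × N = 1000; 50 × 20 × N = 2000 for the high-persistence
  minimum; 200 daughters for the two-mark panel) were chosen so that
  standard errors sit one to two orders of magnitude below the effects
  being measured; `--full` / `full_scale=True` restores 300 × 200.

## Known limitations

* The decoder assumes the true `(α, β)` are known; estimation error from
  short regions propagates into `k*` and is not modelled.
* Boundary zero-runs are never reconstructed, which inflates the error
  slightly for short regions (~1 nucleosome per end at retention ½).
* The two-mark extension corrects each mark independently; cooperative
  or multi-step enzyme kinetics are not modelled.
* The model is equilibrium-style (most probable configuration), with no
  kinetics: many different kinetic schemes would produce the same
  reconstructions.
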