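# Methods

## Problem and approach

The package selects the *k* smallest values of the Cartesian sum
*X* + *Y* = {*X<sub>i</sub>* + *Y<sub>j</sub>*} of two numeric vectors.
Naive routes cost *O*(*n*² log *n*) (generate and sort) or *O*(*n*²)
(generate and rank-select); the lower bound is Ω(*n* + *k*) since the
input must be read and *k* values returned.  The implementation reaches
that bound with layer-ordered heaps: both vectors are partitioned into
ascending geometric layers, and the grid of layer *products* is swept
through min/max corner sentinels so that only *O*(*k*) candidate sums
are ever generated before one final linear-time selection.

Everything rests on a single primitive, worst-case linear-time rank
selection (`linear_select`): a groups-of-five median-of-medians with a
sort cutoff below length 10.  `partition_by_rank` splits a multiset
around a requested left-part size and distributes duplicates of the
threshold value so part sizes are exact — this tie contract is what lets
the top level return *exactly* k values even when the k-th value is
tied.  Ranks are 0-based in code; the field's "k-th smallest" is
rank k − 1.  Inputs are never mutated.

## Parameters

* **k** — number of sums returned, 0 ≤ k ≤ |X|·|Y|.  k = 0 returns an
  empty result by choice (total function) rather than an error.
* **α (rank, default 2.0)** — limiting ratio of consecutive LOH layer
  sizes; must exceed 1 (α = 1 degenerates to a full sort).  Layer u
  (1-based) has scheduled size ⌈α^(u−1)⌉ with the final layer truncated
  to make sizes sum to n; for α = 2 this is the doubling schedule
  1, 2, 4, …, remainder, and the truncated layer is always the last
  (largest) one.  The ⌈α^(u−1)⌉ realization for fractional α is a design
  choice — any schedule with the right limit ratio would do.  Smaller α
  means costlier LOHify but less overshoot; larger α the reverse.  The
  iterative peel-the-largest-layer construction used here is the optimal
  regime for α ≥ 2; the specialized constructions for α close to 1 are
  out of scope.
* **Corner-key order** — keys are (value, (u, v), flag) with flag
  MIN = 0 < MAX = 1, compared lexicographically.  The layer pair breaks
  value ties deterministically and the flag guarantees ⌊(u,v)⌋ < ⌈(u,v)⌉
  even for a layer product whose values are all equal.  Layer indices
  are 0-based internally, so the origin product is (0, 0).
* **Duplicate prevention** — the sweep keeps an explicit membership set
  keyed by (u, v, flag) alongside the binary heap, mirroring the
  reference formulation; the row-major proposal scheme that would make
  the set unnecessary is used only in the combinatoric-heap baseline.

## Variants

* `select_topk` — the heap-driven sweep (phases 0–3).
* `select_topk_sorted_corners` — sorts all 2·L<sub>x</sub>·L<sub>y</sub>
  corner keys and scans; still *o*(n) for the corner handling and
  returns an identical multiset, but inflates candidates eagerly, which
  costs more when k ≪ n².
* `select_topk_compressed` — stops after phase 2 and returns the
  committed layer products in factored form plus the trace; phases 0–2
  cost *O*(n) independent of k.  Consumers re-derive the LOHs
  (construction is deterministic) to inflate.  Recursive selection on
  the compressed products is not implemented.
* Baselines (`topk_sort`, `topk_select`, `topk_comb_heap`) serve as
  oracles and comparators.  The combinatoric-heap baseline heapifies X
  and Y and proposes pairs row-major through a plain binary priority
  queue — with an exact queue the pops come out sorted, so no
  post-selection is needed.  Soft-heap corruption accounting belongs to
  that replaced queue and is out of scope.

With duplicate-heavy inputs the layer membership of tied values is
implementation-defined (the partition fills counts with threshold
copies); every returned *multiset* is nevertheless exact, which is what
the cross-variant agreement tests assert.

## Overshoot benchmark

The sweep generates s + s′ candidates to find k, so (s + s′)/k measures
overshoot (always ≥ 1; exactly 1 when k = n²).  `overshoot_experiment`
measures it over a 15-configuration grid — n ∈ {1000, 2000, 4000} with
k from n/4 up to 4n — at α = 2, 10 repetitions per configuration, with
the grand mean taken over per-configuration means.  Instances are
uniform random integers in [0, 2²⁰), a range chosen so ties are rare at
these n; per-repetition seeds are spawned from the base seed via NumPy's
`SeedSequence`.  Theory bounds s′ ≤ (α² + 2α)·s + 1 asymptotically; the
test suite monitors that bound at α = 2 and logs rather than asserts it,
since finite instances need not track the asymptotic constant.
Wall-clock timings are recorded per phase for information only and never
asserted — they are hardware-dependent.

## Isotopologue demo

A fragment's isotope peak list holds (mass in Da, probability in (0, 1])
rows with probabilities summing to ≤ 1.  Combined-pair abundance is the
product of peak probabilities, so the k most abundant pairs are the k
smallest sums of the negative-log probabilities (natural log; the base
is irrelevant under a monotone transform).  The core selection returns
values, not index pairs (a deliberate non-goal), so the demo uses the
k-th smallest neg-log sum from `select_topk` as a threshold and recovers
pair identities with a scan over the |A|·|B| grid — sums strictly below
the threshold, plus ties at the threshold trimmed to exactly k.  Both
paths compute each sum with the same floating-point expression, so
threshold equality is consistent.  Returned probabilities are recomputed
as p<sub>A</sub>·p<sub>B</sub> products to avoid exp/log round-trip
error.  Isobaric pairs (equal total mass) are not merged; aggregation is
a separate convolution step outside scope, as are peak-shape modeling
and selection over more than two fragments.

## What the synthetic data does and does not emulate

Random uniform integer vectors exercise the algorithm's combinatorics
fully — the correctness guarantees are distribution-free — but real
isotope distributions are far from uniform (probabilities decay roughly
geometrically across isotopes), and real peak lists carry correlated
mass/probability structure.  Passing tests establish exact multiset
correctness and the expected overshoot behavior, not application-level
performance on any particular compound class.

## Numerical notes and limitations

* Values may be ints (exact) or floats; mixed comparisons follow Python
  semantics and overflow/precision is the caller's contract.
* Output order is unspecified (selection semantics); pass `sort=True`
  or `--sorted` for ascending output.
* Returning the (i, j) index pair of each selected sum, m-vector sums
  X₁ + ⋯ + X<sub>m</sub>, and online/streaming updates are out of scope.
* The problem sizes used by the test suite (vectors ≤ 25 for exhaustive
  oracle comparisons, the 15-configuration grid for the overshoot
  statistic) were chosen as the smallest sizes at which every claimed
  property is actually exercised; the implementation itself has no size
  limits beyond memory.
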