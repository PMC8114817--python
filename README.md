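# lohselect

Optimal top-*k* selection on the Cartesian sum *X* + *Y* with
layer-ordered heaps.

Given two numeric vectors *X* and *Y* of length *n*, the package returns
the *k* smallest pairwise sums *X<sub>i</sub>* + *Y<sub>j</sub>* in
*O*(*n* + *k*) time — without materializing the *n*² sum matrix and
without soft heaps or other exotic data structures.  The only primitive
it relies on is worst-case linear-time rank selection (median of
medians).  The motivating application is mass spectrometry: the *k* most
abundant combined isotopologue pairs of two molecular fragments are
exactly the *k* smallest sums of the fragments' negative-log peak
probabilities, and a demo subcommand does that ranking directly.

## The algorithm

A **layer-ordered heap** (LOH) of rank α > 1 partitions a vector into
ascending layers *X*⁽¹⁾ ≤ *X*⁽²⁾ ≤ …, where every value in a layer is ≤
every value in the next layer, values within a layer stay unordered, and
layer sizes grow geometrically (|*X*⁽¹⁾| = 1, ratio → α; α = 2 gives
1, 2, 4, 8, …).  An LOH is built in linear time by iteratively peeling
off the largest remaining layer with a rank partition.

Selection proceeds in four phases:

* **Phase 0** — LOHify *X* and *Y*.
* **Phase 1** — consider the *layer products* *X*⁽ᵘ⁾ + *Y*⁽ᵛ⁾ through
  their corner keys only: ⌊(u,v)⌋ = (min(*X*⁽ᵘ⁾ + *Y*⁽ᵛ⁾), (u,v), 0) and
  ⌈(u,v)⌉ = (max(*X*⁽ᵘ⁾ + *Y*⁽ᵛ⁾), (u,v), 1), computed from cached layer
  extrema.  A binary min-heap pops corners in ascending order; popping a
  min corner proposes its right/down neighbors and its own max corner,
  and each max-corner pop commits the product's full area
  |*X*⁽ᵘ⁾|·|*Y*⁽ᵛ⁾| into a running total *s*.  Stop when *s* ≥ *k*; the
  last popped value is the threshold τ, an upper bound on the *k*-th
  smallest sum.
* **Phase 2** — every product whose min corner was visited but whose max
  corner is still pending may also contain contenders; commit those too
  (total area *s*′).
* **Phase 3** — inflate the *s* + *s*′ ∈ *O*(*k*) committed candidate
  sums and extract the *k* smallest with one linear-time selection.

The heap only ever touches the *O*(log²n) corner keys, so phases 1–2
cost *o*(*n*); a simplified variant that fully sorts the corner keys
(`select_topk_sorted_corners`) and a compressed mode that stops after
phase 2 and returns the factored layer products (`select_topk_compressed`)
are also provided, along with three baselines: full sort, full
*k*-selection, and lazy binary-heap frontier enumeration.

## Worked example

With *X* = 31,5,11,7,33,6,39,42,20,0,9,1,41,26,8 and
*Y* = 12,26,40,9,14,49,8,2,20,1,46,43,4,5,7 (one value per line in
`x.txt` / `y.txt`):

```sh
$ lohselect select -x x.txt -y y.txt -k 14 --sorted --trace
1
2
2
3
4
5
5
6
6
7
7
7
8
8
s=17 s_prime=16 tau=10 pops=14
```

The 14 values are the 14 smallest of the 225 pairwise sums.  The trace
line (standard error) says phase 1 committed layer products holding
*s* = 17 candidate sums before reaching *k* = 14, phase 2 added *s*′ = 16
more, and the largest corner value visited was τ = 10 — so only 33 of
the 225 sums were ever generated.  The same library calls are available
in Python:

```python
from lohselect import select_topk
result = select_topk(X, Y, k=14, alpha=2, sort=True)
result.values          # [1, 2, 2, 3, 4, 5, 5, 6, 6, 7, 7, 7, 8, 8]
result.trace.tau       # 10
```

The isotopologue demo ranks combined peaks of two fragments (here two
carbon atoms, TSV columns mass and probability):

```sh
$ lohselect isotopes -a carbon.tsv -b carbon.tsv -k 3
24.000000	0.978121
25.003350	0.010879
25.003350	0.010879
```

i.e. ¹²C¹²C at 24 Da with probability 0.989² = 0.978121, then the two
¹²C¹³C pairs — kept distinct, not mass-merged.

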