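"""Top-k selection on the Cartesian sum X + Y via layer-ordered heaps.

The k smallest pairwise sums ``X[i] + Y[j]`` are found without forming the
full |X|x|Y| sum matrix.  Both vectors are first layer-ordered-heapified
(phase 0).  Layer *products* — the Cartesian sums of one layer of X with
one layer of Y — are then explored through their corner keys only: the
min corner of product (u, v) holds the smallest sum the product can
contain, the max corner the largest.  A binary min-heap pops corner keys
in ascending order; popping a min corner proposes the (u+1, v) and
(u, v+1) min corners and the product's own max corner, and each max-corner
pop commits its product's full area toward k (phase 1).  Once the
committed area s reaches k, every product whose min corner was visited
but whose max corner is still pending may also hold contenders and is
committed too (phase 2, area s').  The s + s' candidate sums — O(k) of
them — are inflated and a single linear-time rank selection extracts the
k smallest (phase 3).

Total work is O(n + k): heap traffic touches only the O(log^2 n) corner
keys, never the sums themselves.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Sequence, Tuple, TypeVar

from .linear_select import partition_by_rank
from .loh import LayerOrderedHeap, lohify

T = TypeVar("T")

MIN = 0
MAX = 1

__all__ = [
    "MIN",
    "MAX",
    "CornerKey",
    "LayerProductIndex",
    "SelectionTrace",
    "SelectionResult",
    "corner_keys",
    "phase1_sweep",
    "phase2_collect",
    "inflate_candidates",
    "select_topk",
    "select_topk_sorted_corners",
    "select_topk_compressed",
]


class CornerKey(NamedTuple):
    """Totally ordered corner of a layer product.

    Tuple comparison gives the required order: by sum value, then by
    layer pair, then MIN before MAX — so the two corners of a product
    with homogeneous values still compare strictly.
    """

    value: float
    layer_pair: Tuple[int, int]
    corner: int  # MIN or MAX


class LayerProductIndex(NamedTuple):
    """A layer product identified by its layer pair; area = |X^(u)|*|Y^(v)|."""

    u: int
    v: int
    area: int


@dataclass
class SelectionTrace:
    """Progress record of the corner sweep.

    `q` lists committed layer products — the first `phase1_products`
    entries were committed by max-corner pops (total area `s`), the rest
    during the frontier collection (total area `s_prime`).  `tau` is the
    value of the last corner key popped in phase 1, an upper bound on the
    k-th smallest sum.
    """

    q: List[LayerProductIndex] = field(default_factory=list)
    s: int = 0
    s_prime: int = 0
    tau: Optional[float] = None
    pop_count: int = 0
    phase1_products: int = 0
    popped: Optional[List[CornerKey]] = None  # recorded when instrumented

    @property
    def candidate_count(self) -> int:
        return self.s + self.s_prime


@dataclass
class SelectionResult:
    """The k selected sums plus the sweep trace.

    `values` holds exactly k sums (the k smallest of X + Y as a
    multiset); `compressed` is set instead when inflation was skipped.
    """

    values: Optional[List[T]]
    trace: SelectionTrace
    compressed: Optional[List[LayerProductIndex]] = None


def corner_keys(
    loh_x: LayerOrderedHeap, loh_y: LayerOrderedHeap, u: int, v: int
) -> Tuple[CornerKey, CornerKey]:
    """Min and max corner keys of layer product (u, v).

    Only the cached layer extrema are touched; the product itself is
    never materialized.
    """
    if not (0 <= u < loh_x.num_layers and 0 <= v < loh_y.num_layers):
        raise ValueError(
            f"layer pair ({u}, {v}) out of bounds for "
            f"{loh_x.num_layers} x {loh_y.num_layers} layers"
        )
    return (
        CornerKey(loh_x.layer_mins[u] + loh_y.layer_mins[v], (u, v), MIN),
        CornerKey(loh_x.layer_maxs[u] + loh_y.layer_maxs[v], (u, v), MAX),
    )


def _product_area(loh_x: LayerOrderedHeap, loh_y: LayerOrderedHeap, u: int, v: int) -> int:
    return len(loh_x.layers[u]) * len(loh_y.layers[v])


def phase1_sweep(
    loh_x: LayerOrderedHeap,
    loh_y: LayerOrderedHeap,
    k: int,
    record_pops: bool = False,
) -> Tuple[SelectionTrace, List[CornerKey]]:
    """Pop corner keys in ascending order until committed area reaches k.

    Returns the trace (committed products, s, tau, pop count) and the
    frontier: every corner key still pending in the heap at termination.
    With ``record_pops`` the full popped-key sequence is kept on the
    trace for invariant checking.
    """
    if not 1 <= k <= loh_x.n * loh_y.n:
        raise ValueError(f"k must be in [1, {loh_x.n * loh_y.n}] (got {k})")
    heap: List[CornerKey] = [corner_keys(loh_x, loh_y, 0, 0)[MIN]]
    members = {(0, 0, MIN)}
    trace = SelectionTrace(popped=[] if record_pops else None)

    def push(u: int, v: int, corner: int) -> None:
        if u >= loh_x.num_layers or v >= loh_y.num_layers:
            return
        if (u, v, corner) in members:
            return
        heapq.heappush(heap, corner_keys(loh_x, loh_y, u, v)[corner])
        members.add((u, v, corner))

    while True:
        key = heapq.heappop(heap)
        u, v = key.layer_pair
        members.discard((u, v, key.corner))
        trace.pop_count += 1
        if trace.popped is not None:
            trace.popped.append(key)
        if key.corner == MIN:
            push(u + 1, v, MIN)
            push(u, v + 1, MIN)
            push(u, v, MAX)
        else:
            area = _product_area(loh_x, loh_y, u, v)
            trace.q.append(LayerProductIndex(u, v, area))
            trace.s += area
            if trace.s >= k:
                trace.tau = key.value
                break
    trace.phase1_products = len(trace.q)
    return trace, list(heap)


def phase2_collect(
    trace: SelectionTrace,
    frontier: Sequence[CornerKey],
    loh_x: LayerOrderedHeap,
    loh_y: LayerOrderedHeap,
) -> SelectionTrace:
    """Commit every max-flagged frontier product into the trace.

    A pending max corner marks a product whose min corner was already
    visited: the product may hold values below tau, so its area joins
    s' and its index joins q.  Min-flagged frontier keys are ignored.
    """
    for key in frontier:
        if key.corner == MAX:
            u, v = key.layer_pair
            area = _product_area(loh_x, loh_y, u, v)
            trace.q.append(LayerProductIndex(u, v, area))
            trace.s_prime += area
    return trace


def inflate_candidates(
    loh_x: LayerOrderedHeap,
    loh_y: LayerOrderedHeap,
    q: Sequence[Tuple[int, int]] | Sequence[LayerProductIndex],
) -> List[T]:
    """Generate every sum in every listed layer product."""
    return [
        x + y
        for entry in q
        for x in loh_x.layers[entry[0]]
        for y in loh_y.layers[entry[1]]
    ]


def _validate(X: Sequence[T], Y: Sequence[T], k: int) -> None:
    if not X or not Y:
        raise ValueError("X and Y must be nonempty")
    if not 0 <= k <= len(X) * len(Y):
        raise ValueError(f"k must be in [0, {len(X) * len(Y)}] (got {k})")


def _empty_result() -> SelectionResult:
    return SelectionResult(values=[], trace=SelectionTrace())


def _select_from_lohs(
    loh_x: LayerOrderedHeap,
    loh_y: LayerOrderedHeap,
    k: int,
    record_pops: bool = False,
) -> SelectionResult:
    trace, frontier = phase1_sweep(loh_x, loh_y, k, record_pops=record_pops)
    phase2_collect(trace, frontier, loh_x, loh_y)
    candidates = inflate_candidates(loh_x, loh_y, trace.q)
    values, _ = partition_by_rank(candidates, k)
    return SelectionResult(values=values, trace=trace)


def select_topk(
    X: Sequence[T],
    Y: Sequence[T],
    k: int,
    alpha: float = 2.0,
    sort: bool = False,
    record_pops: bool = False,
) -> SelectionResult:
    """Select the k smallest pairwise sums X[i] + Y[j].

    Parameters
    ----------
    X, Y
        Nonempty numeric vectors (any mutually comparable values).
    k
        Number of sums to return, ``0 <= k <= len(X) * len(Y)``.
    alpha
        Layer-ordered-heap rank (> 1); 2.0 doubles layer sizes.
    sort
        Return the values ascending instead of in selection order.
    record_pops
        Keep the popped corner-key sequence on the trace.

    Returns
    -------
    SelectionResult
        ``result.values`` is the multiset of the k smallest sums; ties at
        the k-th value are resolved by count, so exactly k values come
        back.  ``result.trace`` records q, s, s', tau.
    """
    _validate(X, Y, k)
    if k == 0:
        return _empty_result()
    result = _select_from_lohs(lohify(X, alpha), lohify(Y, alpha), k, record_pops)
    if sort:
        result.values.sort()
    return result


def select_topk_sorted_corners(
    X: Sequence[T],
    Y: Sequence[T],
    k: int,
    alpha: float = 2.0,
    sort: bool = False,
) -> SelectionResult:
    """Simplified variant: sort all corner keys instead of using a heap.

    All 2 * L_x * L_y corner keys are sorted ascending and scanned: a min
    corner inflates its product into the candidate pool, a max corner
    commits its area, and the scan stops once the committed area reaches
    k.  Sorting the corners is still o(n) work, and the returned multiset
    is identical to :func:`select_topk`'s, but the candidate pool is
    inflated eagerly, which is slower in practice when k << n^2.
    """
    _validate(X, Y, k)
    if k == 0:
        return _empty_result()
    loh_x, loh_y = lohify(X, alpha), lohify(Y, alpha)
    corners = sorted(
        key
        for u in range(loh_x.num_layers)
        for v in range(loh_y.num_layers)
        for key in corner_keys(loh_x, loh_y, u, v)
    )
    trace = SelectionTrace()
    candidates: List[T] = []
    committed: List[LayerProductIndex] = []
    seen_min: List[Tuple[int, int]] = []
    for key in corners:
        u, v = key.layer_pair
        trace.pop_count += 1
        if key.corner == MIN:
            candidates.extend(
                x + y for x in loh_x.layers[u] for y in loh_y.layers[v]
            )
            seen_min.append((u, v))
        else:
            area = _product_area(loh_x, loh_y, u, v)
            committed.append(LayerProductIndex(u, v, area))
            trace.s += area
            if trace.s >= k:
                trace.tau = key.value
                break
    trace.q = list(committed)
    trace.phase1_products = len(committed)
    max_popped = {(p.u, p.v) for p in committed}
    for (u, v) in seen_min:
        if (u, v) not in max_popped:
            area = _product_area(loh_x, loh_y, u, v)
            trace.q.append(LayerProductIndex(u, v, area))
            trace.s_prime += area
    values, _ = partition_by_rank(candidates, k)
    if sort:
        values.sort()
    return SelectionResult(values=values, trace=trace)


def select_topk_compressed(
    X: Sequence[T],
    Y: Sequence[T],
    k: int,
    alpha: float = 2.0,
) -> Tuple[List[LayerProductIndex], SelectionTrace]:
    """Run phases 0-2 only and return the committed layer products.

    No layer product is inflated: the returned q lists the (u, v) pairs
    whose union is guaranteed to contain the k smallest sums, in
    compressed (factored) form.  Phases 0-2 cost O(n) regardless of k.
    Re-deriving the LOHs of X and Y (construction is deterministic) and
    calling :func:`inflate_candidates` on q followed by a k-selection
    reproduces :func:`select_topk` exactly.
    """
    _validate(X, Y, k)
    if k == 0:
        return [], SelectionTrace()
    loh_x, loh_y = lohify(X, alpha), lohify(Y, alpha)
    trace, frontier = phase1_sweep(loh_x, loh_y, k)
    phase2_collect(trace, frontier, loh_x, loh_y)
    return list(trace.q), trace
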