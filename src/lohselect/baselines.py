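"""Reference top-k implementations used as oracles and comparators.

Three progressively smarter baselines for the k smallest pairwise sums:

* :func:`topk_sort` — materialize all |X|*|Y| sums and sort.
* :func:`topk_select` — materialize all sums and rank-partition, avoiding
  the sort's log factor.
* :func:`topk_comb_heap` — lazy frontier enumeration over a combinatoric
  heap: X and Y are binary-min-heapified, and pairs (i, j) are proposed
  row-major through a priority queue so every pair is inserted exactly
  once.  This is the classic tree-based scheme (with a plain binary
  queue standing where the original formulation used a soft heap, so
  pops come out exactly sorted and no post-selection is needed).
"""

from __future__ import annotations

import heapq
from typing import List, Optional, Sequence, Set, Tuple, TypeVar

from .linear_select import partition_by_rank

T = TypeVar("T")

__all__ = ["topk_sort", "topk_select", "topk_comb_heap"]


def _validate(X: Sequence[T], Y: Sequence[T], k: int) -> None:
    if not X or not Y:
        raise ValueError("X and Y must be nonempty")
    if not 1 <= k <= len(X) * len(Y):
        raise ValueError(f"k must be in [1, {len(X) * len(Y)}] (got {k})")


def topk_sort(X: Sequence[T], Y: Sequence[T], k: int) -> List[T]:
    """All sums, sorted ascending, first k.  O(n^2 log n + k)."""
    _validate(X, Y, k)
    sums = sorted(x + y for x in X for y in Y)
    return sums[:k]


def topk_select(X: Sequence[T], Y: Sequence[T], k: int) -> List[T]:
    """All sums, rank-partitioned; unsorted output.  O(n^2)."""
    _validate(X, Y, k)
    sums = [x + y for x in X for y in Y]
    left, _ = partition_by_rank(sums, k)
    return left


def topk_comb_heap(
    X: Sequence[T],
    Y: Sequence[T],
    k: int,
    _inserted_pairs: Optional[Set[Tuple[int, int]]] = None,
) -> List[T]:
    """k smallest sums via lazy row-major pair proposals, ascending.

    X and Y are heapified so that (1-based) ``X[i] <= X[2i], X[2i+1]``.
    The queue starts with pair (1, 1); popping (i, j) proposes

    * (2i, 1), (2i+1, 1), (i, 2), (i, 3)  when j == 1,
    * (i, 2j), (i, 2j+1)                  when j > 1,

    bounds permitting.  Each pair has a unique proposer, so no membership
    set is needed; `_inserted_pairs`, when supplied, collects every
    proposed pair so tests can assert uniqueness.
    """
    _validate(X, Y, k)
    hx, hy = list(X), list(Y)
    heapq.heapify(hx)
    heapq.heapify(hy)
    nx, ny = len(hx), len(hy)

    queue: List[Tuple[T, int, int]] = [(hx[0] + hy[0], 1, 1)]  # 1-based pair
    if _inserted_pairs is not None:
        _inserted_pairs.add((1, 1))
    out: List[T] = []

    def propose(i: int, j: int) -> None:
        if i > nx or j > ny:
            return
        if _inserted_pairs is not None:
            assert (i, j) not in _inserted_pairs, f"pair {(i, j)} proposed twice"
            _inserted_pairs.add((i, j))
        heapq.heappush(queue, (hx[i - 1] + hy[j - 1], i, j))

    for _ in range(k):
        value, i, j = heapq.heappop(queue)
        out.append(value)
        if j == 1:
            propose(2 * i, 1)
            propose(2 * i + 1, 1)
            propose(i, 2)
            propose(i, 3)
        else:
            propose(i, 2 * j)
            propose(i, 2 * j + 1)
    return out
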