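"""Worst-case linear-time rank selection and rank partitioning.

These are the only order-statistic primitives the layer-ordered-heap
machinery depends on.  ``select_nth`` is a classic median-of-medians
(groups of five, sort cutoff for short inputs); ``partition_by_rank``
splits a multiset around a requested left-part size, distributing
duplicates of the threshold value so that the part sizes are exact.

Ranks are 0-based throughout: the field's usual "k-th smallest" maps to
``rank = k - 1``.  Inputs are never mutated.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple, TypeVar

T = TypeVar("T")

_SORT_CUTOFF = 10
_GROUP = 5

__all__ = ["select_nth", "partition_by_rank"]


def _mom_select(values: List[T], rank: int) -> T:
    """Median-of-medians selection on a private, mutable list."""
    while True:
        n = len(values)
        if n < _SORT_CUTOFF:
            values.sort()
            return values[rank]
        medians = [
            sorted(values[i : i + _GROUP])[(min(_GROUP, n - i) - 1) // 2]
            for i in range(0, n, _GROUP)
        ]
        pivot = _mom_select(medians, (len(medians) - 1) // 2)
        below: List[T] = []
        above: List[T] = []
        n_equal = 0
        for v in values:
            if v < pivot:
                below.append(v)
            elif v > pivot:
                above.append(v)
            else:
                n_equal += 1
        if rank < len(below):
            values = below
        elif rank < len(below) + n_equal:
            return pivot
        else:
            rank -= len(below) + n_equal
            values = above


def select_nth(values: Sequence[T], rank: int) -> T:
    """Return the value of 0-based `rank` in ascending order.

    Equivalent to ``sorted(values)[rank]`` but runs in worst-case linear
    time and does not modify the input.

    Raises
    ------
    ValueError
        If `values` is empty or `rank` is out of ``[0, len(values))``.
    """
    buf = list(values)
    if not buf:
        raise ValueError("select_nth requires a nonempty sequence")
    if not 0 <= rank < len(buf):
        raise ValueError(f"rank {rank} out of range for {len(buf)} values")
    return _mom_select(buf, rank)


def partition_by_rank(
    values: Iterable[T], left_count: int
) -> Tuple[List[T], List[T]]:
    """Split `values` into (left, right) with ``len(left) == left_count``.

    Every element of the left part is <= every element of the right part,
    and the two parts together are a permutation of the input.  Elements
    equal to the threshold value are distributed to make the counts exact,
    so ties at the split never change the part sizes.

    ``left_count == 0`` returns ``([], values)``; ``left_count == n``
    returns ``(values, [])``.
    """
    buf = list(values)
    n = len(buf)
    if not 0 <= left_count <= n:
        raise ValueError(f"left_count {left_count} out of range for {n} values")
    if left_count == 0:
        return [], buf
    if left_count == n:
        return buf, []
    threshold = _mom_select(list(buf), left_count - 1)
    left: List[T] = []
    right: List[T] = []
    for v in buf:
        if v < threshold:
            left.append(v)
        elif v > threshold:
            right.append(v)
    left.extend([threshold] * (left_count - len(left)))
    right.extend([threshold] * ((n - left_count) - len(right)))
    return left, right
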