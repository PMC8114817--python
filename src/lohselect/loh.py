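"""Layer-ordered heaps (LOHs).

A layer-ordered heap partitions a multiset into ascending *layers*: every
value in layer ``u`` is <= every value in layer ``u + 1``, while values
within a layer stay unordered.  Layer sizes start at 1 and grow
geometrically with rank ``alpha > 1`` (``alpha = 2`` doubles:
1, 2, 4, 8, ...), which is what lets construction run in linear time by
repeatedly peeling off the largest remaining layer with a rank partition.
``alpha = 1`` would make every layer a singleton, i.e. a full sort, and is
rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, TypeVar

from .linear_select import partition_by_rank

T = TypeVar("T")

__all__ = [
    "LayerOrderedHeap",
    "LohReport",
    "layer_size_schedule",
    "lohify",
    "layer_extrema",
    "verify_loh",
]


def layer_size_schedule(n: int, alpha: float) -> List[int]:
    """Layer sizes for `n` elements at rank `alpha`.

    Layer ``u`` (1-based) has scheduled size ``ceil(alpha ** (u - 1))``;
    the final layer is truncated so the sizes sum to exactly `n`.  For
    ``alpha = 2`` this is the doubling schedule 1, 2, 4, ..., remainder.
    """
    if alpha <= 1:
        raise ValueError(f"alpha must be > 1 (got {alpha}); alpha = 1 is sorting")
    if n < 0:
        raise ValueError(f"n must be >= 0 (got {n})")
    sizes: List[int] = []
    total = 0
    u = 0
    while total < n:
        size = min(math.ceil(alpha**u), n - total)
        sizes.append(size)
        total += size
        u += 1
    return sizes


@dataclass
class LayerOrderedHeap:
    """Ascending layers of a multiset with cached per-layer extrema."""

    layers: List[List[T]]
    alpha: float
    layer_mins: List[T] = field(default_factory=list)
    layer_maxs: List[T] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layer_mins:
            self.layer_mins = [min(layer) for layer in self.layers]
        if not self.layer_maxs:
            self.layer_maxs = [max(layer) for layer in self.layers]

    @property
    def n(self) -> int:
        return sum(len(layer) for layer in self.layers)

    @property
    def num_layers(self) -> int:
        return len(self.layers)

    def __len__(self) -> int:
        return self.num_layers

    def __getitem__(self, u: int) -> List[T]:
        return self.layers[u]

    def layer_extrema(self, u: int) -> Tuple[T, T]:
        if not 0 <= u < self.num_layers:
            raise ValueError(f"layer index {u} out of range for {self.num_layers} layers")
        return self.layer_mins[u], self.layer_maxs[u]


def lohify(values: Iterable[T], alpha: float = 2.0) -> LayerOrderedHeap:
    """Build a layer-ordered heap of rank `alpha` from `values`.

    Construction iteratively selects and removes the largest remaining
    layer with :func:`partition_by_rank`, so the total work is linear in
    the input size for any fixed ``alpha > 1``.

    Examples
    --------
    >>> [sorted(l) for l in lohify([8, 1, 6, 4, 5, 3, 2], alpha=2).layers]
    [[1], [2, 3], [4, 5, 6, 8]]
    """
    remaining = list(values)
    sizes = layer_size_schedule(len(remaining), alpha)
    layers: List[List[T]] = []
    for size in reversed(sizes):
        remaining, top = partition_by_rank(remaining, len(remaining) - size)
        layers.append(top)
    layers.reverse()
    return LayerOrderedHeap(layers=layers, alpha=alpha)


def layer_extrema(loh: LayerOrderedHeap, u: int) -> Tuple[T, T]:
    """Cached (min, max) of layer `u`."""
    return loh.layer_extrema(u)


@dataclass
class LohReport:
    """Outcome of :func:`verify_loh`; falsy when any invariant fails."""

    ok: bool
    messages: List[str] = field(default_factory=list)
    first_violation: Optional[Tuple[int, int]] = None

    def __bool__(self) -> bool:
        return self.ok


def verify_loh(
    loh: LayerOrderedHeap, expected_values: Optional[Sequence[T]] = None
) -> LohReport:
    """Check every layer-ordered-heap invariant and report violations.

    Checks the layer ordering (``max(layer u) <= min(layer u+1)``), the
    cached extrema, the geometric layer-size schedule, and — when
    `expected_values` is given — multiset conservation of the
    construction input.
    """
    messages: List[str] = []
    first_violation: Optional[Tuple[int, int]] = None
    for u, layer in enumerate(loh.layers):
        if not layer:
            messages.append(f"layer {u} is empty")
        elif (min(layer), max(layer)) != (loh.layer_mins[u], loh.layer_maxs[u]):
            messages.append(f"cached extrema of layer {u} are stale")
    for u in range(loh.num_layers - 1):
        if loh.layer_maxs[u] > loh.layer_mins[u + 1]:
            messages.append(
                f"layer ordering violated between layers {u} and {u + 1}: "
                f"max {loh.layer_maxs[u]!r} > min {loh.layer_mins[u + 1]!r}"
            )
            if first_violation is None:
                first_violation = (u, u + 1)
    sizes = [len(layer) for layer in loh.layers]
    if sizes != layer_size_schedule(loh.n, loh.alpha):
        messages.append(
            f"layer sizes {sizes} do not match the rank-{loh.alpha} schedule"
        )
    if loh.n >= 1 and sizes and sizes[0] != 1:
        messages.append(f"first layer has size {sizes[0]}, expected 1")
    if expected_values is not None:
        got = sorted(v for layer in loh.layers for v in layer)
        if got != sorted(expected_values):
            messages.append("layer contents are not a permutation of the input")
    return LohReport(ok=not messages, messages=messages, first_violation=first_violation)
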