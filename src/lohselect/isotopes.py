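"""Top-k combined isotopologue pairs of two molecular fragments.

Each fragment is described by an isotope peak list: (mass in Da,
probability) pairs whose probabilities sum to at most 1.  The abundance
of a combined isotopologue is the product of the two peak probabilities,
so ranking pairs by abundance is top-k on the Cartesian sum of the
negative-log probabilities: the most probable pairs have the smallest
summed -log p.  The k-th smallest neg-log sum found by the layer-ordered
sweep acts as the selection threshold; pair identities are then recovered
by a scan of the pair grid (the core selection returns values, not index
pairs), with ties at the threshold trimmed so exactly k pairs come back.

Pairs that happen to share a total mass are *not* merged: aggregating
isobaric species is a separate convolution step outside this module's
scope.  Returned probabilities are recomputed as products p_A * p_B, not
exponentiated logs, to avoid round-trip error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, List, Tuple, Union

from .topk import select_topk

__all__ = ["IsotopePeakList", "PeakListError", "read_peak_list", "top_isotopologue_pairs"]

_PROB_SUM_TOLERANCE = 1e-6


class PeakListError(ValueError):
    """Malformed or physically invalid peak-list input."""


@dataclass(frozen=True)
class IsotopePeakList:
    """(mass in Da, probability) peaks of one molecular fragment."""

    peaks: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        for mass, prob in self.peaks:
            if mass <= 0:
                raise PeakListError(f"nonpositive mass {mass}")
            if not 0 < prob <= 1:
                raise PeakListError(f"probability {prob} outside (0, 1]")
        total = sum(p for _, p in self.peaks)
        if total > 1 + _PROB_SUM_TOLERANCE:
            raise PeakListError(f"probabilities sum to {total} > 1")

    def __len__(self) -> int:
        return len(self.peaks)


def read_peak_list(source: Union[str, Path, IO[str], Iterable[str]]) -> IsotopePeakList:
    """Parse a two-column TSV peak list: ``mass<TAB>probability``.

    Lines starting with ``#`` and blank lines are skipped.  Raises
    :class:`PeakListError` naming the offending line on malformed input,
    nonpositive mass, probability outside (0, 1], or a probability sum
    exceeding 1.
    """
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            lines = handle.readlines()
    else:
        lines = list(source)
    peaks: List[Tuple[float, float]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise PeakListError(
                f"line {lineno}: expected 'mass<TAB>probability', got {line!r}"
            )
        try:
            mass, prob = float(fields[0]), float(fields[1])
        except ValueError:
            raise PeakListError(f"line {lineno}: non-numeric field in {line!r}") from None
        if mass <= 0:
            raise PeakListError(f"line {lineno}: nonpositive mass {mass}")
        if not 0 < prob <= 1:
            raise PeakListError(f"line {lineno}: probability {prob} outside (0, 1]")
        peaks.append((mass, prob))
    try:
        return IsotopePeakList(peaks=tuple(peaks))
    except PeakListError as err:
        raise PeakListError(f"invalid peak list: {err}") from None


def top_isotopologue_pairs(
    A: IsotopePeakList, B: IsotopePeakList, k: int
) -> List[Tuple[float, float]]:
    """The k most abundant combined isotopologue pairs of fragments A and B.

    Returns (mass_A + mass_B, p_A * p_B) tuples, descending by
    probability (ties in arbitrary order).  Distinct pairs with equal
    total mass stay distinct.
    """
    if len(A) == 0 or len(B) == 0:
        raise ValueError("peak lists must be nonempty")
    if not 1 <= k <= len(A) * len(B):
        raise ValueError(f"k must be in [1, {len(A) * len(B)}] (got {k})")
    neglog_a = [-math.log(p) for _, p in A.peaks]
    neglog_b = [-math.log(p) for _, p in B.peaks]
    result = select_topk(neglog_a, neglog_b, k)
    threshold = max(result.values)
    below: List[Tuple[float, float]] = []
    at: List[Tuple[float, float]] = []
    for (mass_a, p_a), x in zip(A.peaks, neglog_a):
        for (mass_b, p_b), y in zip(B.peaks, neglog_b):
            total = x + y  # same expression as the selection path, so
            if total < threshold:  # threshold equality is consistent
                below.append((mass_a + mass_b, p_a * p_b))
            elif total == threshold:
                at.append((mass_a + mass_b, p_a * p_b))
    pairs = below + at[: k - len(below)]
    pairs.sort(key=lambda pair: -pair[1])
    return pairs
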