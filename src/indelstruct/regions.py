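"""Modeled-region mapping and low-complexity detection.

A residue is "modeled" when its position in the target sequence aligns
to a non-gap template position, hence can be assessed on the 3D model.
Intervals are 1-based and closed throughout.

Low-complexity regions are found with a Wootton–Federhen-style
two-threshold sliding-window scan of Shannon entropy (bits over the
20-letter alphabet): windows at or below ``k_low`` seed a region, which
is extended across neighbouring windows while entropy stays at or
below ``k_high``; overlapping regions are merged.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from .conservation import GAP_CHARS, MultipleAlignment
from .variants import IndelVariant, membership_interval

__all__ = [
    "ModeledRegionMap",
    "Membership",
    "LowComplexityAnnotation",
    "modeled_intervals_from_alignment",
    "region_membership",
    "low_complexity_intervals",
    "homopolymer_runs",
    "in_low_complexity",
    "window_entropy",
]

Interval = tuple[int, int]


class Membership(str, Enum):
    fully_modeled = "fully_modeled"
    partially_modeled = "partially_modeled"
    unmodeled = "unmodeled"


def _check_intervals(intervals: tuple[Interval, ...], upper: int | None) -> None:
    prev_end = 0
    for start, end in intervals:
        if start < 1 or end < start:
            raise ValueError(f"bad interval ({start}, {end})")
        if start <= prev_end:
            raise ValueError("intervals must be sorted and disjoint")
        if upper is not None and end > upper:
            raise ValueError(f"interval ({start}, {end}) exceeds length {upper}")
        prev_end = end


@dataclass(frozen=True)
class ModeledRegionMap:
    """Sorted disjoint closed intervals of structurally modeled residues."""

    intervals: tuple[Interval, ...]
    protein_length: int

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise ValueError("protein_length must be >= 1")
        _check_intervals(self.intervals, self.protein_length)

    def contains(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.intervals)

    @property
    def modeled_residue_count(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# 1-based closed intervals; protein_length={self.protein_length}\n")
            fh.write("start\tend\n")
            for s, e in self.intervals:
                fh.write(f"{s}\t{e}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ModeledRegionMap":
        protein_length = None
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    if "protein_length=" in line:
                        protein_length = int(line.split("protein_length=")[1].split()[0])
                    continue
                if not line or line.startswith("start"):
                    continue
                s, e = line.split("\t")[:2]
                intervals.append((int(s), int(e)))
        if protein_length is None:
            protein_length = max(e for _, e in intervals) if intervals else 1
        return cls(intervals=tuple(intervals), protein_length=protein_length)


def modeled_intervals_from_alignment(pairwise: MultipleAlignment) -> ModeledRegionMap:
    """Derive modeled intervals from a 2-row target–template alignment.

    Row 1 is the target, row 2 the template.  A target position is
    modeled iff it aligns to a non-gap template symbol.
    """
    if len(pairwise.records) != 2:
        raise ValueError(f"expected a 2-row alignment, got {len(pairwise.records)} rows")
    target = pairwise.records[0][1].upper()
    template = pairwise.records[1][1].upper()
    intervals: list[Interval] = []
    pos = 0
    run_start = None
    for t, m in zip(target, template):
        if t in GAP_CHARS:
            continue
        pos += 1
        if m not in GAP_CHARS:
            if run_start is None:
                run_start = pos
        elif run_start is not None:
            intervals.append((run_start, pos - 1))
            run_start = None
    if run_start is not None:
        intervals.append((run_start, pos))
    if pos == 0:
        raise ValueError("target row is all gaps")
    return ModeledRegionMap(intervals=tuple(intervals), protein_length=pos)


def region_membership(
    v: IndelVariant, region_map: ModeledRegionMap
) -> tuple[Membership, float]:
    """Membership of the variant's interval in the modeled regions.

    Returns the status plus the fraction of interval residues that are
    modeled (1.0 = fully modeled, 0.0 = unmodeled).
    """
    start, end = membership_interval(v)
    if start < 1 or end > region_map.protein_length:
        raise ValueError(
            f"variant interval ({start}, {end}) outside protein "
            f"1..{region_map.protein_length}"
        )
    n = end - start + 1
    modeled = sum(region_map.contains(p) for p in range(start, end + 1))
    fraction = modeled / n
    if modeled == n:
        return Membership.fully_modeled, fraction
    if modeled == 0:
        return Membership.unmodeled, fraction
    return Membership.partially_modeled, fraction


@dataclass(frozen=True)
class LowComplexityAnnotation:
    lcr_intervals: tuple[Interval, ...]
    homopolymer_runs: tuple[tuple[str, int, int, int], ...] = ()

    def __post_init__(self) -> None:
        _check_intervals(self.lcr_intervals, None)
        for aa, s, e, ln in self.homopolymer_runs:
            if ln != e - s + 1 or ln < 2:
                raise ValueError(f"inconsistent run {(aa, s, e, ln)}")


def window_entropy(sequence: str, start: int, window: int) -> float:
    """Shannon entropy (bits) of sequence[start:start+window], 0-based."""
    counts = Counter(sequence[start : start + window])
    n = sum(counts.values())
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def low_complexity_intervals(
    sequence: str,
    window: int = 12,
    k_low: float = 2.2,
    k_high: float = 2.5,
) -> tuple[Interval, ...]:
    """Two-threshold entropy scan for low-complexity regions.

    Defaults (window 12, 2.2/2.5 bits) flag poly-amino-acid runs such
    as a 16-residue poly-Glu stretch while leaving typical globular
    sequence unflagged.  Returns merged 1-based closed intervals.
    """
    if window < 4:
        raise ValueError(f"window must be >= 4, got {window}")
    sequence = sequence.upper()
    n = len(sequence)
    if n < window:
        raise ValueError(f"sequence length {n} shorter than window {window}")
    n_win = n - window + 1
    entropies = [window_entropy(sequence, i, window) for i in range(n_win)]
    seeds = [i for i, h in enumerate(entropies) if h <= k_low]
    regions: list[Interval] = []
    for seed in seeds:
        lo = seed
        while lo > 0 and entropies[lo - 1] <= k_high:
            lo -= 1
        hi = seed
        while hi < n_win - 1 and entropies[hi + 1] <= k_high:
            hi += 1
        regions.append((lo + 1, hi + window))  # 1-based closed, spans of windows lo..hi
    regions.sort()
    merged: list[Interval] = []
    for s, e in regions:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return tuple(merged)


def homopolymer_runs(
    sequence: str, min_len: int = 4
) -> tuple[tuple[str, int, int, int], ...]:
    """All maximal single-residue runs of length >= min_len (1-based)."""
    if min_len < 2:
        raise ValueError(f"min_len must be >= 2, got {min_len}")
    sequence = sequence.upper()
    runs = []
    i = 0
    while i < len(sequence):
        j = i
        while j < len(sequence) and sequence[j] == sequence[i]:
            j += 1
        if j - i >= min_len:
            runs.append((sequence[i], i + 1, j, j - i))
        i = j
    return tuple(runs)


def in_low_complexity(v: IndelVariant, annotation: LowComplexityAnnotation) -> bool:
    """True iff the variant's membership interval overlaps any LCR."""
    start, end = membership_interval(v)
    return any(s <= end and start <= e for s, e in annotation.lcr_intervals)
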