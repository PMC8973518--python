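"""Genomic interval collections and set operations on MAR peak sets.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``. All higher-level statistics in :mod:`marseq` consume the
types defined here.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "VennPartition",
    "BedParseError",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "venn_partition",
    "length_distribution",
    "VENN_REGIONS",
]

VENN_REGIONS = ("onlyA", "onlyB", "onlyC", "AB_only", "AC_only", "BC_only", "ABC")


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed; names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome.

    Parameters
    ----------
    chrom : chromosome / scaffold identifier.
    start : 0-based inclusive start (bp).
    end : 0-based exclusive end (bp); must exceed ``start``.
    name : optional feature label (e.g. a peak name).
    score : optional numeric score.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`, grouped by chromosome.

    The set carries a ``label`` naming the dataset (e.g. ``SG1`` for the
    day-1 silk-gland peak set). Construction preserves input order;
    :meth:`merge` returns a normalized set whose intervals are sorted and
    pairwise non-overlapping on every chromosome.
    """

    def __init__(self, label: str, intervals: Iterable[GenomicInterval] = ()) -> None:
        self.label = label
        self.intervals: list[GenomicInterval] = list(intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.label == other.label and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet({self.label!r}, n={len(self)})"

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def total_bp(self) -> int:
        """Total covered bases after collapsing overlaps."""
        return sum(iv.length for iv in merge_intervals(self))

    def sorted(self) -> "IntervalSet":
        return IntervalSet(self.label, sorted(self.intervals))

    def merge(self) -> "IntervalSet":
        return merge_intervals(self)

    def restrict(self, chrom: str, start: int, end: int) -> "IntervalSet":
        """Sub-set of intervals overlapping ``chrom:[start, end)`` by >= 1 bp."""
        window = GenomicInterval(chrom, start, end)
        return IntervalSet(
            self.label,
            [iv for iv in self.intervals if iv.overlap_bp(window) > 0],
        )

    def lengths(self) -> np.ndarray:
        return np.array([iv.length for iv in self.intervals], dtype=np.int64)


def read_bed(path: str | Path, label: str | None = None) -> IntervalSet:
    """Read a BED3/BED4/BED6 file into an :class:`IntervalSet`.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped. Input
    order is preserved (normalize with :func:`merge_intervals`). Malformed
    lines raise :class:`BedParseError` naming the 1-based line number.
    """
    path = Path(path)
    if label is None:
        label = path.stem
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}/{fields[2]!r}"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}:{lineno}: non-numeric score {fields[4]!r}"
                    ) from exc
            try:
                out.append(GenomicInterval(chrom, start, end, name, score))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(label, out)


def write_bed(s: IntervalSet | Sequence[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED (3 or 4 columns depending on names)."""
    intervals = list(s)
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def merge_intervals(s: IntervalSet | Sequence[GenomicInterval]) -> IntervalSet:
    """Collapse overlapping and bookended intervals into single spans.

    Per chromosome, every maximal run of intervals in which each interval
    overlaps or directly abuts (``end == next start``) the next is replaced by
    one interval spanning the run. This mirrors ``bedtools merge`` with its
    default distance of 0. The result is sorted and pairwise non-overlapping.
    """
    label = s.label if isinstance(s, IntervalSet) else "merged"
    per_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in s:
        per_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(per_chrom):
        ivs = sorted(per_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or bookend
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return IntervalSet(label, merged)


def _overlap_bp_with_set(iv: GenomicInterval, chrom_index: dict[str, tuple[list[int], list[int]]]) -> int:
    """Total bases of ``iv`` covered by a normalized set (binary-searched)."""
    if iv.chrom not in chrom_index:
        return 0
    starts, ends = chrom_index[iv.chrom]
    # first interval whose end is past iv.start
    i = bisect.bisect_right(ends, iv.start)
    total = 0
    while i < len(starts) and starts[i] < iv.end:
        total += min(ends[i], iv.end) - max(starts[i], iv.start)
        i += 1
    return total


def _index(s: IntervalSet) -> dict[str, tuple[list[int], list[int]]]:
    out: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ivs in s.by_chrom().items():
        out[chrom] = ([iv.start for iv in ivs], [iv.end for iv in ivs])
    return out


@dataclass
class VennPartition:
    """Seven-region decomposition of three normalized interval sets.

    Every interval of the merged union of the three inputs is assigned to
    exactly one region (``onlyA`` ... ``ABC``) according to which input sets
    it overlaps by at least ``min_overlap`` bases. Membership is
    presence/absence: a union interval covering two peaks of the same input
    counts that input once.
    """

    labels: tuple[str, str, str]
    regions: dict[str, list[GenomicInterval]]
    min_overlap: int = 1

    @property
    def counts(self) -> dict[str, int]:
        return {r: len(self.regions[r]) for r in VENN_REGIONS}

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def percentages(self) -> dict[str, float]:
        """Common/unique membership percentages over the union size."""
        n = self.union_size
        if n == 0:
            return {k: float("nan") for k in ("common", "uniqueA", "uniqueB", "uniqueC")}
        return {
            "common": 100.0 * len(self.regions["ABC"]) / n,
            "uniqueA": 100.0 * len(self.regions["onlyA"]) / n,
            "uniqueB": 100.0 * len(self.regions["onlyB"]) / n,
            "uniqueC": 100.0 * len(self.regions["onlyC"]) / n,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": list(VENN_REGIONS), "count": [len(self.regions[r]) for r in VENN_REGIONS]}
        )


_MEMBERSHIP_TO_REGION = {
    (True, False, False): "onlyA",
    (False, True, False): "onlyB",
    (False, False, True): "onlyC",
    (True, True, False): "AB_only",
    (True, False, True): "AC_only",
    (False, True, True): "BC_only",
    (True, True, True): "ABC",
}


def venn_partition(
    a: IntervalSet, b: IntervalSet, c: IntervalSet, min_overlap: int = 1
) -> VennPartition:
    """Partition the merged union of three peak sets into 7 overlap regions.

    Inputs are normalized (merged) first. Each union interval's membership in
    a set requires >= ``min_overlap`` total overlapping bases with that set;
    should a large ``min_overlap`` leave an interval below threshold for every
    set, it falls back to the set covering it most (every union interval is
    covered by at least one input by construction).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    sets = [merge_intervals(x) for x in (a, b, c)]
    union = merge_intervals(
        IntervalSet("union", [iv for s in sets for iv in s])
    )
    indexes = [_index(s) for s in sets]
    regions: dict[str, list[GenomicInterval]] = {r: [] for r in VENN_REGIONS}
    for iv in union:
        overlaps = [_overlap_bp_with_set(iv, idx) for idx in indexes]
        member = tuple(o >= min_overlap for o in overlaps)
        if not any(member):
            best = int(np.argmax(overlaps))
            member = tuple(i == best for i in range(3))
        regions[_MEMBERSHIP_TO_REGION[member]].append(iv)
    return VennPartition(
        labels=(a.label, b.label, c.label), regions=regions, min_overlap=min_overlap
    )


def length_distribution(s: IntervalSet, bin_width: int) -> pd.Series:
    """Histogram of interval lengths in ``[k*bin_width, (k+1)*bin_width)`` bins.

    Returns a Series indexed by the left edge of each occupied bin; the sum of
    counts equals the number of intervals. Empty input yields an empty Series.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lengths = s.lengths()
    if lengths.size == 0:
        return pd.Series(dtype=np.int64, name="count")
    left_edges = (lengths // bin_width) * bin_width
    counts = pd.Series(left_edges).value_counts().sort_index()
    counts.name = "count"
    counts.index.name = "bin_start"
    return counts
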