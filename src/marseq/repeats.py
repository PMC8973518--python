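"""Simple-sequence-repeat detection and transposable-element hit filtering.

SSR detection follows the MISA conventions used for MAR sequence analysis:
perfect tandem arrays of 2–6 bp units with at least ``min_reps`` copies, and
compound records grouping simple SSRs separated by at most
``max_interruption`` bases. Mononucleotide runs are excluded by default.

TE annotation itself (alignment) is external; this module consumes
blast-style tabular hits and applies the identity/length thresholds, then
reports merged per-TE occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, merge_intervals

__all__ = [
    "SSRRecord",
    "find_ssrs",
    "ssr_class_summary",
    "te_hit_filter",
    "read_blast_tab",
    "BLAST6_COLUMNS",
]

BLAST6_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


@dataclass(frozen=True)
class SSRRecord:
    """A detected SSR: a perfect tandem (simple) or a grouped run (compound).

    For simple records ``end - start == unit_size * n_reps``. Compound
    records span from the first member's start to the last member's end and
    list their constituent simple SSRs and the spacer lengths between them.
    """

    seq_id: str
    unit: str
    unit_size: int
    n_reps: int
    start: int
    end: int
    kind: str = "simple"
    members: tuple["SSRRecord", ...] = ()
    spacers: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "simple" and self.end - self.start != self.unit_size * self.n_reps:
            raise ValueError("simple SSR span must equal unit_size * n_reps")


def _minimal_period(unit: str) -> int:
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return p
    return len(unit)


def find_ssrs(
    seq: str,
    min_reps: int = 5,
    unit_sizes: Sequence[int] = (2, 3, 4, 5, 6),
    max_interruption: int = 100,
    seq_id: str = "seq",
) -> list[SSRRecord]:
    """Maximal perfect tandem repeats plus compound groupings.

    A run whose unit is itself a tandem of a smaller allowed unit is reported
    only at the smallest allowed unit size (so an (ATAT)n run appears as
    (AT)2n, never twice). Within one unit size, when two maximal periodic
    regions abut so closely that their full tandem spans would overlap, the
    later region is trimmed to start at the earlier one's end (keeping
    periodicity) — spans of equal unit size therefore never overlap. Simple
    SSRs separated by <= ``max_interruption`` bases are additionally grouped
    into compound records; the simple records are retained alongside.
    """
    if min_reps < 2:
        raise ValueError("min_reps must be >= 2")
    seq = seq.upper()
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    unit_sizes = sorted(set(unit_sizes))
    simples: list[SSRRecord] = []
    for k in unit_sizes:
        if n < k * min_reps:
            continue
        match = arr[:-k] == arr[k:]
        # maximal runs of True in `match`: a run [i, i+r) means positions
        # [i, i+r+k) are k-periodic
        padded = np.concatenate(([False], match, [False]))
        diff = np.diff(padded.astype(np.int8))
        run_starts = np.nonzero(diff == 1)[0]
        run_ends = np.nonzero(diff == -1)[0]
        last_end = -1
        for i, j in zip(run_starts, run_ends):
            start = int(i)
            region_end = int(j) + k  # exclusive end of the periodic region
            if start < last_end:  # trim overlap with previous same-k record
                start = last_end
            reps = (region_end - start) // k
            if reps < min_reps:
                continue
            unit = seq[start : start + k]
            p = _minimal_period(unit)
            if p < k and p in unit_sizes:
                continue  # reported at the smaller allowed unit size
            if p < k and p not in unit_sizes and p == 1:
                continue  # mononucleotide run masquerading as a larger unit
            end = start + reps * k
            simples.append(SSRRecord(seq_id, unit, k, reps, start, end))
            last_end = end
    simples.sort(key=lambda r: (r.start, r.end))
    records: list[SSRRecord] = list(simples)
    # compound grouping across unit sizes
    group: list[SSRRecord] = []
    out_compound: list[SSRRecord] = []

    def flush() -> None:
        if len(group) >= 2:
            spacers = tuple(
                group[i + 1].start - group[i].end for i in range(len(group) - 1)
            )
            out_compound.append(
                SSRRecord(
                    seq_id=seq_id,
                    unit="+".join(r.unit for r in group),
                    unit_size=0,
                    n_reps=len(group),
                    start=group[0].start,
                    end=group[-1].end,
                    kind="compound",
                    members=tuple(group),
                    spacers=spacers,
                )
            )

    for rec in simples:
        if group and rec.start - group[-1].end <= max_interruption:
            group.append(rec)
        else:
            flush()
            group = [rec]
    flush()
    records.extend(out_compound)
    return records


def ssr_class_summary(records: Iterable[SSRRecord]) -> pd.DataFrame:
    """Occurrence counts per distinct unit, partitioned by unit size.

    Counts simple records only; members of compound records are themselves
    simple records and hence counted individually. Sorted by unit size then
    descending count.
    """
    rows = [
        {"unit_size": r.unit_size, "unit": r.unit}
        for r in records
        if r.kind == "simple"
    ]
    if not rows:
        return pd.DataFrame(columns=["unit_size", "unit", "count"])
    df = (
        pd.DataFrame(rows)
        .groupby(["unit_size", "unit"])
        .size()
        .reset_index(name="count")
        .sort_values(["unit_size", "count", "unit"], ascending=[True, False, True])
        .reset_index(drop=True)
    )
    return df


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Read a 12-column blast outfmt-6 style TSV."""
    return pd.read_csv(path, sep="\t", header=None, names=list(BLAST6_COLUMNS), comment="#")


def te_hit_filter(
    hits: pd.DataFrame,
    min_identity: float = 90.0,
    min_length: int = 100,
    te_col: str = "qseqid",
    seq_col: str = "sseqid",
    span_cols: tuple[str, str] = ("sstart", "send"),
) -> tuple[pd.DataFrame, pd.Series]:
    """Filter TE alignment hits and report per-TE occupied bases.

    Hits with identity below ``min_identity`` percent or alignment length
    below ``min_length`` bp are removed; boundary values (exactly 90 %,
    exactly 100 bp) are retained. Occupancy per TE is the total of merged
    alignment spans on each target sequence (overlapping spans merged before
    summing), so stacked hits are not double-counted.

    Returns (filtered hit frame, per-TE occupied-bp Series).
    """
    kept = hits[(hits["pident"] >= min_identity) & (hits["length"] >= min_length)].copy()
    occupied: dict[str, int] = {}
    s_col, e_col = span_cols
    for te, sub in kept.groupby(te_col):
        ivs = []
        for row in sub.itertuples():
            s, e = getattr(row, s_col), getattr(row, e_col)
            lo, hi = (int(s), int(e)) if s <= e else (int(e), int(s))
            # blast spans are 1-based inclusive; convert to half-open
            ivs.append(GenomicInterval(str(getattr(row, seq_col)), lo - 1, hi))
        occupied[str(te)] = merge_intervals(IntervalSet(str(te), ivs)).total_bp()
    per_te = pd.Series(occupied, name="occupied_bp", dtype=np.int64).sort_index()
    return kept.reset_index(drop=True), per_te
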