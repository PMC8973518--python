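"""Degenerate MAR-motif scanning: IUPAC patterns, gapped patterns, and the
bipartite MAR recognition signature (MRS).

Patterns are written in a compact notation: literal IUPAC letters, with
``n_k_`` denoting a fixed spacer of ``k`` unconstrained bases between two
literal segments (e.g. ``TAn_3_TGn_3_CA`` is TA, 3 any, TG, 3 any, CA — a
kinked-DNA signal). A lower-case ``n`` not followed by ``_k_`` is the IUPAC
``N`` inside a segment.

The built-in catalog covers the classical MAR-associated signals: replication
origin (ORI) ATTA/ATTTA/ATTTTA, TG-rich, curved DNA, kinked DNA,
topoisomerase II consensus sites, and the AT-rich WWWWWW signal. The MRS is
a pair of elements — an 8-mer (AATAAYAA) and a 16-mer (AWWRTAANNWWGNNNC) —
within 200 bp of each other, handled by :func:`scan_mrs`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import reverse_complement

__all__ = [
    "IUPAC",
    "MotifPattern",
    "MotifHit",
    "MRSHit",
    "PatternCompileError",
    "compile_pattern",
    "scan",
    "scan_mrs",
    "motif_abundance",
    "mrs_abundance",
    "builtin_catalog",
    "load_catalog",
    "MRS_8MER",
    "MRS_16MER",
]

# IUPAC degenerate nucleotide codes used by the catalog. Pattern N matches
# any sequence base including N; every other code fails on a sequence N so
# that masked regions do not inflate AT-rich counts.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}

MRS_8MER = "AATAAYAA"
MRS_16MER = "AWWRTAANNWWGNNNC"

# (motif_id, category, pattern spec) — the classical MAR-associated signal
# catalog. m_16 is the 18-position vertebrate topo-II consensus; the shorter
# 15-position variant is available as the alias m_16a but not scanned by
# default.
_BUILTIN_SPECS: tuple[tuple[str, str, str], ...] = (
    ("m_1", "ORI", "ATTA"),
    ("m_2", "ORI", "ATTTA"),
    ("m_3", "ORI", "ATTTTA"),
    ("m_4", "TG_rich", "TGTTTTG"),
    ("m_5", "TG_rich", "TGTTTTTTG"),
    ("m_6", "TG_rich", "TTTTGGGG"),
    ("m_7", "curved_DNA", "AAAAn_7_AAAAn_7_AAAA"),
    ("m_8", "curved_DNA", "TTTTn_7_TTTTn_7_TTTT"),
    ("m_9", "curved_DNA", "TTTAAA"),
    ("m_10", "kinked_DNA", "TAn_3_TGn_3_CA"),
    ("m_11", "kinked_DNA", "TAn_3_CAn_3_TG"),
    ("m_12", "kinked_DNA", "TGn_3_TAn_3_CA"),
    ("m_13", "kinked_DNA", "TGn_3_CAn_3_TA"),
    ("m_14", "kinked_DNA", "CAn_3_TAn_3_TG"),
    ("m_15", "kinked_DNA", "CAn_3_TGn_3_TA"),
    ("m_16", "mtopoII", "RnYnnCnnGYnGKTnYnY"),
    ("m_17", "dtopoII", "GTnWAYATTnATnnR"),
    ("m_18", "AT_rich", "WWWWWW"),
)

TOPOII_SHORT_VARIANT = ("m_16a", "mtopoII", "RnYnnGYnGKTnYnY")


class PatternCompileError(ValueError):
    """Raised on an unparsable pattern spec, naming the offending token."""


@dataclass(frozen=True)
class MotifPattern:
    """A compiled gapped degenerate pattern.

    ``segments`` are literal IUPAC strings and ``gaps`` the fixed spacer
    lengths between consecutive segments (``len(gaps) == len(segments) - 1``).
    """

    motif_id: str
    category: str
    segments: tuple[str, ...]
    gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.gaps) != len(self.segments) - 1:
            raise ValueError("need exactly one gap between consecutive segments")
        if any(g < 0 for g in self.gaps):
            raise ValueError("gaps must be >= 0")

    @property
    def span(self) -> int:
        return sum(len(s) for s in self.segments) + sum(self.gaps)

    def spec_string(self) -> str:
        """Render back to the compact notation (compile→render round-trip)."""
        parts = [self.segments[0]]
        for gap, seg in zip(self.gaps, self.segments[1:]):
            parts.append(f"n_{gap}_{seg}")
        return "".join(parts)

    def offsets(self) -> list[tuple[int, str]]:
        """(offset, segment) pairs relative to a match start."""
        out, pos = [], 0
        for i, seg in enumerate(self.segments):
            out.append((pos, seg))
            pos += len(seg)
            if i < len(self.gaps):
                pos += self.gaps[i]
        return out

    def to_regex(self) -> str:
        classes = {
            code: ("[ACGTN]" if code == "N" else "[" + "".join(sorted(bases)) + "]")
            for code, bases in IUPAC.items()
        }
        parts = []
        for i, seg in enumerate(self.segments):
            parts.append("".join(classes[c] for c in seg))
            if i < len(self.gaps) and self.gaps[i]:
                parts.append(f"[ACGTN]{{{self.gaps[i]}}}")
        return "".join(parts)


@dataclass(frozen=True)
class MotifHit:
    """A located pattern match; ``end - start`` equals the pattern span."""

    motif_id: str
    seq_id: str
    start: int
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class MRSHit:
    """A bipartite MRS occurrence: an 8-mer and a 16-mer within the window.

    ``separation`` is the gap between the two elements (0 when they overlap).
    """

    seq_id: str
    pos8: int
    pos16: int
    separation: int
    strand8: str = "+"
    strand16: str = "+"


_GAP_TOKEN = re.compile(r"n_(\d+)_")


def compile_pattern(
    spec: str, motif_id: str = "pattern", category: str = "custom"
) -> MotifPattern:
    """Compile a pattern spec such as ``"TAn_3_TGn_3_CA"``.

    ``n_k_`` tokens become fixed gaps of ``k`` bases; all other characters
    are IUPAC letters (case-insensitive; a bare ``n`` is IUPAC N). Whitespace
    is ignored. Unknown characters raise :class:`PatternCompileError`.
    """
    cleaned = "".join(spec.split())
    segments: list[str] = []
    gaps: list[int] = []
    pos = 0
    current = ""
    while pos < len(cleaned):
        m = _GAP_TOKEN.match(cleaned, pos)
        if m:
            if not current:
                raise PatternCompileError(
                    f"{spec!r}: gap token {m.group(0)!r} must follow a segment"
                )
            segments.append(current)
            gaps.append(int(m.group(1)))
            current = ""
            pos = m.end()
            continue
        ch = cleaned[pos].upper()
        if ch not in IUPAC:
            raise PatternCompileError(f"{spec!r}: unknown character {cleaned[pos]!r}")
        current += ch
        pos += 1
    if not current:
        raise PatternCompileError(f"{spec!r}: pattern may not end with a gap")
    segments.append(current)
    return MotifPattern(motif_id, category, tuple(segments), tuple(gaps))


def builtin_catalog(include_topoII_short: bool = False) -> list[MotifPattern]:
    """The built-in MAR-associated motif catalog (m_1 … m_18)."""
    specs = _BUILTIN_SPECS + ((TOPOII_SHORT_VARIANT,) if include_topoII_short else ())
    return [compile_pattern(spec, motif_id, category) for motif_id, category, spec in specs]


def load_catalog(path: str | Path) -> list[MotifPattern]:
    """Load a catalog override from TSV with columns motif_id, category, spec."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"motif_id", "category", "spec"}
    if not required.issubset(df.columns):
        raise ValueError(f"catalog TSV needs columns {sorted(required)}")
    return [
        compile_pattern(row.spec, row.motif_id, row.category)
        for row in df.itertuples()
    ]


def scan(
    seq: str,
    pattern: MotifPattern,
    strands: str = "forward",
    seq_id: str = "seq",
) -> list[MotifHit]:
    """All (overlapping) matches of ``pattern`` in ``seq``.

    With ``strands='both'`` the reverse complement is also scanned and hits
    are mapped back to forward coordinates with strand ``'-'``. Hits are
    distinct (start, strand) pairs, sorted by start.
    """
    if strands not in ("forward", "both"):
        raise ValueError("strands must be 'forward' or 'both'")
    seq = seq.upper()
    rx = re.compile(f"(?=({pattern.to_regex()}))")
    span = pattern.span
    hits = [
        MotifHit(pattern.motif_id, seq_id, m.start(), m.start() + span, "+")
        for m in rx.finditer(seq)
    ]
    if strands == "both":
        rc = reverse_complement(seq)
        n = len(seq)
        hits += [
            MotifHit(
                pattern.motif_id, seq_id, n - m.start() - span, n - m.start(), "-"
            )
            for m in rx.finditer(rc)
        ]
    return sorted(hits, key=lambda h: (h.start, h.strand))


def _element_gap(s1: int, e1: int, s2: int, e2: int) -> int:
    if e1 <= s2:
        return s2 - e1
    if e2 <= s1:
        return s1 - e2
    return 0


def scan_mrs(
    seq: str,
    window: int = 200,
    strands: str = "both",
    seq_id: str = "seq",
) -> list[MRSHit]:
    """MAR recognition signatures: 8-mer and 16-mer within ``window`` bp.

    Either element may precede the other, and by default both strands are
    searched for each element independently (a strict ``strands='forward'``
    mode is available). Pairs are deduplicated on (pos8, pos16).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    p8 = compile_pattern(MRS_8MER, "MRS_8mer", "MRS")
    p16 = compile_pattern(MRS_16MER, "MRS_16mer", "MRS")
    hits8 = scan(seq, p8, strands=strands, seq_id=seq_id)
    hits16 = scan(seq, p16, strands=strands, seq_id=seq_id)
    out: dict[tuple[int, int], MRSHit] = {}
    for h8 in hits8:
        for h16 in hits16:
            sep = _element_gap(h8.start, h8.end, h16.start, h16.end)
            if sep <= window and (h8.start, h16.start) not in out:
                out[(h8.start, h16.start)] = MRSHit(
                    seq_id, h8.start, h16.start, sep, h8.strand, h16.strand
                )
    return sorted(out.values(), key=lambda h: (h.pos8, h.pos16))


def motif_abundance(
    seqs: Mapping[str, str] | Sequence[str],
    catalog: Sequence[MotifPattern] | None = None,
    strands: str = "forward",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Total hit counts and presence percentages over a sequence collection.

    For each motif: ``total_hits`` is the number of distinct
    (motif, start, strand) matches summed over sequences; ``presence_pct`` is
    100 × (#sequences with >= 1 hit) / (#sequences). The second frame
    aggregates per category, where a sequence counts as positive if ANY motif
    of the category hits it.

    Returns (per-motif frame, per-category frame).
    """
    if catalog is None:
        catalog = builtin_catalog()
    if not catalog:
        raise ValueError("catalog must be non-empty")
    if not isinstance(seqs, Mapping):
        seqs = {f"seq{i}": s for i, s in enumerate(seqs)}
    if not seqs:
        raise ValueError("empty sequence collection")
    n_seqs = len(seqs)
    rows = []
    category_positive: dict[str, set[str]] = {}
    for pattern in catalog:
        total = 0
        with_hit = 0
        for sid, s in seqs.items():
            hits = scan(s, pattern, strands=strands, seq_id=sid)
            total += len(hits)
            if hits:
                with_hit += 1
                category_positive.setdefault(pattern.category, set()).add(sid)
        rows.append(
            {
                "motif_id": pattern.motif_id,
                "category": pattern.category,
                "spec": pattern.spec_string(),
                "total_hits": total,
                "n_seqs_with_hit": with_hit,
                "presence_pct": 100.0 * with_hit / n_seqs,
            }
        )
    per_motif = pd.DataFrame(rows)
    per_category = pd.DataFrame(
        [
            {
                "category": cat,
                "n_seqs_with_hit": len(category_positive.get(cat, ())),
                "presence_pct": 100.0 * len(category_positive.get(cat, ())) / n_seqs,
            }
            for cat in dict.fromkeys(p.category for p in catalog)
        ]
    )
    return per_motif, per_category


def mrs_abundance(
    seqs: Mapping[str, str] | Sequence[str],
    window: int = 200,
    strands: str = "both",
) -> dict[str, float]:
    """MRS totals and presence percentage over a sequence collection."""
    if not isinstance(seqs, Mapping):
        seqs = {f"seq{i}": s for i, s in enumerate(seqs)}
    if not seqs:
        raise ValueError("empty sequence collection")
    total = 0
    with_hit = 0
    for sid, s in seqs.items():
        hits = scan_mrs(s, window=window, strands=strands, seq_id=sid)
        total += len(hits)
        if hits:
            with_hit += 1
    return {
        "total_hits": total,
        "n_seqs_with_hit": with_hit,
        "presence_pct": 100.0 * with_hit / len(seqs),
    }


def hits_to_bed(hits: Iterable[MotifHit], path: str | Path) -> None:
    """Write motif hits as BED6 with the motif id in the name field."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.seq_id}\t{h.start}\t{h.end}\t{h.motif_id}\t0\t{h.strand}\n")
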