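"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (per-base masks, per-position character
checks, greedy run enumeration) and shares no code with the library paths it
validates.
"""

from __future__ import annotations

import numpy as np

IUPAC_SETS = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "W": "AT",
    "S": "CG",
    "K": "GT",
    "M": "AC",
    "N": "ACGTN",
}

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def occupancy_merge(intervals, span: int):
    """Union of intervals on one chromosome via a per-base boolean mask."""
    mask = np.zeros(span, dtype=bool)
    for start, end in intervals:
        mask[start:end] = True
    out = []
    i = 0
    while i < span:
        if mask[i]:
            j = i
            while j < span and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def occupancy_venn(sets, span: int):
    """Seven-region counts from per-base masks of three interval lists."""
    masks = []
    for ivs in sets:
        m = np.zeros(span, dtype=bool)
        for start, end in ivs:
            m[start:end] = True
        masks.append(m)
    union = masks[0] | masks[1] | masks[2]
    counts = {
        "onlyA": 0, "onlyB": 0, "onlyC": 0,
        "AB_only": 0, "AC_only": 0, "BC_only": 0, "ABC": 0,
    }
    key = {
        (True, False, False): "onlyA",
        (False, True, False): "onlyB",
        (False, False, True): "onlyC",
        (True, True, False): "AB_only",
        (True, False, True): "AC_only",
        (False, True, True): "BC_only",
        (True, True, True): "ABC",
    }
    i = 0
    while i < span:
        if union[i]:
            j = i
            while j < span and union[j]:
                j += 1
            member = tuple(bool(m[i:j].any()) for m in masks)
            counts[key[member]] += 1
            i = j
        else:
            i += 1
    return counts


def pattern_positions(spec_segments, gaps, seq: str):
    """All forward match starts of a gapped IUPAC pattern, checked per char."""
    offsets = []
    pos = 0
    for i, seg in enumerate(spec_segments):
        for c in seg:
            offsets.append((pos, c))
            pos += 1
        if i < len(gaps):
            pos += gaps[i]
    span = pos
    out = []
    for start in range(len(seq) - span + 1):
        ok = True
        for off, code in offsets:
            if seq[start + off] not in IUPAC_SETS[code]:
                ok = False
                break
        if ok:
            out.append(start)
    return out, span


def scan_oracle(seq: str, pattern, strands: str = "forward"):
    """(start, strand) match pairs via the naive per-position matcher."""
    starts, span = pattern_positions(pattern.segments, pattern.gaps, seq)
    hits = [(s, "+") for s in starts]
    if strands == "both":
        rc = revcomp(seq)
        starts_rc, _ = pattern_positions(pattern.segments, pattern.gaps, rc)
        n = len(seq)
        hits += [(n - s - span, "-") for s in starts_rc]
    return sorted(hits)


def mrs_oracle(seq: str, window: int = 200, strands: str = "both"):
    """Deduplicated (pos8, pos16) MRS pairs via the naive matcher."""

    def element_hits(spec: str):
        segs, gaps = (spec,), ()
        starts, span = pattern_positions(segs, gaps, seq)
        hits = [(s, s + span) for s in starts]
        if strands == "both":
            rc = revcomp(seq)
            starts_rc, _ = pattern_positions(segs, gaps, rc)
            n = len(seq)
            hits += [(n - s - span, n - s) for s in starts_rc]
        return sorted(set(hits))

    h8 = element_hits("AATAAYAA")
    h16 = element_hits("AWWRTAANNWWGNNNC")
    pairs = set()
    for s8, e8 in h8:
        for s16, e16 in h16:
            if e8 <= s16:
                sep = s16 - e8
            elif e16 <= s8:
                sep = s8 - e16
            else:
                sep = 0
            if sep <= window:
                pairs.add((s8, s16))
    return sorted(pairs)


def _min_period(unit: str) -> int:
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return p
    return len(unit)


def ssr_oracle(seq: str, min_reps: int = 5, unit_sizes=(2, 3, 4, 5, 6)):
    """Simple SSRs (unit, reps, start, end) by greedy maximal-run enumeration.

    Follows the same stated contract as the library (smallest-allowed-unit
    canonicalization, mononucleotide masquerade exclusion, left-to-right
    trimming of same-size overlaps) but enumerates runs character by
    character.
    """
    seq = seq.upper()
    n = len(seq)
    unit_sizes = sorted(set(unit_sizes))
    out = []
    for k in unit_sizes:
        if n < k * min_reps:
            continue
        # maximal k-periodic regions, found character by character
        j = 0
        regions = []
        while j < n - k:
            if seq[j] == seq[j + k]:
                i = j
                while j < n - k and seq[j] == seq[j + k]:
                    j += 1
                regions.append((i, j + k))  # [i, j+k) is k-periodic
            else:
                j += 1
        last_end = -1
        for i, region_end in regions:
            start = max(i, last_end)
            reps = (region_end - start) // k
            if reps < min_reps:
                continue
            unit = seq[start : start + k]
            p = _min_period(unit)
            if p < k and (p in unit_sizes or p == 1):
                continue
            end = start + reps * k
            out.append((unit, reps, start, end))
            last_end = end
    return sorted(out, key=lambda r: (r[2], r[3]))


def te_filter_oracle(rows, min_identity=90.0, min_length=100):
    """Plain predicate filter over (pident, length) tuples -> kept indices."""
    return [
        i
        for i, (pident, length) in enumerate(rows)
        if pident >= min_identity and length >= min_length
    ]


def pearson_oracle(x, y):
    """Closed-form sum formula for the product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    num = n * (x * y).sum() - x.sum() * y.sum()
    den = np.sqrt(n * (x**2).sum() - x.sum() ** 2) * np.sqrt(
        n * (y**2).sum() - y.sum() ** 2
    )
    return num / den
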