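"""Synthetic genomes, gene models, peak sets and planted sequence features.

Every generator is deterministic under a fixed seed and emits ground-truth
records, so each pipeline stage can be tested for exact recovery without any
external data. Defaults emulate the study system this package targets: a
small AT-rich multi-chromosome genome (GC ≈ 0.38, as in the silkworm
genome), peaks of 200–400 bp, three developmental peak sets whose sizes and
overlap structure scale the real datasets down to a few-megabase genome, and
MAR-associated motifs / MRS pairs / SSRs planted at configurable rates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_stats import GeneModel
from .intervals import VENN_REGIONS, GenomicInterval, IntervalSet, write_bed
from .motifs import IUPAC, MRS_16MER, MRS_8MER, MotifPattern, builtin_catalog, compile_pattern
from .seqio import write_fasta

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "make_genome",
    "make_peak_sets",
    "make_uniform_peaks",
    "make_gene_models",
    "write_gff",
    "plant_features",
    "plant_context_peaks",
    "plant_tss_peaks",
    "make_te_hits",
    "simulate",
]

_REGION_MEMBERSHIP = {
    "onlyA": (0,),
    "onlyB": (1,),
    "onlyC": (2,),
    "AB_only": (0, 1),
    "AC_only": (0, 2),
    "BC_only": (1, 2),
    "ABC": (0, 1, 2),
}

# Seven-region design scaling the three developmental peak sets (1861 / 6158
# / 11075 regions on a 460 Mb genome) down to the default 4.8 Mb genome while
# keeping the common/unique proportions of the union.
_DEFAULT_VENN = {
    "onlyA": 2,
    "onlyB": 28,
    "onlyC": 77,
    "AB_only": 3,
    "AC_only": 3,
    "BC_only": 23,
    "ABC": 10,
}

# Per-region planting probabilities chosen to mirror the observed presence
# percentages of the motif categories in real MAR sequences (AT-rich ~0.9,
# ORI ~0.77, curved ~0.1-0.2, kinked ~0.1, TG-rich and topo-II rare).
_DEFAULT_MOTIF_RATES = {
    "m_18": 0.92,
    "m_1": 0.77,
    "m_9": 0.15,
    "m_10": 0.12,
    "m_4": 0.02,
    "m_16": 0.01,
}

_DEFAULT_SSR_PLAN = (
    ("TATT", 5, 6),
    ("TGAA", 5, 4),
    ("AGTC", 5, 3),
    ("TTAGG", 5, 3),
    ("CCTAA", 5, 2),
    ("TACCAA", 5, 2),
    ("TTATTG", 5, 2),
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study bundle.

    The defaults describe the emulated study conditions: three chromosomes of
    1.6 Mb (a ~4.8 Mb genome), GC fraction 0.38, 50 genes per chromosome
    with 3 exons each, three peak sets with the seven-region overlap design
    above, and peaks 200–400 bp long.
    """

    seed: int = 0
    n_chroms: int = 3
    chrom_size_bp: int = 1_600_000
    gc_fraction: float = 0.38
    n_genes_per_chrom: int = 50
    exons_per_gene: int = 3
    exon_len: int = 400
    intron_len: int = 1200
    peak_length: tuple[int, int] = (200, 400)
    venn_design: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_VENN))
    peak_counts: tuple[int, int, int] | None = None
    dataset_labels: tuple[str, str, str] = ("SG1", "SG5", "SG7")
    motif_plant_rates: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MOTIF_RATES)
    )
    mrs_plant_rate: float = 0.09
    ssr_plan: tuple[tuple[str, int, int], ...] = _DEFAULT_SSR_PLAN

    def __post_init__(self) -> None:
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        lo, hi = self.peak_length
        if not 0 < lo <= hi < self.chrom_size_bp:
            raise ValueError("peak_length range must lie within (0, chrom_size_bp)")
        unknown = set(self.venn_design) - set(VENN_REGIONS)
        if unknown:
            raise ValueError(f"unknown venn regions: {sorted(unknown)}")
        if any(v < 0 for v in self.venn_design.values()):
            raise ValueError("venn region counts must be non-negative")
        implied = self.implied_peak_counts()
        if self.peak_counts is not None and tuple(self.peak_counts) != implied:
            raise ValueError(
                f"peak_counts {self.peak_counts} inconsistent with venn_design "
                f"(implies {implied})"
            )

    def implied_peak_counts(self) -> tuple[int, int, int]:
        counts = [0, 0, 0]
        for region, n in self.venn_design.items():
            for m in _REGION_MEMBERSHIP[region]:
                counts[m] += n
        return tuple(counts)

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass(frozen=True)
class TruthRecord:
    """One planted item (peak region, motif, SSR or MRS) with its coordinates."""

    kind: str
    chrom: str
    start: int
    end: int
    identity: str
    membership: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_genome(cfg: SyntheticConfig, rng: np.random.Generator | None = None) -> tuple[dict[str, str], dict[str, int]]:
    """Random genome with the configured base composition.

    Returns (``{chrom: sequence}``, ``{chrom: length}``). Byte-identical for
    a fixed seed (PCG64 stream, fixed consumption order).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    at = (1 - cfg.gc_fraction) / 2
    gc = cfg.gc_fraction / 2
    probs = [at, gc, gc, at]  # A C G T
    genome: dict[str, str] = {}
    sizes: dict[str, int] = {}
    for chrom in cfg.chrom_names:
        arr = rng.choice(_BASES, size=cfg.chrom_size_bp, p=probs)
        genome[chrom] = arr.tobytes().decode("ascii")
        sizes[chrom] = cfg.chrom_size_bp
    return genome, sizes


def make_peak_sets(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, IntervalSet], list[TruthRecord]]:
    """Three peak sets realizing the configured seven-region overlap design.

    Distinct truth regions are placed on a coarse slot grid so that they stay
    at least 2 bp apart (merging can never fuse two regions); a region shared
    by several datasets is the identical interval in each of them.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    design = {r: cfg.venn_design.get(r, 0) for r in VENN_REGIONS}
    total = sum(design.values())
    lo, hi = cfg.peak_length
    slot = hi + 2
    slots_per_chrom = cfg.chrom_size_bp // slot
    all_slots = [
        (chrom, i * slot)
        for chrom in cfg.chrom_names
        for i in range(slots_per_chrom)
    ]
    if total > len(all_slots):
        raise ValueError(
            f"infeasible design: {total} regions exceed {len(all_slots)} "
            "available placement slots"
        )
    chosen_idx = rng.choice(len(all_slots), size=total, replace=False)
    chosen = sorted(all_slots[i] for i in chosen_idx)
    region_labels = [r for r in VENN_REGIONS for _ in range(design[r])]
    rng.shuffle(region_labels)
    labels = cfg.dataset_labels
    sets: dict[str, list[GenomicInterval]] = {lab: [] for lab in labels}
    truth: list[TruthRecord] = []
    for (chrom, pos), region in zip(chosen, region_labels):
        length = int(rng.integers(lo, hi + 1))
        iv = GenomicInterval(chrom, pos, pos + length)
        membership = tuple(labels[m] for m in _REGION_MEMBERSHIP[region])
        for lab in membership:
            sets[lab].append(iv)
        truth.append(TruthRecord("peak-region", chrom, iv.start, iv.end, region, membership))
    return (
        {lab: IntervalSet(lab, sorted(ivs)) for lab, ivs in sets.items()},
        truth,
    )


def make_uniform_peaks(
    n_peaks: int,
    spacing_bp: int,
    chrom: str = "chr1",
    chrom_size: int | None = None,
    peak_len: int = 200,
    offset: int = 0,
    label: str = "uniform",
) -> IntervalSet:
    """Peaks with exactly uniform midpoint spacing (loop-length ground truth)."""
    if n_peaks < 2 or spacing_bp <= peak_len:
        raise ValueError("need >= 2 peaks and spacing larger than the peak length")
    last_end = offset + (n_peaks - 1) * spacing_bp + peak_len
    if chrom_size is not None and last_end > chrom_size:
        raise ValueError(f"{n_peaks} peaks at {spacing_bp} bp exceed chromosome size")
    return IntervalSet(
        label,
        [
            GenomicInterval(chrom, offset + i * spacing_bp, offset + i * spacing_bp + peak_len)
            for i in range(n_peaks)
        ],
    )


def make_gene_models(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Non-overlapping gene models with regular exon/intron structure.

    Genes are placed on a slot grid (gene length + a 3 kb spacer) with random
    strand; each gene has ``exons_per_gene`` exons of ``exon_len`` bp
    separated by ``intron_len`` bp introns.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    gene_len = cfg.exons_per_gene * cfg.exon_len + (cfg.exons_per_gene - 1) * cfg.intron_len
    slot = gene_len + 3000
    slots_per_chrom = cfg.chrom_size_bp // slot
    if cfg.n_genes_per_chrom > slots_per_chrom:
        raise ValueError(
            f"infeasible packing: {cfg.n_genes_per_chrom} genes need "
            f"{cfg.n_genes_per_chrom} slots, only {slots_per_chrom} fit"
        )
    genes: list[GeneModel] = []
    idx = 0
    for chrom in cfg.chrom_names:
        starts = np.sort(
            rng.choice(slots_per_chrom, size=cfg.n_genes_per_chrom, replace=False)
        )
        for s in starts:
            start = int(s) * slot + 1000
            exons = tuple(
                (
                    start + i * (cfg.exon_len + cfg.intron_len),
                    start + i * (cfg.exon_len + cfg.intron_len) + cfg.exon_len,
                )
                for i in range(cfg.exons_per_gene)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"BMSYN{idx:05d}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=exons[-1][1],
                    exons=exons,
                )
            )
            idx += 1
    return genes


def write_gff(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene + exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tmarseq\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tmarseq\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def _expand_pattern(pattern: MotifPattern, rng: np.random.Generator) -> str:
    """One concrete realization of a degenerate pattern (gaps random ACGT)."""
    out: list[str] = []
    for i, seg in enumerate(pattern.segments):
        for code in seg:
            choices = sorted(IUPAC[code] - {"N"}) or ["A", "C", "G", "T"]
            out.append(choices[int(rng.integers(len(choices)))])
        if i < len(pattern.gaps):
            out.extend(
                "ACGT"[int(rng.integers(4))] for _ in range(pattern.gaps[i])
            )
    return "".join(out)


def plant_features(
    seq: str,
    plan: Sequence[Mapping],
    rng: np.random.Generator | None = None,
    seed: int = 0,
    chrom: str = "seq",
) -> tuple[str, list[TruthRecord]]:
    """Write motifs, SSRs and MRS pairs into a sequence at planned positions.

    Each plan entry is a mapping with ``kind`` in {"motif", "ssr", "mrs"}:

    - motif: ``pos`` and ``pattern`` (a :class:`MotifPattern` or spec string);
      a concrete expansion is sampled uniformly per degenerate position.
    - ssr: ``pos``, ``unit``, ``n_reps`` — a perfect tandem.
    - mrs: ``pos`` and ``separation`` (<= 200): 8-mer, spacer, 16-mer.

    Planted spans must be in-bounds and pairwise non-overlapping; violations
    raise ``ValueError`` before the sequence is touched.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    resolved: list[tuple[int, str, str]] = []  # (pos, insert, identity)
    for entry in plan:
        kind = entry["kind"]
        pos = int(entry["pos"])
        if kind == "motif":
            pattern = entry["pattern"]
            if isinstance(pattern, str):
                pattern = compile_pattern(pattern)
            insert = _expand_pattern(pattern, rng)
            identity = pattern.motif_id
        elif kind == "ssr":
            insert = entry["unit"] * int(entry["n_reps"])
            identity = f"({entry['unit']}){entry['n_reps']}"
        elif kind == "mrs":
            sep = int(entry["separation"])
            if sep > 200:
                raise ValueError(f"MRS separation {sep} exceeds the 200 bp window")
            e8 = _expand_pattern(compile_pattern(MRS_8MER), rng)
            spacer = "".join("ACGT"[int(rng.integers(4))] for _ in range(sep))
            e16 = _expand_pattern(compile_pattern(MRS_16MER), rng)
            insert = e8 + spacer + e16
            identity = "MRS"
        else:
            raise ValueError(f"unknown plan kind {kind!r}")
        if pos < 0 or pos + len(insert) > len(seq):
            raise ValueError(f"planted {kind} at {pos} exceeds sequence bounds")
        resolved.append((pos, insert, identity))
    resolved.sort()
    for (p1, i1, _), (p2, _, _) in zip(resolved, resolved[1:]):
        if p1 + len(i1) > p2:
            raise ValueError(f"planted spans at {p1} and {p2} overlap")
    arr = bytearray(seq, "ascii")
    truth: list[TruthRecord] = []
    for pos, insert, identity in resolved:
        arr[pos : pos + len(insert)] = insert.encode("ascii")
        kind = "mrs" if identity == "MRS" else ("ssr" if identity.startswith("(") else "motif")
        if kind == "ssr":
            # guard bases so the tandem run cannot extend into the flanks,
            # keeping the reported unit identical to the planted one
            unit = identity.split(")")[0][1:]
            end = pos + len(insert)
            if pos > 0:
                choices = sorted(set("ACGT") - {unit[-1]})
                arr[pos - 1] = ord(choices[int(rng.integers(len(choices)))])
            if end < len(arr):
                choices = sorted(set("ACGT") - {unit[0]})
                arr[end] = ord(choices[int(rng.integers(len(choices)))])
        truth.append(TruthRecord(kind, chrom, pos, pos + len(insert), identity))
    return arr.decode("ascii"), truth


def plant_context_peaks(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    n_exonic: int,
    n_intronic: int,
    n_intergenic: int,
    peak_len: int = 100,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    label: str = "context",
) -> tuple[IntervalSet, list[str]]:
    """Peaks planted fully inside exons, introns, or intergenic space.

    Returns the peak set and the true context label of each peak, in set
    order, for validating genomic-context classification.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    exons = [(g.chrom, s, e) for g in genes for (s, e) in g.exons if e - s >= peak_len]
    introns = [
        (g.chrom, s, e) for g in genes for (s, e) in g.introns if e - s >= peak_len
    ]
    gaps: list[tuple[str, int, int]] = []
    for chrom, size in chrom_sizes.items():
        bounds = sorted((g.start, g.end) for g in by_chrom.get(chrom, []))
        prev = 0
        for s, e in bounds + [(size, size)]:
            if s - prev >= peak_len + 2:
                gaps.append((chrom, prev + 1, s - 1))
            prev = max(prev, e)
    if not exons and n_exonic:
        raise ValueError("no exon can hold a peak of the requested length")
    if not introns and n_intronic:
        raise ValueError("no intron can hold a peak of the requested length")
    if not gaps and n_intergenic:
        raise ValueError("no intergenic gap can hold a peak of the requested length")
    peaks: list[GenomicInterval] = []
    labels: list[str] = []
    for pool, n, name in (
        (exons, n_exonic, "exonic"),
        (introns, n_intronic, "intronic"),
        (gaps, n_intergenic, "non-genic"),
    ):
        for _ in range(n):
            chrom, s, e = pool[int(rng.integers(len(pool)))]
            start = int(rng.integers(s, e - peak_len + 1))
            peaks.append(GenomicInterval(chrom, start, start + peak_len))
            labels.append(name)
    return IntervalSet(label, peaks), labels


def plant_tss_peaks(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    n_peaks: int,
    sigma_bp: float = 5000.0,
    peak_len: int = 200,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    label: str = "tss",
) -> IntervalSet:
    """Peaks whose midpoints are Normal(0, sigma) around random gene TSSs.

    The offset is applied in the gene's orientation, so the signed TSS
    distances of the planted peaks are draws from Normal(0, sigma).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    peaks: list[GenomicInterval] = []
    half = peak_len // 2
    while len(peaks) < n_peaks:
        g = genes[int(rng.integers(len(genes)))]
        d = int(round(rng.normal(0.0, sigma_bp)))
        mid = g.tss + d if g.strand == "+" else g.tss - d
        start = mid - half
        if start < 0 or start + peak_len > chrom_sizes[g.chrom]:
            continue
        peaks.append(GenomicInterval(g.chrom, start, start + peak_len))
    return IntervalSet(label, peaks)


def make_te_hits(
    rng: np.random.Generator | None = None,
    seed: int = 0,
    n_pass: int = 12,
    n_fail: int = 10,
    te_names: Sequence[str] = ("L1Bm", "R1Bmks", "Gypsy"),
) -> tuple[pd.DataFrame, int]:
    """A synthetic blast outfmt-6 hit table with known threshold structure.

    ``n_pass`` hits satisfy (identity >= 90, length >= 100) — including a few
    exactly at the boundary — and ``n_fail`` hits violate at least one
    threshold. Returns (hit frame, number of passing hits).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []

    def add(pident: float, length: int) -> None:
        te = te_names[int(rng.integers(len(te_names)))]
        sstart = int(rng.integers(1, 5000))
        qstart = int(rng.integers(1, 500))
        rows.append(
            {
                "qseqid": te,
                "sseqid": f"chr{int(rng.integers(1, 4))}",
                "pident": round(pident, 2),
                "length": length,
                "mismatch": int(round(length * (100 - pident) / 100)),
                "gapopen": 0,
                "qstart": qstart,
                "qend": qstart + length - 1,
                "sstart": sstart,
                "send": sstart + length - 1,
                "evalue": 1e-10,
                "bitscore": float(length),
            }
        )

    add(90.0, 100)  # both thresholds exactly at the boundary
    add(90.0, 250)
    add(95.5, 100)
    for _ in range(n_pass - 3):
        add(float(rng.uniform(90.5, 100.0)), int(rng.integers(101, 400)))
    for i in range(n_fail):
        if i % 2 == 0:
            add(float(rng.uniform(60.0, 89.9)), int(rng.integers(100, 400)))
        else:
            add(float(rng.uniform(90.0, 100.0)), int(rng.integers(30, 100)))
    return pd.DataFrame(rows), n_pass


def simulate(outdir: str | Path, cfg: SyntheticConfig | None = None) -> dict:
    """Generate the full synthetic study bundle on disk.

    Writes ``genome.fa``, ``chrom_sizes.tsv``, one BED per dataset, a GFF3 of
    gene models, a gene→pathway table, a synthetic TE hit table and
    ``truth.json`` describing everything planted. Returns the truth dict.
    """
    if cfg is None:
        cfg = SyntheticConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genome, sizes = make_genome(cfg, rng)
    peak_sets, region_truth = make_peak_sets(cfg, rng)
    genes = make_gene_models(cfg, rng)

    # plant motifs / MRS / SSRs inside the distinct truth regions
    catalog = {p.motif_id: p for p in builtin_catalog()}
    arrays = {chrom: bytearray(s, "ascii") for chrom, s in genome.items()}
    feature_truth: list[TruthRecord] = []
    ssr_queue = [
        (unit, reps) for unit, reps, count in cfg.ssr_plan for _ in range(count)
    ]
    if ssr_queue:
        targets = rng.choice(len(region_truth), size=len(ssr_queue), replace=False)
        ssr_targets = {int(t): ssr_queue[i] for i, t in enumerate(targets)}
    else:
        ssr_targets = {}
    for ridx, region in enumerate(region_truth):
        cursor = region.start
        plan: list[dict] = []
        if ridx in ssr_targets:
            unit, reps = ssr_targets[ridx]
            span = len(unit) * reps
            if cursor + span + 2 <= region.end:
                plan.append({"kind": "ssr", "pos": cursor, "unit": unit, "n_reps": reps})
                cursor += span + 2
        for motif_id, rate in cfg.motif_plant_rates.items():
            if rng.random() >= rate:
                continue
            pattern = catalog[motif_id]
            if cursor + pattern.span + 2 > region.end:
                continue
            plan.append({"kind": "motif", "pos": cursor, "pattern": pattern})
            cursor += pattern.span + 2
        if rng.random() < cfg.mrs_plant_rate:
            sep = int(rng.integers(0, 121))
            span = 8 + sep + 16
            if cursor + span <= region.end:
                plan.append({"kind": "mrs", "pos": cursor, "separation": sep})
                cursor += span
        if not plan:
            continue
        chrom_seq = arrays[region.chrom].decode("ascii")
        mutated, truth = plant_features(chrom_seq, plan, rng=rng, chrom=region.chrom)
        arrays[region.chrom] = bytearray(mutated, "ascii")
        feature_truth.extend(
            dataclasses.replace(t, membership=region.membership) for t in truth
        )
    genome = {chrom: arr.decode("ascii") for chrom, arr in arrays.items()}

    write_fasta(genome, outdir / "genome.fa")
    pd.DataFrame(sizes.items()).to_csv(
        outdir / "chrom_sizes.tsv", sep="\t", header=False, index=False
    )
    for label, s in peak_sets.items():
        write_bed(s, outdir / f"{label}.bed")
    write_gff(genes, outdir / "genes.gff3")

    pathways = (
        "Metabolic pathways",
        "Genetic information processing",
        "Signal transduction",
        "Apoptosis",
        "Ribosome biogenesis",
        "Transcription",
        "DNA repair",
    )
    mapping_rows = [
        {"gene_id": g.gene_id, "pathway": pathways[int(rng.integers(len(pathways)))]}
        for g in genes
    ]
    pd.DataFrame(mapping_rows).to_csv(outdir / "pathways.tsv", sep="\t", index=False)

    te_hits, n_te_pass = make_te_hits(rng)
    te_hits.to_csv(outdir / "te_hits.tsv", sep="\t", header=False, index=False)

    truth = {
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(cfg).items()
                if not isinstance(v, dict)
            },
            "venn_design": cfg.venn_design,
            "motif_plant_rates": cfg.motif_plant_rates,
        },
        "venn_counts": {r: cfg.venn_design.get(r, 0) for r in VENN_REGIONS},
        "regions": [t.to_dict() for t in region_truth],
        "planted_features": [t.to_dict() for t in feature_truth],
        "n_genes": len(genes),
        "n_te_hits_passing": n_te_pass,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=list)
    return truth
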