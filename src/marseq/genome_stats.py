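"""Chromosome-wise MAR statistics, loop lengths, TSS profiles and annotation.

Gene models are read from GFF3 (1-based inclusive coordinates) and converted
to the package-wide 0-based half-open convention on input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .intervals import GenomicInterval, IntervalSet, merge_intervals, venn_partition

__all__ = [
    "GeneModel",
    "ContextCounts",
    "TSSProfile",
    "read_gff",
    "read_chrom_sizes",
    "chromosome_summary",
    "loop_lengths",
    "density_correlation",
    "classify_context",
    "tss_profile",
    "gene_flank_report",
    "pathway_join",
    "round_half_up",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon structure, in 0-based half-open coordinates.

    The transcription start site is ``start`` on the + strand and ``end - 1``
    on the − strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: require 0 <= start < end")
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise ValueError(
                    f"gene {self.gene_id}: exon ({s},{e}) outside gene body"
                )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        exons = sorted(self.exons)
        return tuple(
            (exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i + 1][0] > exons[i][1]
        )


@dataclass
class ContextCounts:
    """MAR counts by genomic context (exon > intron > non-genic precedence)."""

    n_exonic: int = 0
    n_intronic: int = 0
    n_nongenic: int = 0

    @property
    def total(self) -> int:
        return self.n_exonic + self.n_intronic + self.n_nongenic


@dataclass
class TSSProfile:
    """Binned signed MAR-midpoint distances to the nearest TSS."""

    window_bp: int
    bin_bp: int
    counts: np.ndarray
    n_within_window: int
    n_total: int

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(-self.window_bp, self.window_bp + self.bin_bp, self.bin_bp)

    def to_frame(self) -> pd.DataFrame:
        edges = self.bin_edges
        return pd.DataFrame(
            {"bin_start": edges[:-1], "bin_end": edges[1:], "count": self.counts}
        )

    @property
    def modal_bin_start(self) -> int:
        return int(self.bin_edges[int(np.argmax(self.counts))])


def read_gff(path: str | Path) -> list[GeneModel]:
    """Read gene and exon features from a GFF3/GTF-like file.

    Exons are linked to genes via their ``Parent`` attribute (falling back to
    ``gene_id``). GFF 1-based inclusive spans become 0-based half-open.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent") or exon.attributes.get("gene_id") or []
        for parent in parents:
            exons_by_gene.setdefault(parent, []).append((exon.start - 1, exon.end))
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand if g.strand in "+-" else "+",
                start=g.start - 1,
                end=g.end,
                exons=tuple(sorted(exons_by_gene.get(g.id, ()))),
            )
        )
    return genes


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV (chrom, length_bp) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def round_half_up(x: float, digits: int = 2) -> float:
    """Round half away from zero (matching common report formatting)."""
    factor = 10 ** digits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def _gene_counts(genes, chroms: Iterable[str]) -> dict[str, int]:
    if isinstance(genes, Mapping):
        return {c: int(genes.get(c, 0)) for c in chroms}
    counts: dict[str, int] = {c: 0 for c in chroms}
    for g in genes:
        if g.chrom in counts:
            counts[g.chrom] += 1
    return counts


def chromosome_summary(
    mars: IntervalSet,
    chrom_sizes: Mapping[str, int],
    genes: Sequence[GeneModel] | Mapping[str, int] | None = None,
    strict: bool = True,
    digits: int = 2,
) -> pd.DataFrame:
    """Per-chromosome MAR and gene counts with densities per Mb.

    ``genes`` may be a collection of :class:`GeneModel` or a precomputed
    ``{chrom: gene_count}`` mapping. Densities are reported both raw and
    rounded (half away from zero) to ``digits`` decimals. Chromosomes present
    in ``mars`` but missing from ``chrom_sizes`` raise in strict mode;
    otherwise they are pooled into a residual ``unplaced`` row carrying counts
    only.
    """
    mars = merge_intervals(mars)
    by_chrom = mars.by_chrom()
    missing = [c for c in by_chrom if c not in chrom_sizes]
    if missing and strict:
        raise KeyError(
            f"chromosomes missing from size table: {', '.join(sorted(missing))}"
        )
    gene_counts = _gene_counts(genes if genes is not None else {}, chrom_sizes.keys())
    rows = []
    for chrom, size_bp in chrom_sizes.items():
        size_mb = size_bp / 1e6
        ivs = by_chrom.get(chrom, [])
        n_genes = gene_counts.get(chrom, 0)
        mids = np.array([iv.midpoint for iv in ivs])
        mean_loop_kb = float(np.diff(np.sort(mids)).mean() / 1e3) if len(ivs) >= 2 else np.nan
        rows.append(
            {
                "chrom": chrom,
                "size_mb": size_mb,
                "n_genes": n_genes,
                "gene_density_raw": n_genes / size_mb,
                "mar_count": len(ivs),
                "mar_density_raw": len(ivs) / size_mb,
                "mean_loop_kb": mean_loop_kb,
            }
        )
    if missing:
        n_unplaced = sum(len(by_chrom[c]) for c in missing)
        rows.append(
            {
                "chrom": "unplaced",
                "size_mb": np.nan,
                "n_genes": 0,
                "gene_density_raw": np.nan,
                "mar_count": n_unplaced,
                "mar_density_raw": np.nan,
                "mean_loop_kb": np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df["gene_density"] = [
        round_half_up(x, digits) if np.isfinite(x) else np.nan
        for x in df["gene_density_raw"]
    ]
    df["mar_density"] = [
        round_half_up(x, digits) if np.isfinite(x) else np.nan
        for x in df["mar_density_raw"]
    ]
    return df[
        [
            "chrom",
            "size_mb",
            "n_genes",
            "gene_density",
            "mar_count",
            "mar_density",
            "mean_loop_kb",
            "gene_density_raw",
            "mar_density_raw",
        ]
    ]


def loop_lengths(
    mars: IntervalSet,
    method: str = "midpoint",
    aggregate: str = "per_chromosome_mean",
) -> tuple[pd.Series, float]:
    """Inter-MAR distances as a chromatin loop-length proxy.

    ``method='midpoint'`` measures consecutive midpoint-to-midpoint
    distances; ``method='gap'`` measures end-to-next-start gaps. The overall
    average (kb) is either the mean of per-chromosome means or the mean over
    all distances pooled (``aggregate='global_mean'``). Chromosomes with
    fewer than two MARs contribute nothing.

    Returns (per-chromosome mean loop length in kb, overall average in kb).
    """
    if method not in ("midpoint", "gap"):
        raise ValueError("method must be 'midpoint' or 'gap'")
    if aggregate not in ("per_chromosome_mean", "global_mean"):
        raise ValueError("aggregate must be 'per_chromosome_mean' or 'global_mean'")
    mars = merge_intervals(mars)
    per_chrom: dict[str, float] = {}
    all_dists: list[np.ndarray] = []
    for chrom, ivs in mars.by_chrom().items():
        if len(ivs) < 2:
            continue
        ivs = sorted(ivs)
        if method == "midpoint":
            pos = np.array([iv.midpoint for iv in ivs])
            dists = np.diff(pos)
        else:
            dists = np.array(
                [ivs[i + 1].start - ivs[i].end for i in range(len(ivs) - 1)], dtype=float
            )
        per_chrom[chrom] = float(dists.mean() / 1e3)
        all_dists.append(dists)
    series = pd.Series(per_chrom, name="mean_loop_kb").sort_index()
    if not per_chrom:
        return series, float("nan")
    if aggregate == "per_chromosome_mean":
        overall = float(series.mean())
    else:
        overall = float(np.concatenate(all_dists).mean() / 1e3)
    return series, overall


def density_correlation(summary: pd.DataFrame, x: str, y: str) -> dict[str, float]:
    """Pearson r (with Spearman rho as a secondary statistic) across chromosomes.

    Rows with NaN in either column (e.g. the residual unplaced row) are
    dropped. Zero variance in either column yields NaN coefficients.
    """
    cols = summary[[x, y]].dropna()
    n = len(cols)
    if n < 3:
        raise ValueError("need at least 3 chromosomes for a correlation")
    xv, yv = cols[x].to_numpy(float), cols[y].to_numpy(float)
    if np.std(xv) == 0 or np.std(yv) == 0:
        return {"r": float("nan"), "rho": float("nan"), "n": n}
    r, _ = stats.pearsonr(xv, yv)
    rho, _ = stats.spearmanr(xv, yv)
    return {"r": float(r), "rho": float(rho), "n": n}


def classify_context(
    mars: IntervalSet, genes: Sequence[GeneModel]
) -> tuple[ContextCounts, list[str]]:
    """Label each MAR exonic, intronic or non-genic.

    Precedence: a MAR overlapping any exon by >= 1 bp is exonic; otherwise a
    MAR overlapping any gene body is intronic; otherwise non-genic. Returns
    the aggregate counts and one label per input MAR, in input order.
    """
    exon_trees: dict[str, IntervalTree] = {}
    gene_trees: dict[str, IntervalTree] = {}
    for g in genes:
        gene_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
        for s, e in g.exons:
            exon_trees.setdefault(g.chrom, IntervalTree()).addi(s, e)
    counts = ContextCounts()
    labels: list[str] = []
    for iv in mars:
        if iv.chrom in exon_trees and exon_trees[iv.chrom].overlap(iv.start, iv.end):
            labels.append("exonic")
            counts.n_exonic += 1
        elif iv.chrom in gene_trees and gene_trees[iv.chrom].overlap(iv.start, iv.end):
            labels.append("intronic")
            counts.n_intronic += 1
        else:
            labels.append("non-genic")
            counts.n_nongenic += 1
    return counts, labels


def tss_profile(
    mars: IntervalSet,
    genes: Sequence[GeneModel],
    window: int = 100_000,
    bin: int = 10_000,
) -> TSSProfile:
    """Distribution of signed MAR distances to the nearest TSS.

    For every MAR the signed distance from its midpoint to the nearest TSS is
    computed strand-aware: positive means downstream of the TSS in the gene's
    orientation. Ties between equidistant TSSs resolve to the smaller
    gene_id. Distances with |d| <= window are binned into ``2*window/bin``
    bins; a distance of exactly +window falls in the last bin.
    """
    if window <= 0 or bin <= 0 or (2 * window) % bin != 0:
        raise ValueError("require window > 0, bin > 0 and bin dividing 2*window")
    if not genes:
        raise ValueError("no genes supplied")
    tss_by_chrom: dict[str, list[tuple[int, str, str]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id, g.strand))
    for chrom in tss_by_chrom:
        tss_by_chrom[chrom].sort()
    n_bins = (2 * window) // bin
    counts = np.zeros(n_bins, dtype=np.int64)
    n_within = 0
    n_total = 0
    for iv in mars:
        if iv.chrom not in tss_by_chrom:
            continue
        n_total += 1
        entries = tss_by_chrom[iv.chrom]
        positions = [t[0] for t in entries]
        mid = iv.midpoint
        i = np.searchsorted(positions, mid)
        candidates = []
        if i > 0:
            candidates.append(entries[i - 1])
        if i < len(entries):
            candidates.append(entries[i])
        # nearest by absolute distance; tie -> smaller gene_id
        best = min(candidates, key=lambda t: (abs(mid - t[0]), t[1]))
        tss, _, strand = best
        d = mid - tss if strand == "+" else tss - mid
        if abs(d) <= window:
            n_within += 1
            idx = int((d + window) // bin)
            if idx == n_bins:  # d == +window exactly
                idx -= 1
            counts[idx] += 1
    return TSSProfile(window, bin, counts, n_within, n_total)


def gene_flank_report(
    mars_by_dataset: Mapping[str, IntervalSet],
    gene: GeneModel,
    flank: int,
    min_overlap: int = 1,
) -> dict:
    """MARs per dataset within ``[gene_start − flank, gene_end + flank)``.

    Returns the window, per-dataset restricted interval sets and counts and —
    when exactly three datasets are given — the Venn partition of the
    restricted sets (unique/common MARs in the flank window).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    win_start = max(0, gene.start - flank)
    win_end = gene.end + flank
    restricted = {
        label: s.merge().restrict(gene.chrom, win_start, win_end)
        for label, s in mars_by_dataset.items()
    }
    report = {
        "gene_id": gene.gene_id,
        "chrom": gene.chrom,
        "window": (win_start, win_end),
        "datasets": restricted,
        "counts": {label: len(s) for label, s in restricted.items()},
    }
    if len(restricted) == 3:
        a, b, c = restricted.values()
        report["venn"] = venn_partition(a, b, c, min_overlap=min_overlap)
    return report


def pathway_join(
    mar_genes: Iterable[str], mapping: pd.DataFrame
) -> tuple[pd.Series, list[str]]:
    """Count MAR-associated genes per pathway via the gene→pathway mapping.

    ``mapping`` must have columns ``gene_id`` and ``pathway``. Genes absent
    from the mapping are returned in the unmapped list rather than silently
    dropped. A gene annotated to several pathways counts once in each.
    """
    if mapping.empty:
        raise ValueError("empty gene->pathway mapping")
    if not {"gene_id", "pathway"}.issubset(mapping.columns):
        raise ValueError("mapping must have columns 'gene_id' and 'pathway'")
    gene_list = list(dict.fromkeys(mar_genes))
    genes_df = pd.DataFrame({"gene_id": gene_list})
    joined = genes_df.merge(mapping, on="gene_id", how="left")
    unmapped = sorted(joined.loc[joined["pathway"].isna(), "gene_id"].unique())
    counts = (
        joined.dropna(subset=["pathway"])
        .groupby("pathway")["gene_id"]
        .nunique()
        .sort_values(ascending=False)
    )
    counts.name = "n_genes"
    return counts, unmapped
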