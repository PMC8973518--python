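"""End-to-end orchestration: merge → compare → annotate → scan → report.

:func:`run_pipeline` wires the module operations together over a
:class:`RunConfig`, writing one TSV/JSON per stage plus a manifest
(parameters, package version, input checksums) sufficient to reproduce the
run. Stages whose optional inputs are missing are skipped with a logged
notice; any stage error aborts the run naming the failing stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genome_stats import (
    chromosome_summary,
    classify_context,
    density_correlation,
    gene_flank_report,
    loop_lengths,
    pathway_join,
    read_chrom_sizes,
    read_gff,
    tss_profile,
)
from .intervals import (
    GenomicInterval,
    IntervalSet,
    length_distribution,
    merge_intervals,
    read_bed,
    venn_partition,
    write_bed,
)
from .motifs import builtin_catalog, load_catalog, motif_abundance, mrs_abundance
from .repeats import find_ssrs, read_blast_tab, ssr_class_summary, te_hit_filter
from .seqio import extract_sequences

logger = logging.getLogger("marseq")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the failing stage."""


@dataclass
class RunConfig:
    """Inputs and parameter overrides for a full pipeline run."""

    beds: dict[str, str]  # label -> BED path (2 or 3 datasets; venn needs 3)
    chrom_sizes: str
    outdir: str
    fasta: str | None = None
    gff: str | None = None
    pathway_map: str | None = None
    te_hits: str | None = None
    catalog: str | None = None
    min_overlap: int = 1
    loop_method: str = "midpoint"
    loop_aggregate: str = "per_chromosome_mean"
    tss_window: int = 100_000
    tss_bin: int = 10_000
    length_bin: int = 100
    motif_strands: str = "forward"
    ssr_min_reps: int = 5
    ssr_unit_sizes: tuple[int, ...] = (2, 3, 4, 5, 6)
    ssr_max_interruption: int = 100
    te_min_identity: float = 90.0
    te_min_length: int = 100
    flank_genes: list[tuple[str, int]] = field(default_factory=list)
    strict_chroms: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "flank_genes" in data:
            data["flank_genes"] = [tuple(x) for x in data["flank_genes"]]
        if "ssr_unit_sizes" in data:
            data["ssr_unit_sizes"] = tuple(data["ssr_unit_sizes"])
        return cls(**data)

    def input_paths(self) -> dict[str, str]:
        paths = {f"bed:{label}": p for label, p in self.beds.items()}
        paths["chrom_sizes"] = self.chrom_sizes
        for name in ("fasta", "gff", "pathway_map", "te_hits", "catalog"):
            value = getattr(self, name)
            if value:
                paths[name] = value
        return paths


def _md5(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every applicable stage; return the run manifest."""
    for name, path in cfg.input_paths().items():
        if not Path(path).exists():
            raise PipelineError(f"startup: input {name} not found: {path}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {
            k: v for k, v in dataclasses.asdict(cfg).items() if k not in ("beds",)
        },
        "inputs": {n: {"path": p, "md5": _md5(p)} for n, p in cfg.input_paths().items()},
        "outputs": [],
        "skipped": [],
    }

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"].append(name)

    def skip(stage: str, reason: str) -> None:
        logger.info("skipping %s: %s", stage, reason)
        manifest["skipped"].append({"stage": stage, "reason": reason})

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    try:
        current = stage("merge")
        merged: dict[str, IntervalSet] = {}
        for label, path in cfg.beds.items():
            merged[label] = merge_intervals(read_bed(path, label))
            write_bed(merged[label], outdir / f"merged_{label}.bed")
            manifest["outputs"].append(f"merged_{label}.bed")
            hist = length_distribution(merged[label], cfg.length_bin)
            emit(f"length_hist_{label}.tsv", hist.reset_index())

        current = stage("venn")
        if len(merged) == 3:
            a, b, c = merged.values()
            venn = venn_partition(a, b, c, min_overlap=cfg.min_overlap)
            emit("venn.tsv", venn.to_frame())
            for region, ivs in venn.regions.items():
                write_bed(ivs, outdir / f"venn_{region}.bed")
                manifest["outputs"].append(f"venn_{region}.bed")
            pct = venn.percentages()
            emit(
                "venn_percentages.tsv",
                pd.DataFrame([{"statistic": k, "percent": v} for k, v in pct.items()]),
            )
        else:
            venn = None
            skip("venn", f"need exactly 3 datasets, got {len(merged)}")

        current = stage("chromstats")
        sizes = read_chrom_sizes(cfg.chrom_sizes)
        genes = read_gff(cfg.gff) if cfg.gff else None
        for label, s in merged.items():
            summary = chromosome_summary(
                s, sizes, genes, strict=cfg.strict_chroms
            )
            emit(f"chromstats_{label}.tsv", summary)

        current = stage("loops")
        loop_rows = []
        for label, s in merged.items():
            per_chrom, overall = loop_lengths(
                s, method=cfg.loop_method, aggregate=cfg.loop_aggregate
            )
            for chrom, kb in per_chrom.items():
                loop_rows.append({"dataset": label, "chrom": chrom, "mean_loop_kb": kb})
            loop_rows.append(
                {"dataset": label, "chrom": "overall", "mean_loop_kb": overall}
            )
        emit("loops.tsv", pd.DataFrame(loop_rows))

        current = stage("correlation")
        corr_rows = []
        for label, s in merged.items():
            summary = chromosome_summary(s, sizes, genes, strict=cfg.strict_chroms)
            summary = summary[summary["chrom"] != "unplaced"]
            if len(summary) >= 3:
                corr = density_correlation(summary, "mar_count", "gene_density_raw")
                corr_rows.append({"dataset": label, **corr})
        if corr_rows:
            emit("correlations.tsv", pd.DataFrame(corr_rows))
        else:
            skip("correlation", "fewer than 3 chromosomes")

        current = stage("context")
        if genes:
            rows = []
            for label, s in merged.items():
                counts, _ = classify_context(s, genes)
                rows.append(
                    {
                        "dataset": label,
                        "exonic": counts.n_exonic,
                        "intronic": counts.n_intronic,
                        "non_genic": counts.n_nongenic,
                    }
                )
            emit("context.tsv", pd.DataFrame(rows))
            current = stage("tss")
            for label, s in merged.items():
                profile = tss_profile(s, genes, window=cfg.tss_window, bin=cfg.tss_bin)
                emit(f"tss_{label}.tsv", profile.to_frame())
        else:
            skip("context", "no GFF supplied")
            skip("tss", "no GFF supplied")

        if cfg.fasta:
            current = stage("motifs")
            catalog = load_catalog(cfg.catalog) if cfg.catalog else builtin_catalog()
            motif_rows, category_rows, mrs_rows, ssr_frames = [], [], [], []
            for label, s in merged.items():
                seqs = extract_sequences(cfg.fasta, s)
                per_motif, per_category = motif_abundance(
                    seqs, catalog, strands=cfg.motif_strands
                )
                per_motif.insert(0, "dataset", label)
                per_category.insert(0, "dataset", label)
                motif_rows.append(per_motif)
                category_rows.append(per_category)
                mrs = mrs_abundance(seqs)
                mrs_rows.append({"dataset": label, **mrs})
                current = stage(f"ssr:{label}")
                records = [
                    r
                    for sid, seq in seqs.items()
                    for r in find_ssrs(
                        seq,
                        min_reps=cfg.ssr_min_reps,
                        unit_sizes=cfg.ssr_unit_sizes,
                        max_interruption=cfg.ssr_max_interruption,
                        seq_id=sid,
                    )
                ]
                frame = pd.DataFrame(
                    [
                        {
                            "seq_id": r.seq_id,
                            "unit": r.unit,
                            "unit_size": r.unit_size,
                            "n_reps": r.n_reps,
                            "start": r.start,
                            "end": r.end,
                            "kind": r.kind,
                        }
                        for r in records
                    ]
                )
                emit(f"ssr_{label}.tsv", frame)
                summary = ssr_class_summary(records)
                summary.insert(0, "dataset", label)
                ssr_frames.append(summary)
            emit("motif_counts.tsv", pd.concat(motif_rows, ignore_index=True))
            emit("motif_categories.tsv", pd.concat(category_rows, ignore_index=True))
            emit("mrs.tsv", pd.DataFrame(mrs_rows))
            emit("ssr_summary.tsv", pd.concat(ssr_frames, ignore_index=True))
        else:
            skip("motifs", "no FASTA supplied")
            skip("mrs", "no FASTA supplied")
            skip("ssr", "no FASTA supplied")

        current = stage("tefilter")
        if cfg.te_hits:
            hits = read_blast_tab(cfg.te_hits)
            kept, per_te = te_hit_filter(
                hits, min_identity=cfg.te_min_identity, min_length=cfg.te_min_length
            )
            emit("te_filtered.tsv", kept)
            emit("te_occupancy.tsv", per_te.rename_axis("te_name").reset_index())
        else:
            skip("tefilter", "no TE hit table supplied")

        current = stage("flank")
        if cfg.flank_genes and genes:
            gene_index = {g.gene_id: g for g in genes}
            for gene_id, flank in cfg.flank_genes:
                if gene_id not in gene_index:
                    raise PipelineError(f"flank: gene {gene_id} not found in GFF")
                report = gene_flank_report(merged, gene_index[gene_id], flank)
                rows = [
                    {"dataset": label, "n_mars": n}
                    for label, n in report["counts"].items()
                ]
                if "venn" in report:
                    for region, count in report["venn"].counts.items():
                        rows.append({"dataset": f"venn:{region}", "n_mars": count})
                emit(f"flank_{gene_id}.tsv", pd.DataFrame(rows))
        elif cfg.flank_genes:
            skip("flank", "no GFF supplied")

        current = stage("pathways")
        if cfg.pathway_map and genes:
            mapping = pd.read_csv(cfg.pathway_map, sep="\t")
            mar_genes = []
            union = merge_intervals(
                IntervalSet("union", [iv for s in merged.values() for iv in s])
            )
            for g in genes:
                gene_iv = GenomicInterval(g.chrom, g.start, g.end)
                if any(gene_iv.overlap_bp(iv) > 0 for iv in union):
                    mar_genes.append(g.gene_id)
            counts, unmapped = pathway_join(mar_genes, mapping)
            emit("pathways.tsv", counts.reset_index())
            emit("pathways_unmapped.tsv", pd.DataFrame({"gene_id": unmapped}))
        elif cfg.pathway_map:
            skip("pathways", "no GFF supplied")
        else:
            skip("pathways", "no pathway mapping supplied")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=list)
    return manifest
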