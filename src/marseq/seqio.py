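"""FASTA helpers: writing genomes and extracting interval sequences."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from .intervals import GenomicInterval

__all__ = ["write_fasta", "extract_sequences"]


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def extract_sequences(
    fasta: str | Path | Mapping[str, str],
    intervals: Iterable[GenomicInterval],
) -> dict[str, str]:
    """Fetch the sequence under each interval, keyed ``chrom:start-end``.

    ``fasta`` may be a path (read through pyfaidx) or an in-memory
    ``{chrom: sequence}`` mapping.
    """
    out: dict[str, str] = {}
    if isinstance(fasta, Mapping):
        for iv in intervals:
            out[f"{iv.chrom}:{iv.start}-{iv.end}"] = fasta[iv.chrom][iv.start : iv.end]
        return out
    fa = Fasta(str(fasta))
    for iv in intervals:
        out[f"{iv.chrom}:{iv.start}-{iv.end}"] = str(fa[iv.chrom][iv.start : iv.end])
    return out
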