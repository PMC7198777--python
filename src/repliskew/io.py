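"""Readers and writers for the plain-text formats the pipeline touches.

FASTA and FASTQ go through Biopython; GFF3 and bedGraph are flat
tab-separated tables handled with pandas.  All genomic output follows the
format conventions: FASTA wrapped at 60 columns, GFF3 1-based inclusive,
bedGraph 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import CircularGenome, GeneRecord
from .skew import CumulativeProfile, WindowedProfile


def read_fasta(path: str | Path) -> list[CircularGenome]:
    """Load every record of a (multi-)FASTA as a circular genome."""
    genomes = [CircularGenome(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(str(path), "fasta")]
    if not genomes:
        raise ValueError(f"no FASTA records in {path}")
    return genomes


def write_fasta(genome: CircularGenome, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")


def read_gff3(path: str | Path, feature_types: tuple = ("gene", "CDS"),
              genome_length: int | None = None) -> list[GeneRecord]:
    """Extract gene intervals from a GFF3 file (1-based inclusive on disk).

    Features whose type is not in ``feature_types`` are skipped; wrap-around
    genes (end past the genome length) are split at the origin.
    """
    cols = ["seqid", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols,
                     dtype={"start": int, "end": int})
    genes: list[GeneRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        if row.type not in feature_types or row.strand not in ("+", "-"):
            continue
        start0, end0 = row.start - 1, row.end  # to 0-based half-open
        gid = f"{row.seqid}_{i}"
        if genome_length is not None and end0 > genome_length:
            genes.append(GeneRecord(start0, genome_length, row.strand, id=gid + "a"))
            genes.append(GeneRecord(0, end0 - genome_length, row.strand, id=gid + "b"))
        else:
            genes.append(GeneRecord(start0, end0, row.strand, id=gid))
    return genes


def write_gff3(genes: list[GeneRecord], genome_id: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            attrs = f"ID={gene.id}" if gene.id else "."
            fh.write(f"{genome_id}\trepliskew\tgene\t{gene.start + 1}\t{gene.end}"
                     f"\t.\t{gene.strand}\t.\t{attrs}\n")


def write_bedgraph(chrom: str, window: int, counts: np.ndarray,
                   genome_length: int, path: str | Path) -> None:
    """One line per window, 0-based half-open, final window clipped at L."""
    n = len(counts)
    with open(path, "w") as fh:
        for i, value in enumerate(counts):
            start = i * window
            end = (i + 1) * window if i < n - 1 else genome_length
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_fluorescence_csv(path: str | Path) -> np.ndarray:
    """Per-event fluorescence from a one-column CSV (header optional)."""
    try:
        first = pd.read_csv(path, header=None, nrows=1).iloc[0, 0]
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"no fluorescence values in {path}") from exc
    header = 0 if isinstance(first, str) else None
    values = pd.read_csv(path, header=header).iloc[:, 0].to_numpy(dtype=float)
    if len(values) == 0:
        raise ValueError(f"no fluorescence values in {path}")
    return values


def write_profile_tsv(profile: WindowedProfile, cum: CumulativeProfile | None,
                      path: str | Path) -> None:
    """Tab-separated (position, value, cumulative) profile dump."""
    df = pd.DataFrame({"position": profile.starts, "value": profile.values})
    if cum is not None:
        df["cumulative"] = cum.cum_values
    df.to_csv(path, sep="\t", index=False)
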