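"""Readers and writers for the standard formats the pipelines exchange.

FASTA via Biopython, VCF via pysam, FASTQ via Biopython; BED, GFF3,
bedGraph and all summary tables as tab-separated text through pandas.
SNP tables use 0-based positions in memory and 1-based positions on the
VCF side, as the formats require.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_vcf(
    snps: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    path: str | os.PathLike,
) -> None:
    """Write a substitution-SNP table (0-based ``pos``) as uncompressed VCF."""
    header = pysam.VariantHeader()
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in snps.itertuples():
            out.write(
                out.new_record(
                    contig=rec.chrom,
                    start=int(rec.pos),
                    stop=int(rec.pos) + 1,
                    alleles=(rec.ref, rec.alt),
                )
            )


def read_vcf(path: str | os.PathLike) -> pd.DataFrame:
    """Read substitution SNPs from a VCF into (chrom, pos, ref, alt), 0-based.

    Records that are not single-base substitutions are skipped.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(rec.ref) != 1 or len(alts) != 1 or len(alts[0]) != 1:
                continue
            rows.append((rec.contig, rec.start, rec.ref, alts[0]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def write_fastq(reads: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write reads (columns read_id, sequence) as FASTQ with uniform quality."""
    records = []
    for rec in reads.itertuples():
        r = SeqRecord(Seq(rec.sequence), id=rec.read_id, description="")
        r.letter_annotations["phred_quality"] = [40] * len(rec.sequence)
        records.append(r)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | os.PathLike) -> pd.DataFrame:
    rows = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]
    return pd.DataFrame(rows, columns=["read_id", "sequence"])


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read the first 3-4 BED columns (0-based half-open)."""
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    return df


def write_bed(intervals: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "fragment_id") if c in intervals]
    intervals[cols].to_csv(str(path), sep="\t", header=False, index=False)


def read_gff_genes(path: str | os.PathLike) -> pd.DataFrame:
    """Gene intervals from a GFF3 file, converted to 0-based half-open."""
    names = [
        "seqid", "source", "type", "start", "end",
        "score", "strand", "phase", "attributes",
    ]
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#", names=names)
    genes = df[df["type"] == "gene"].copy()
    genes["start"] = genes["start"] - 1  # GFF is 1-based inclusive
    return genes[["seqid", "start", "end"]].rename(columns={"seqid": "chrom"})


def write_bedgraph(
    windows: pd.DataFrame, path: str | os.PathLike, value_col: str = "value"
) -> None:
    """Write per-window values as bedGraph; missing values are omitted."""
    sub = windows.dropna(subset=[value_col])
    sub[["chrom", "start", "end", value_col]].to_csv(
        str(path), sep="\t", header=False, index=False
    )


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(str(path), sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")
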