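"""Plain-text readers and writers for the pipeline's file formats.

Annotation is a GTF-like TSV (one row per segment), tags are an
extended BED (single-nt intervals marking the read 5' position, name =
experimental:random barcode), expression and design are TSV, term sets
are GMT, sequences are FASTA.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import GenomeAnnotation

_ANN_COLS = ["gene_id", "chrom", "strand", "seg_type", "start", "end"]
_BED_COLS = ["chrom", "start", "end", "name", "score", "strand",
             "genotype", "replicate"]


def write_annotation(ann: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#chrom_len\t{ann.chrom}\t{ann.chrom_len}\n")
        ann.segments[_ANN_COLS].to_csv(fh, sep="\t", index=False)


def read_annotation(path: str | Path) -> GenomeAnnotation:
    """Rebuild a GenomeAnnotation from its TSV (plant sites are not
    serialized; target status is inferred from segment ids only when a
    ``genes`` table can be reconstructed, with is_target False)."""
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        chrom, chrom_len = header[1], int(header[2])
        segments = pd.read_csv(fh, sep="\t")
    gene_rows = []
    real = segments[~segments["gene_id"].str.endswith("_nc")]
    for gid, sub in real.groupby("gene_id"):
        gene_rows.append(
            (gid, sub["strand"].iloc[0], int(sub["start"].min()),
             int(sub["end"].max()), False)
        )
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "strand", "start", "end", "is_target"]
    ).set_index("gene_id")
    return GenomeAnnotation(chrom, chrom_len, segments, genes)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_reads_bed(reads: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "start": reads["position"],
            "end": reads["position"] + 1,
            "name": reads["exp_barcode"] + ":" + reads["rand_barcode"],
            "score": 1,
            "strand": reads["strand"],
            "genotype": reads["genotype"],
            "replicate": reads["replicate"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_reads_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=_BED_COLS)
    name = bed["name"].str.split(":", expand=True)
    return pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "position": bed["start"],
            "strand": bed["strand"],
            "exp_barcode": name[0],
            "rand_barcode": name[1],
            "genotype": bed["genotype"],
            "replicate": bed["replicate"],
        }
    )


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_gmt(terms: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in terms.items():
            fh.write("\t".join([name, name] + list(members)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    terms: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                terms[parts[0]] = parts[2:]
    return terms
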