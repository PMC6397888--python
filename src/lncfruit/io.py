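"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, GFF3/GTF via gffutils, tables as TSV-with-header via
pandas.  Genomic coordinates are 1-based closed on disk and 0-based
half-open in memory.
"""

from __future__ import annotations

import os
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    EvidenceTable,
    ExpressionMatrix,
    GenomicInterval,
    SampleSheet,
    Transcript,
    VALID_BASES,
)


def _normalize_sequence(seq: str, record_id: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(
            f"record {record_id!r}: invalid bases {sorted(bad)} "
            "(expected A/C/G/T/N, U is mapped to T)"
        )
    return seq


def read_fasta(path: str | os.PathLike) -> list[Transcript]:
    """Read transcripts from FASTA; uppercased, U->T, ids must be unique."""
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        seen.add(record.id)
        seq = str(record.seq)
        if not seq:
            raise ValueError(f"record {record.id!r} has an empty sequence")
        transcripts.append(Transcript(record.id, _normalize_sequence(seq, record.id)))
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description="") for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_annotation(
    path: str | os.PathLike, dialect: str = "GFF3"
) -> dict[str, tuple[GenomicInterval, str]]:
    """Map transcript_id -> (interval, gene_id) from a GFF3 or GTF file.

    Transcripts absent from the file are simply absent from the map
    (de-novo assembled transcripts carry no genomic coordinates).
    """
    if dialect not in ("GFF3", "GTF"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    out: dict[str, tuple[GenomicInterval, str]] = {}
    for feat in db.features_of_type("transcript"):
        if feat.start > feat.end:
            raise ValueError(
                f"feature on {feat.seqid}: start {feat.start} > end {feat.end}"
            )
        if dialect == "GTF":
            if "transcript_id" not in feat.attributes:
                raise ValueError(
                    f"GTF transcript feature on {feat.seqid}:{feat.start} "
                    "lacks a transcript_id attribute"
                )
            tid = feat.attributes["transcript_id"][0]
            gene = feat.attributes.get("gene_id", [tid])[0]
        else:
            tid = feat.attributes.get("ID", [feat.id])[0]
            gene = feat.attributes.get(
                "Parent", feat.attributes.get("gene_id", [tid])
            )[0]
        interval = GenomicInterval(
            feat.seqid, feat.start - 1, feat.end, feat.strand or "."
        )
        out[tid] = (interval, gene)
    return out


def write_gff3(
    entries: dict[str, tuple[GenomicInterval, str]],
    path: str | os.PathLike,
    source: str = "lncfruit",
) -> None:
    """Write transcript (and parent gene) features as GFF3 (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        genes_seen: set[str] = set()
        for tid, (iv, gene) in entries.items():
            start, end = iv.start + 1, iv.end
            if gene not in genes_seen:
                genes_seen.add(gene)
                fh.write(
                    f"{iv.chrom}\t{source}\tgene\t{start}\t{end}\t.\t"
                    f"{iv.strand}\t.\tID={gene}\n"
                )
            fh.write(
                f"{iv.chrom}\t{source}\ttranscript\t{start}\t{end}\t.\t"
                f"{iv.strand}\t.\tID={tid};Parent={gene}\n"
            )


def read_matrix(
    path: str | os.PathLike,
    unit: str = "counts",
    lengths: pd.Series | None = None,
) -> ExpressionMatrix:
    """Read a feature x sample TSV (first column = feature id)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.index.duplicated().any():
        dups = sorted(set(table.index[table.index.duplicated()]))
        raise ValueError(f"duplicate feature ids: {dups[:5]}")
    return ExpressionMatrix(table, unit=unit, lengths=lengths)


def write_matrix(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    if matrix.unit == "counts":
        out.to_csv(path, sep="\t")
    else:
        out.to_csv(path, sep="\t", float_format="%.10g")


def read_lengths(path: str | os.PathLike) -> pd.Series:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return table.iloc[:, 0].astype(float)


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t"))


def read_evidence(path: str | os.PathLike) -> EvidenceTable:
    return EvidenceTable(pd.read_csv(path, sep="\t"))


def read_edge_table(path: str | os.PathLike) -> pd.DataFrame:
    """PPI edge list: node_a, node_b, confidence."""
    table = pd.read_csv(path, sep="\t")
    required = {"node_a", "node_b", "confidence"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"edge table missing columns: {sorted(missing)}")
    return table


def read_term_map(path: str | os.PathLike) -> dict[str, set[str]]:
    """Gene->term TSV (term_id, gene_id[, description]) as term -> genes."""
    table = pd.read_csv(path, sep="\t")
    if not {"term_id", "gene_id"} <= set(table.columns):
        raise ValueError("term map needs term_id and gene_id columns")
    return {
        term: set(group["gene_id"]) for term, group in table.groupby("term_id")
    }


def read_ct_table(path: str | os.PathLike) -> pd.DataFrame:
    """qPCR Ct table: gene, condition, ct_target, ct_reference."""
    table = pd.read_csv(path, sep="\t")
    required = {"gene", "condition", "ct_target", "ct_reference"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return table
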