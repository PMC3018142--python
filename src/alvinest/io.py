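"""File I/O: FASTA + phred QUAL pairs, edge lists, hit tables, GFF3.

FASTA and QUAL parsing is delegated to Biopython; the helpers here pair the
two files by record id and move between files and :class:`QualityRead`
objects.  All writers emit deterministic, plain-text output.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cleaning import QualityRead


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file as (id, sequence) tuples."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def read_fasta_qual(
    fasta_path: str | os.PathLike, qual_path: str | os.PathLike
) -> list[QualityRead]:
    """Read paired FASTA/QUAL files (matched by record id) as QualityReads."""
    quals = {
        rec.id: rec.letter_annotations["phred_quality"]
        for rec in SeqIO.parse(str(qual_path), "qual")
    }
    reads = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in quals:
            raise ValueError(f"no QUAL record for read {rec.id}")
        reads.append(
            QualityRead(
                id=rec.id, seq=str(rec.seq), qual=np.array(quals[rec.id])
            )
        )
    return reads


def write_fasta_qual(
    reads: Iterable[QualityRead],
    fasta_path: str | os.PathLike,
    qual_path: str | os.PathLike,
    masked_lowercase: bool = False,
) -> None:
    """Write reads to FASTA + QUAL (same record order in both files)."""
    reads = list(reads)
    with open(fasta_path, "w") as fh:
        for read in reads:
            seq = read.display_seq() if masked_lowercase else read.seq
            fh.write(f">{read.id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(qual_path, "w") as fh:
        for read in reads:
            fh.write(f">{read.id}\n")
            vals = [str(int(q)) for q in read.qual]
            for i in range(0, len(vals), 20):
                fh.write(" ".join(vals[i : i + 20]) + "\n")


def read_edge_list(path: str | os.PathLike) -> pd.DataFrame:
    """Read a 3-column TSV edge list (node_a, node_b, combined_score)."""
    df = pd.read_csv(
        str(path),
        sep="\t",
        header=None,
        names=["node_a", "node_b", "combined_score"],
        comment="#",
        dtype={"node_a": str, "node_b": str},
    )
    bad = df["combined_score"].isna() | (df["combined_score"] < 0) | (
        df["combined_score"] > 1
    )
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise ValueError(f"malformed edge row at line {line}")
    return df


def write_edge_list(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(str(path), sep="\t", header=False, index=False)


def read_hit_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a (query, subject, taxon, evalue) homology hit TSV."""
    return pd.read_csv(
        str(path),
        sep="\t",
        header=0,
        dtype={"query": str, "subject": str, "taxon": str},
    )


def write_gff3(features: Iterable[dict], path: str | os.PathLike) -> None:
    """Write CDS/UTR features as GFF3 (1-based inclusive coordinates).

    Each feature dict needs: seqid, source, type, start, end (0-based
    half-open; converted on output), strand, frame ('.' allowed),
    attributes (str).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f["seqid"],
                        f.get("source", "alvinest"),
                        f["type"],
                        str(f["start"] + 1),
                        str(f["end"]),
                        f.get("score", "."),
                        f["strand"],
                        str(f.get("frame", ".")),
                        f.get("attributes", "."),
                    ]
                )
                + "\n"
            )
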