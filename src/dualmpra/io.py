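"""Flat-file I/O: FASTQ, FASTA, BED6, TSV.

FASTQ parsing goes through Biopython's ``FastqGeneralIterator`` (the fast
title/seq/qual path); everything simulated is written with constant Q37
qualities, matching modern high-accuracy basecalls.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Tuple

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

Q37 = "F"  # Phred+33 encoding of quality 37


def write_fastq(path, seqs: Iterable[str], prefix: str = "read") -> int:
    """Write sequences as 4-line FASTQ records with flat Q37 qualities."""
    n = 0
    with open(path, "w") as fh:
        for i, seq in enumerate(seqs):
            fh.write(f"@{prefix}_{i:07d}\n{seq}\n+\n{Q37 * len(seq)}\n")
            n += 1
    return n


def read_fastq(path) -> Iterator[Tuple[str, str]]:
    """Yield ``(name, sequence)`` pairs from a FASTQ file."""
    with open(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq


def read_fastq_pairs(path1, path2) -> Iterator[Tuple[str, str]]:
    """Yield ``(seq1, seq2)`` from two position-paired FASTQ files."""
    with open(path1) as fh1, open(path2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (_t1, s1, _q1), (_t2, s2, _q2) in zip(it1, it2):
            yield s1, s2


def write_fasta(path, records: Iterable[Tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed6(path, df: pd.DataFrame) -> None:
    """Write a BED6 file (0-based half-open) from a DataFrame with columns
    chrom, start, end, name, score, strand (missing score/strand filled)."""
    out = df.copy()
    if "score" not in out:
        out["score"] = 0
    if "strand" not in out:
        out["strand"] = "+"
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed6(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    for col in ("name", "score", "strand"):
        if col not in df:
            df[col] = {"name": ".", "score": 0, "strand": "+"}[col]
    return df


def write_tsv(path, df: pd.DataFrame, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    return df
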