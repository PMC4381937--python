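"""Readers and writers for the plain-text genomic formats used throughout.

Genomes travel as FASTA, interval annotations as BED (0-based, half-open),
per-CG tracks (methylation %, DNase cut counts) as bedGraph-like TSV, and
simulated bisulfite reads as FASTQ.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    """A (simulated) sequencing read; the name carries its provenance."""

    name: str
    sequence: str


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: list[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def read_fastq(path: str | Path) -> list[Read]:
    return [Read(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write a BED file from a frame with contig/start/end (+ optional name column)."""
    cols = [c for c in ("contig", "start", "end") if c in intervals.columns]
    extra = [c for c in intervals.columns if c not in cols]
    intervals[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    base = ["contig", "start", "end"]
    if names is None:
        names = base + [f"col{i}" for i in range(3, df.shape[1])]
    df.columns = names[: df.shape[1]]
    return df


def write_bedgraph(track: pd.DataFrame, path: str | Path, value_cols: list[str]) -> None:
    """bedGraph-like TSV: contig, start, end then the requested value columns."""
    cols = ["contig", "start", "end"] + value_cols
    track[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path, value_cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = ["contig", "start", "end"] + value_cols
    return df
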