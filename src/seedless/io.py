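"""File-format helpers shared by the command-line interface.

Guides and UTRs travel as FASTA (via Biopython); read pools as FASTQ or
one-sequence-per-line text; everything tabular as TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .site_grammar import MirnaGuide
from .targetome_survey import SiteAnnotation, UtrRecord

__all__ = [
    "read_guides",
    "read_reads",
    "read_utrs",
    "read_tsv",
    "write_tsv",
    "annotations_to_frame",
]


def read_guides(path: str | Path) -> list[MirnaGuide]:
    """Guides from a single- or multi-record FASTA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [MirnaGuide(r.id, str(r.seq)) for r in records]


def read_reads(path: str | Path) -> list[str]:
    """Read pool from FASTQ (by extension) or plain one-read-per-line text."""
    path = Path(path)
    if path.suffix.lower() in (".fastq", ".fq"):
        return [str(r.seq) for r in SeqIO.parse(str(path), "fastq")]
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_utrs(path: str | Path) -> list[UtrRecord]:
    return [
        UtrRecord(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")
    ]


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def annotations_to_frame(annotations: Iterable[SiteAnnotation]) -> pd.DataFrame:
    """BED-like table (1-based inclusive coordinates)."""
    return pd.DataFrame(
        [
            {
                "utr_id": a.utr_id,
                "start": a.start,
                "end": a.end,
                "mirna": a.mirna,
                "category": a.category,
                "supplementary_3p": a.supplementary_3p,
                "ambiguous": a.ambiguous,
            }
            for a in annotations
        ]
    )
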