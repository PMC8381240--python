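"""Shared file-format helpers (FASTA genomes, TSV tables)."""

from __future__ import annotations

import io
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

__all__ = ["load_fasta", "read_tsv", "fasta_text"]


def load_fasta(source: str | Path) -> dict[str, str]:
    """Read a (multi-record, free line-wrap) FASTA into a chrom -> sequence dict.

    ``source`` may be a path or FASTA-formatted text (detected by a leading '>').
    """
    text = _as_text(source)
    handle = io.StringIO(text)
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def fasta_text(genome: Mapping[str, str], width: int = 70) -> str:
    """Render a chrom -> sequence mapping as FASTA text."""
    chunks = []
    for name, seq in genome.items():
        chunks.append(f">{name}")
        for i in range(0, len(seq), width):
            chunks.append(seq[i : i + width])
    return "\n".join(chunks) + "\n"


def read_tsv(source: str | Path) -> pd.DataFrame:
    """Read a tab-separated table (path or literal text) with string-safe NA handling."""
    text = _as_text(source, sniff=("\t", "\n"))
    return pd.read_csv(io.StringIO(text), sep="\t")


def _as_text(source: str | Path, sniff: tuple[str, ...] = (">",)) -> str:
    """Treat ``source`` as literal text when it looks like the format, else as a path."""
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        if source.lstrip().startswith(sniff[0]) or any(ch in source for ch in sniff):
            return source
        return Path(source).read_text()
    raise TypeError(f"expected path or text, got {type(source)!r}")
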