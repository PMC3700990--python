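"""FASTQ / TSV input-output helpers (plain-text formats only)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ file into a list of (read id, sequence) pairs."""
    return [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path,
                quality_char: str = "I") -> int:
    """Write (id, sequence) pairs as FASTQ with a constant quality string."""
    n = 0
    with open(path, "w") as handle:
        for rid, seq in records:
            handle.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n


def write_tsv(frame: pd.DataFrame, path: str | Path,
              header_comment: str | None = None, index: bool = False) -> None:
    """Write a TSV table, optionally preceded by '#'-prefixed comment lines."""
    with open(path, "w") as handle:
        if header_comment:
            for line in header_comment.splitlines():
                handle.write(f"# {line}\n")
        frame.to_csv(handle, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_library_tsv(counts: dict[str, int], path: str | Path) -> None:
    """Persist a read multiset as a two-column (sequence, copies) TSV."""
    frame = pd.DataFrame(
        {"sequence": list(counts.keys()), "copies": list(counts.values())}
    )
    frame.to_csv(path, sep="\t", index=False)


def read_library_tsv(path: str | Path) -> dict[str, int]:
    frame = pd.read_csv(path, sep="\t", dtype={"sequence": str, "copies": int})
    return dict(zip(frame["sequence"], frame["copies"]))
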