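"""Exact full-length read mapping on both strands, and count aggregation.

A read maps to a reference wherever the full read sequence matches a
reference substring with 100% identity, on either strand. Every occurrence
is reported. Aggregation distinguishes redundant counts (read copies) from
unique counts (distinct sequences), and library totals count each read once
even when it hits several references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .refs import ReferenceSet, revcomp

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class Alignment:
    """One exact occurrence of a read on a reference.

    Coordinates are 0-based half-open on the forward reference strand;
    for strand '-', the read equals the reverse complement of
    ``ref[start:end]``.
    """

    read: str
    copies: int
    ref_id: str
    start: int
    end: int
    strand: str


@dataclass
class AlignmentTable:
    rows: list[Alignment] = field(default_factory=list)
    skipped_reads: int = 0  # reads with non-ACGT characters or empty

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.read, r.copies, r.ref_id, r.start, r.end, r.strand)
                for r in self.rows
            ],
            columns=["read", "copies", "ref_id", "start", "end", "strand"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_bed(self, path: str | Path) -> None:
        """BED6: chrom, start, end, name=read sequence, score=copies, strand."""
        with open(path, "w") as handle:
            for r in self.rows:
                handle.write(
                    f"{r.ref_id}\t{r.start}\t{r.end}\t{r.read}\t{r.copies}\t{r.strand}\n"
                )


def _read_counts(reads) -> Mapping[str, int]:
    # Accept a ReadLibrary, a mapping seq->copies, or an iterable of seqs.
    if hasattr(reads, "counts"):
        return reads.counts
    if isinstance(reads, Mapping):
        return reads
    out: dict[str, int] = {}
    for seq in reads:
        out[seq] = out.get(seq, 0) + 1
    return out


def map_exact(reads, refs: ReferenceSet) -> AlignmentTable:
    """Report every full-length 100%-identity occurrence on either strand.

    Parameters
    ----------
    reads
        A ``ReadLibrary``, a mapping ``sequence -> copy count``, or an
        iterable of sequences (copies counted by repetition).
    refs
        The reference set to scan.

    Reads containing characters outside A/C/G/T (or empty reads) are
    skipped and tallied in ``AlignmentTable.skipped_reads``.
    """
    counts = _read_counts(reads)
    # Index both the read and its reverse complement so a single window
    # lookup per reference position finds hits on both strands. A
    # palindromic read is indexed twice and reported on both strands,
    # matching a naive per-strand scan.
    index: dict[str, list[tuple[str, str]]] = {}
    lengths: set[int] = set()
    skipped = 0
    for seq in counts:
        if not seq or not _ACGT.issuperset(seq):
            skipped += 1
            continue
        index.setdefault(seq, []).append((seq, "+"))
        index.setdefault(revcomp(seq), []).append((seq, "-"))
        lengths.add(len(seq))

    rows: list[Alignment] = []
    get = index.get
    for ref_id, ref_seq in refs.items():
        n = len(ref_seq)
        for L in sorted(lengths):
            if L > n:
                continue
            for i in range(n - L + 1):
                hits = get(ref_seq[i : i + L])
                if hits:
                    for read_seq, strand in hits:
                        rows.append(
                            Alignment(read_seq, counts[read_seq], ref_id, i, i + L, strand)
                        )
    return AlignmentTable(rows=rows, skipped_reads=skipped)


@dataclass
class CountTable:
    """Per-reference and per-library mapping counts for one read library.

    ``per_reference`` is indexed by reference id with columns
    redundant_sense / redundant_antisense / unique_sense / unique_antisense;
    per-reference redundant counts sum read copies over every occurrence,
    while the library totals count each distinct read's copies once even if
    the read hits multiple references or positions.
    """

    library: str
    per_reference: pd.DataFrame
    redundant_mapped_total: int
    unique_mapped_total: int
    references_hit: int
    mapped_sequences: frozenset = frozenset()

    COLUMNS = (
        "redundant_sense",
        "redundant_antisense",
        "unique_sense",
        "unique_antisense",
    )

    def redundant(self) -> pd.Series:
        frame = self.per_reference
        return frame["redundant_sense"] + frame["redundant_antisense"]

    def unique(self) -> pd.Series:
        frame = self.per_reference
        return frame["unique_sense"] + frame["unique_antisense"]

    def to_tsv(self, path: str | Path) -> None:
        frame = self.per_reference.copy()
        frame.insert(0, "ref_id", frame.index)
        frame.to_csv(path, sep="\t", index=False)


def count_by_reference(aln: AlignmentTable, lib) -> CountTable:
    """Aggregate an alignment table into per-reference and library counts."""
    counts = _read_counts(lib)
    label = getattr(lib, "condition", "library")

    red: dict[str, dict[str, int]] = {}
    uniq_sets: dict[tuple[str, str], set[str]] = {}
    mapped: set[str] = set()
    for row in aln:
        cell = red.setdefault(
            row.ref_id, {"redundant_sense": 0, "redundant_antisense": 0}
        )
        key = "redundant_sense" if row.strand == "+" else "redundant_antisense"
        cell[key] += row.copies
        uniq_sets.setdefault((row.ref_id, row.strand), set()).add(row.read)
        mapped.add(row.read)

    ref_ids = sorted(red)
    frame = pd.DataFrame(
        {
            "redundant_sense": [red[r]["redundant_sense"] for r in ref_ids],
            "redundant_antisense": [red[r]["redundant_antisense"] for r in ref_ids],
            "unique_sense": [len(uniq_sets.get((r, "+"), ())) for r in ref_ids],
            "unique_antisense": [len(uniq_sets.get((r, "-"), ())) for r in ref_ids],
        },
        index=pd.Index(ref_ids, name="ref_id"),
        dtype=int,
    )
    return CountTable(
        library=label,
        per_reference=frame,
        redundant_mapped_total=sum(counts[s] for s in mapped),
        unique_mapped_total=len(mapped),
        references_hit=len(ref_ids),
        mapped_sequences=frozenset(mapped),
    )


def combine_count_tables(tables: Iterable[CountTable],
                         label: str = "total") -> CountTable:
    """Aggregate per-library count tables into a total table.

    Redundant totals add across libraries. When the per-library tables
    carry their mapped-sequence sets, the combined unique total is the size
    of the union of distinct mapped sequences (typically below the
    per-library sum); otherwise it falls back to the plain sum.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no count tables to combine")
    frame = (
        pd.concat([t.per_reference for t in tables])
        .groupby(level=0)
        .sum()
        .astype(int)
    )
    frame.index.name = "ref_id"
    have_seqs = all(t.mapped_sequences for t in tables) or all(
        t.unique_mapped_total == len(t.mapped_sequences) for t in tables
    )
    if have_seqs:
        union = frozenset().union(*(t.mapped_sequences for t in tables))
        unique_total = len(union)
    else:
        union = frozenset()
        unique_total = sum(t.unique_mapped_total for t in tables)
    return CountTable(
        library=label,
        per_reference=frame,
        redundant_mapped_total=sum(t.redundant_mapped_total for t in tables),
        unique_mapped_total=unique_total,
        references_hit=int((frame.sum(axis=1) > 0).sum()),
        mapped_sequences=union,
    )


def library_totals_table(per_library: Mapping[str, CountTable]) -> pd.DataFrame:
    """Shape per-library totals plus the combined row like a summary table."""
    rows = []
    for lib, table in per_library.items():
        rows.append(
            (lib, table.redundant_mapped_total, table.unique_mapped_total,
             table.references_hit)
        )
    combined = combine_count_tables(per_library.values())
    rows.append(
        ("Total", combined.redundant_mapped_total,
         combined.unique_mapped_total, combined.references_hit)
    )
    return pd.DataFrame(
        rows, columns=["library", "redundant", "unique", "references_mapped"]
    )
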