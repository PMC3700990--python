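"""Reference sequence sets (genome contigs, CDSs, ESTs, contaminants)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_KINDS = ("genome", "cds", "est", "contaminant")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceSet:
    """A named collection of reference sequences of one kind.

    Sequences are stored in insertion order; ids must be unique. For
    ``kind == "cds"`` the stop-codon anchor of a sequence is the 0-based
    index of the first nucleotide of its final codon.
    """

    kind: str
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown reference kind: {self.kind!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self.sequences

    def __getitem__(self, ref_id: str) -> str:
        return self.sequences[ref_id]

    def items(self):
        return self.sequences.items()

    def length(self, ref_id: str) -> int:
        return len(self.sequences[ref_id])

    def lengths(self) -> dict[str, int]:
        return {rid: len(s) for rid, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def stop_anchor(self, ref_id: str) -> int:
        """0-based index of the first nt of the stop codon (CDSs only)."""
        if self.kind != "cds":
            raise ValueError("stop anchor defined only for CDS references")
        return len(self.sequences[ref_id]) - 3

    def to_fasta(self, path: str | Path) -> None:
        records = (
            SeqRecord(Seq(seq), id=rid, description="")
            for rid, seq in self.sequences.items()
        )
        with open(path, "w") as handle:
            SeqIO.write(records, handle, "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path, kind: str) -> "ReferenceSet":
        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(kind=kind, sequences=seqs)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str], kind: str) -> "ReferenceSet":
        return cls(kind=kind, sequences=dict(mapping))
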