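"""Demultiplexing, adapter/barcode trimming, size selection, decontamination.

All stages operate on :class:`ReadLibrary`, which keeps the distinct-sequence
view (``unique_total``) and per-sequence copy counts (``redundant_total``)
plus provenance counters, so that at every stage the raw input count equals
the sum of all outcome counters.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .refs import ReferenceSet
from . import mapper


@dataclass
class StageCounters:
    raw: int = 0
    untrimmable: int = 0
    size_rejected: int = 0
    contaminant_rejected: int = 0
    retained: int = 0

    def check(self) -> None:
        total = (
            self.untrimmable
            + self.size_rejected
            + self.contaminant_rejected
            + self.retained
        )
        if total != self.raw:
            raise AssertionError(
                f"counter conservation violated: raw={self.raw} sum={total}"
            )

    def as_dict(self) -> dict[str, int]:
        return {
            "raw": self.raw,
            "untrimmable": self.untrimmable,
            "size_rejected": self.size_rejected,
            "contaminant_rejected": self.contaminant_rejected,
            "retained": self.retained,
        }


@dataclass
class ReadLibrary:
    """A condition-labelled multiset of read sequences."""

    condition: str
    counts: Counter = field(default_factory=Counter)
    counters: StageCounters = field(default_factory=StageCounters)

    @property
    def redundant_total(self) -> int:
        return sum(self.counts.values())

    @property
    def unique_total(self) -> int:
        return len(self.counts)

    def sequences(self) -> Iterable[str]:
        return self.counts.keys()


@dataclass
class DemuxResult:
    libraries: dict[str, ReadLibrary]
    unknown_barcode: int
    total_reads: int


def _validate_barcodes(barcode_map: Mapping[str, str]) -> int:
    barcodes = list(barcode_map.values())
    if not barcodes:
        raise ValueError("empty barcode map")
    lengths = {len(b) for b in barcodes}
    if len(lengths) != 1:
        raise ValueError("barcodes must all have the same length")
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("ambiguous barcode table: duplicate barcodes")
    return lengths.pop()


def demultiplex_and_trim(
    reads: Iterable[str] | Iterable[tuple[str, str]],
    barcode_map: Mapping[str, str],
    adapter3: str,
) -> DemuxResult:
    """Assign raw reads to conditions and strip barcode + 3' adapter.

    The barcode is an exact prefix; the adapter is removed at its first
    exact occurrence after the barcode. Reads with an unknown barcode or no
    adapter match are dropped and counted.
    """
    bc_len = _validate_barcodes(barcode_map)
    if not adapter3:
        raise ValueError("empty 3' adapter")
    by_barcode = {bc: cond for cond, bc in barcode_map.items()}
    libs = {
        cond: ReadLibrary(condition=cond) for cond in barcode_map
    }
    unknown = 0
    total = 0
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        total += 1
        cond = by_barcode.get(seq[:bc_len])
        if cond is None:
            unknown += 1
            continue
        lib = libs[cond]
        lib.counters.raw += 1
        body = seq[bc_len:]
        idx = body.find(adapter3)
        if idx < 0:
            lib.counters.untrimmable += 1
            continue
        lib.counts[body[:idx]] += 1
        lib.counters.retained += 1
    return DemuxResult(libraries=libs, unknown_barcode=unknown, total_reads=total)


def size_filter(lib: ReadLibrary, min_len: int, max_len: int) -> ReadLibrary:
    """Keep reads with min_len <= length <= max_len (both ends inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    kept: Counter = Counter()
    rejected = 0
    for seq, copies in lib.counts.items():
        if min_len <= len(seq) <= max_len:
            kept[seq] += copies
        else:
            rejected += copies
    counters = replace(
        lib.counters,
        size_rejected=lib.counters.size_rejected + rejected,
        retained=lib.counters.retained - rejected,
    )
    return ReadLibrary(condition=lib.condition, counts=kept, counters=counters)


def trim_polya(lib: ReadLibrary, min_tail: int = 4) -> ReadLibrary:
    """Remove the maximal trailing run of A's when it is >= min_tail long."""
    trimmed: Counter = Counter()
    for seq, copies in lib.counts.items():
        stripped = seq.rstrip("A")
        if len(seq) - len(stripped) >= min_tail:
            trimmed[stripped] += copies
        else:
            trimmed[seq] += copies
    return ReadLibrary(
        condition=lib.condition, counts=trimmed, counters=replace(lib.counters)
    )


def remove_contaminants(lib: ReadLibrary, contaminant: ReferenceSet) -> ReadLibrary:
    """Drop reads matching any contaminant sequence, either strand, 100% id.

    Uses the same full-length exact-match criterion as the mapper.
    """
    if len(contaminant) == 0:
        return ReadLibrary(
            condition=lib.condition,
            counts=Counter(lib.counts),
            counters=replace(lib.counters),
        )
    hits = mapper.map_exact(lib, contaminant)
    contaminated = {row.read for row in hits}
    kept: Counter = Counter()
    rejected = 0
    for seq, copies in lib.counts.items():
        if seq in contaminated:
            rejected += copies
        else:
            kept[seq] += copies
    counters = replace(
        lib.counters,
        contaminant_rejected=lib.counters.contaminant_rejected + rejected,
        retained=lib.counters.retained - rejected,
    )
    return ReadLibrary(condition=lib.condition, counts=kept, counters=counters)


def counters_report(libs: Mapping[str, ReadLibrary]) -> pd.DataFrame:
    rows = []
    for cond, lib in libs.items():
        lib.counters.check()
        row = {"library": cond}
        row.update(lib.counters.as_dict())
        row["redundant"] = lib.redundant_total
        row["unique"] = lib.unique_total
        rows.append(row)
    return pd.DataFrame(rows)
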