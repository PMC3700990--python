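"""Global sRNA descriptive statistics: sizes, 5' bases, count bins, hotspots."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .preprocess import ReadLibrary


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (so 0.125 -> 0.13 at 2 digits)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def share_percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage numerator/denominator * 100, rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("share_percent with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def _as_libraries(libs) -> list[ReadLibrary]:
    if isinstance(libs, ReadLibrary):
        return [libs]
    if isinstance(libs, Mapping):
        return list(libs.values())
    return list(libs)


@dataclass
class LengthDistribution:
    counts: dict[int, int]

    @property
    def mode(self) -> int | None:
        if not any(self.counts.values()):
            return None
        best = max(self.counts.values())
        return min(length for length, c in self.counts.items() if c == best)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def length_distribution(libs, min_len: int = 16, max_len: int = 32) -> LengthDistribution:
    """Redundant read counts per length over [min_len, max_len]."""
    counts = {length: 0 for length in range(min_len, max_len + 1)}
    for lib in _as_libraries(libs):
        for seq, copies in lib.counts.items():
            counts[len(seq)] = counts.get(len(seq), 0) + copies
    return LengthDistribution(counts=counts)


def first_base_composition(libs) -> dict[str, float]:
    """5'-base fractions over distinct sequences, reported in RNA letters.

    Sequences are pooled across libraries before deduplication, so copy
    counts never influence the composition.
    """
    unique: set[str] = set()
    for lib in _as_libraries(libs):
        unique.update(s for s in lib.counts if s)
    tally = Counter(seq[0] for seq in unique)
    total = sum(tally.values())
    bases = {"A": "A", "C": "C", "G": "G", "T": "U"}
    if total == 0:
        return {rna: 0.0 for rna in ("A", "C", "G", "U")}
    return {rna: tally.get(dna, 0) / total for dna, rna in bases.items()}


@dataclass
class CountBins:
    edges: Sequence[int]
    bin_counts: list[int]  # one per [e_i, e_{i+1}) range, last is [e_last, inf)
    zero_references: int

    def labels(self) -> list[str]:
        labels = [
            f"[{lo},{hi})" for lo, hi in zip(self.edges[:-1], self.edges[1:])
        ]
        labels.append(f">={self.edges[-1]}")
        return labels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": self.labels(), "references": self.bin_counts})


def bin_references_by_count(counts: pd.Series, bin_edges: Sequence[int],
                            n_references: int | None = None) -> CountBins:
    """Histogram references by mapped-read count.

    ``counts`` holds per-reference totals (references with zero counts may
    be absent); references with >=1 read land in exactly one bin, and the
    zero class is reported separately when ``n_references`` is given.
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    if edges[0] < 1:
        raise ValueError("first bin edge must be >= 1")
    nonzero = counts[counts > 0]
    bins = [0] * len(edges)
    for value in nonzero:
        if value < edges[0]:
            raise ValueError(f"count {value} below first bin edge")
        for i in range(len(edges) - 1, -1, -1):
            if value >= edges[i]:
                bins[i] += 1
                break
    zero = (counts == 0).sum()
    if n_references is not None:
        zero += n_references - len(counts)
    return CountBins(edges=edges, bin_counts=bins, zero_references=int(zero))


@dataclass
class HotspotSummary:
    ranked_ids: list[str]
    cumulative_share: list[float]  # percent, non-decreasing, ends at 100
    top_n: int
    top_n_share: float  # percent, 2-decimal half-up
    top_n_genome_fraction: float  # percent of summed reference length

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ref_id": self.ranked_ids, "cumulative_share_pct": self.cumulative_share}
        )


def hotspot_summary(counts: pd.Series, ref_lengths: Mapping[str, int],
                    top_n: int) -> HotspotSummary:
    """Rank references by redundant count and measure top-N concentration.

    Ties are broken by reference id so reports are deterministic. The share
    denominators are the total mapped redundant count and the summed length
    of all references in ``ref_lengths``.
    """
    full = pd.Series(0, index=sorted(ref_lengths), dtype=float)
    full.loc[counts.index] = counts.astype(float)
    if top_n > len(full):
        raise ValueError("top_n exceeds number of references")
    ranked = full.sort_index().sort_values(ascending=False, kind="stable")
    total = float(ranked.sum())
    if total <= 0:
        raise ValueError("no mapped reads for hotspot summary")
    cumulative = (ranked.cumsum() / total * 100.0).tolist()
    top_ids = ranked.index[:top_n]
    top_share = share_percent(float(ranked.iloc[:top_n].sum()), total)
    genome_total = sum(ref_lengths.values())
    top_len = sum(ref_lengths[r] for r in top_ids)
    return HotspotSummary(
        ranked_ids=list(ranked.index),
        cumulative_share=cumulative,
        top_n=top_n,
        top_n_share=top_share,
        top_n_genome_fraction=share_percent(top_len, genome_total),
    )
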