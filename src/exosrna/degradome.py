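"""Degradome 5'-end pileups, stop-distance profile, peak calling, controls.

Peak calling follows the >=3x-of-mean rule: per CDS, tag counts are
normalized to relative frequencies, and a position is a peak when its
relative frequency is at least ``factor_threshold`` times the mean relative
frequency of the CDS (mean over positions with >=1 tag by default; an
all-positions mean is available behind ``mean_over="all"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mapper import AlignmentTable
from .refs import ReferenceSet


@dataclass
class DegradomeProfile:
    """Per-CDS per-position 5'-end tag counts (sense) + antisense tallies."""

    cds_id: str
    length: int
    sense_counts: dict[int, int] = field(default_factory=dict)
    antisense_counts: dict[int, int] = field(default_factory=dict)

    @property
    def total_tags(self) -> int:
        return sum(self.sense_counts.values())

    @property
    def total_antisense(self) -> int:
        return sum(self.antisense_counts.values())

    @property
    def nonzero_positions(self) -> int:
        return len(self.sense_counts)

    def rel_freq(self) -> dict[int, float]:
        total = self.total_tags
        if total == 0:
            return {}
        return {pos: c / total for pos, c in self.sense_counts.items()}


@dataclass
class Peak:
    cds_id: str
    position: int
    tag_count: int
    rel_freq: float
    factor: float


def pileup_5prime(
    aln: AlignmentTable, cds_refs: ReferenceSet
) -> dict[str, DegradomeProfile]:
    """Pile up tag 5' ends per CDS position.

    A sense ('+') alignment contributes its copies at its start coordinate;
    an antisense ('-') alignment's 5' end sits at ``end - 1`` on the
    forward coordinate system and is tallied separately.
    """
    profiles = {
        cds_id: DegradomeProfile(cds_id=cds_id, length=len(seq))
        for cds_id, seq in cds_refs.items()
    }
    for row in aln:
        prof = profiles.get(row.ref_id)
        if prof is None:
            continue
        if row.strand == "+":
            prof.sense_counts[row.start] = (
                prof.sense_counts.get(row.start, 0) + row.copies
            )
        else:
            pos = row.end - 1
            prof.antisense_counts[pos] = (
                prof.antisense_counts.get(pos, 0) + row.copies
            )
    return profiles


def stop_distance_profile(
    profiles: Mapping[str, DegradomeProfile],
    cds_refs: ReferenceSet,
    max_distance: int,
    n_cds: int | None = None,
) -> np.ndarray:
    """Average relative tag frequency as a function of distance from stop.

    Distance 0 is the first nucleotide of the stop codon, increasing toward
    the 5' end. The value at distance d is the sum over CDSs of the
    relative frequency at that position divided by the fixed total number
    of CDSs (CDSs with no tags, or shorter than d, contribute zero).
    """
    if n_cds is None:
        n_cds = len(cds_refs)
    if n_cds <= 0:
        raise ValueError("n_cds must be positive")
    out = np.zeros(max_distance + 1)
    for cds_id, prof in profiles.items():
        if cds_id not in cds_refs:
            continue
        anchor = cds_refs.stop_anchor(cds_id)
        for pos, freq in prof.rel_freq().items():
            d = anchor - pos
            if 0 <= d <= max_distance:
                out[d] += freq
    return out / n_cds


def call_peaks(
    profiles: Mapping[str, DegradomeProfile],
    factor_threshold: float = 3.0,
    mean_over: str = "nonzero",
) -> list[Peak]:
    """Positions whose relative frequency is >= threshold x the CDS mean.

    With ``mean_over="nonzero"`` (default) the mean is taken over positions
    carrying at least one tag, so it equals 1/nonzero_positions; with
    ``"all"`` it is 1/length. Equality with the threshold retains the peak.
    """
    if factor_threshold <= 1:
        raise ValueError("factor_threshold must be > 1")
    if mean_over not in ("nonzero", "all"):
        raise ValueError("mean_over must be 'nonzero' or 'all'")
    peaks: list[Peak] = []
    for cds_id in sorted(profiles):
        prof = profiles[cds_id]
        total = prof.total_tags
        if total == 0:
            continue
        denom = prof.nonzero_positions if mean_over == "nonzero" else prof.length
        mean_freq = 1.0 / denom
        for pos in sorted(prof.sense_counts):
            count = prof.sense_counts[pos]
            freq = count / total
            factor = freq / mean_freq
            if factor >= factor_threshold:
                peaks.append(
                    Peak(
                        cds_id=cds_id,
                        position=pos,
                        tag_count=count,
                        rel_freq=freq,
                        factor=factor,
                    )
                )
    return peaks


def peak_factor_histogram(
    peaks: Sequence[Peak], min_bin: int = 3, max_bin: int = 13
) -> dict[int, int]:
    """Integer-floor factor bins; the final bin absorbs factor >= max_bin."""
    hist = {b: 0 for b in range(min_bin, max_bin + 1)}
    for peak in peaks:
        b = int(np.floor(peak.factor))
        b = min(max(b, min_bin), max_bin)
        hist[b] += 1
    return hist


def _length_offsets(cds_refs: ReferenceSet) -> tuple[list[str], np.ndarray]:
    ids = list(cds_refs)
    lengths = np.array([cds_refs.length(r) for r in ids], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    return ids, offsets


def random_peak_control(
    n_peaks: int,
    cds_refs: ReferenceSet,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[str, int]]:
    """Place n pseudo-peaks uniformly over concatenated CDS coordinates.

    Equivalent to drawing a CDS with probability proportional to its length
    and a position uniformly within it.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ids, offsets = _length_offsets(cds_refs)
    total = int(offsets[-1])
    draws = rng.integers(0, total, size=n_peaks)
    idx = np.searchsorted(offsets, draws, side="right") - 1
    return [
        (ids[i], int(pos - offsets[i])) for i, pos in zip(idx, draws)
    ]


@dataclass
class OverlapTestResult:
    observed_overlap: int
    control_overlaps: np.ndarray
    p_value: float
    n_permutations: int

    @property
    def mean_control_overlap(self) -> float:
        return float(np.mean(self.control_overlaps))


def _coverage_concat(
    srna_aln: AlignmentTable, cds_refs: ReferenceSet
) -> tuple[np.ndarray, dict[str, int]]:
    ids, offsets = _length_offsets(cds_refs)
    start_of = {rid: int(offsets[i]) for i, rid in enumerate(ids)}
    cover = np.zeros(int(offsets[-1]), dtype=bool)
    for row in srna_aln:
        base = start_of.get(row.ref_id)
        if base is None:
            continue
        cover[base + row.start : base + row.end] = True
    return cover, start_of


def srna_peak_overlap_test(
    peaks: Sequence[Peak] | Sequence[tuple[str, int]],
    srna_aln: AlignmentTable,
    cds_refs: ReferenceSet,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
) -> OverlapTestResult:
    """Permutation test of sRNA coverage over degradome peak positions.

    A peak overlaps when any mapped sRNA interval (either strand) covers
    its position. Each permutation replicate redraws the same number of
    pseudo-peaks length-weighted uniformly over the CDSs; the empirical
    p-value is (1 + #{replicates with overlap >= observed}) /
    (1 + n_permutations).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cover, start_of = _coverage_concat(srna_aln, cds_refs)
    positions = []
    for peak in peaks:
        cds_id, pos = (
            (peak.cds_id, peak.position) if isinstance(peak, Peak) else peak
        )
        positions.append(start_of[cds_id] + pos)
    positions = np.asarray(positions, dtype=np.int64)
    observed = int(cover[positions].sum()) if len(positions) else 0
    draws = rng.integers(0, len(cover), size=(n_permutations, len(positions)))
    control = cover[draws].sum(axis=1) if len(positions) else np.zeros(
        n_permutations, dtype=int
    )
    p = (1 + int((control >= observed).sum())) / (1 + n_permutations)
    return OverlapTestResult(
        observed_overlap=observed,
        control_overlaps=np.asarray(control),
        p_value=p,
        n_permutations=n_permutations,
    )


def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.cds_id, p.position, p.tag_count, p.rel_freq, p.factor) for p in peaks],
        columns=["cds_id", "position", "tag_count", "rel_freq", "factor"],
    )


def peaks_to_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """Single-base BED6 intervals (0-based half-open) for called peaks."""
    with open(path, "w") as handle:
        for p in peaks:
            handle.write(
                f"{p.cds_id}\t{p.position}\t{p.position + 1}"
                f"\tpeak\t{p.tag_count}\t+\n"
            )
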