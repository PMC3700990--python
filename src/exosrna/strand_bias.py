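"""Degradome-based transcript orientation and sRNA strand-bias classification.

A CDS/EST is transcriptionally "oriented" when its degradome tags are
predominantly sense (strictly >75% for CDSs, >=70% for ESTs) or when it has
sense tags and no antisense tags at all. For oriented references with
enough sRNAs, the sense/antisense split of mapped sRNAs is computed and
classified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

SENSE_PREVALENT = "sense_prevalent"
ANTISENSE_BIASED = "antisense_biased"
ANTISENSE_ONLY = "antisense_only"


@dataclass
class StrandBiasRecord:
    ref_id: str
    degradome_sense: int
    degradome_antisense: int
    srna_sense: int
    srna_antisense: int
    pct_sense: float
    pct_antisense: float
    bias_class: str
    tie_flag: bool = False  # exact 50/50, counted as sense_prevalent


def orient_references(
    degradome_counts: pd.DataFrame,
    threshold: float = 0.75,
    inclusive: bool = False,
) -> list[str]:
    """Select references whose degradome tags fix the transcription strand.

    ``degradome_counts`` needs ``sense``/``antisense`` columns (or the
    mapper's ``redundant_sense``/``redundant_antisense``), indexed by
    reference id. A reference is retained when its sense fraction exceeds
    ``threshold`` (strictly, or >= with ``inclusive=True``, the EST rule),
    or when it has sense tags and zero antisense tags.
    """
    frame = degradome_counts
    sense_col = "sense" if "sense" in frame.columns else "redundant_sense"
    anti_col = (
        "antisense" if "antisense" in frame.columns else "redundant_antisense"
    )
    retained = []
    for ref_id, row in frame.iterrows():
        s, a = int(row[sense_col]), int(row[anti_col])
        if s == 0 and a == 0:
            continue
        if a == 0:
            retained.append(ref_id)
            continue
        frac = s / (s + a)
        if frac >= threshold if inclusive else frac > threshold:
            retained.append(ref_id)
    return retained


def _classify(sense: int, antisense: int) -> tuple[str, bool]:
    total = sense + antisense
    if total == 0:
        raise ValueError("cannot classify a record with zero sRNAs")
    if sense == 0:
        return ANTISENSE_ONLY, False
    pct_anti = 100.0 * antisense / total
    if pct_anti > 50.0:
        return ANTISENSE_BIASED, False
    # exact 50/50 ties fall to sense_prevalent, flagged
    return SENSE_PREVALENT, pct_anti == 50.0


def srna_strand_profile(
    oriented_ids: Iterable[str],
    srna_counts: pd.DataFrame,
    degradome_counts: pd.DataFrame | None = None,
    min_srna: int = 10,
    unique_mode: bool = False,
) -> list[StrandBiasRecord]:
    """Strand-bias records for oriented references with >= min_srna sRNAs.

    ``srna_counts`` is a mapper per-reference frame. With ``unique_mode``
    the selection threshold and the percentages use distinct-sequence
    counts instead of redundant copies. Records are sorted by pct_sense
    descending (ties by reference id), the x-axis ordering of the
    orientation-bias plot.
    """
    if min_srna < 1:
        raise ValueError("min_srna must be >= 1")
    prefix = "unique" if unique_mode else "redundant"
    records = []
    for ref_id in oriented_ids:
        if ref_id not in srna_counts.index:
            continue
        row = srna_counts.loc[ref_id]
        sense = int(row[f"{prefix}_sense"])
        antisense = int(row[f"{prefix}_antisense"])
        if sense + antisense < min_srna:
            continue
        total = sense + antisense
        bias_class, tie = _classify(sense, antisense)
        if degradome_counts is not None and ref_id in degradome_counts.index:
            drow = degradome_counts.loc[ref_id]
            ds = int(drow.get("sense", drow.get("redundant_sense", 0)))
            da = int(drow.get("antisense", drow.get("redundant_antisense", 0)))
        else:
            ds = da = 0
        records.append(
            StrandBiasRecord(
                ref_id=ref_id,
                degradome_sense=ds,
                degradome_antisense=da,
                srna_sense=sense,
                srna_antisense=antisense,
                pct_sense=100.0 * sense / total,
                pct_antisense=100.0 * antisense / total,
                bias_class=bias_class,
                tie_flag=tie,
            )
        )
    records.sort(key=lambda r: (-r.pct_sense, r.ref_id))
    return records


def classify_bias_summary(
    records: Sequence[StrandBiasRecord], antisense_min: int = 20
) -> dict[str, int]:
    """Tally bias classes, mirroring the headline antisense statistics."""
    summary = {
        "total": len(records),
        "sense_prevalent": 0,
        "antisense_biased": 0,
        "antisense_only": 0,
        "antisense_gt_threshold": 0,
        "sense_prevalent_with_antisense": 0,
        "ties": 0,
    }
    for rec in records:
        if rec.bias_class == SENSE_PREVALENT:
            summary["sense_prevalent"] += 1
            if rec.srna_antisense >= 1:
                summary["sense_prevalent_with_antisense"] += 1
        elif rec.bias_class == ANTISENSE_ONLY:
            summary["antisense_only"] += 1
            summary["antisense_biased"] += 1  # antisense-only is a bias too
        else:
            summary["antisense_biased"] += 1
        if rec.srna_antisense > antisense_min:
            summary["antisense_gt_threshold"] += 1
        if rec.tie_flag:
            summary["ties"] += 1
    return summary


def records_to_frame(records: Sequence[StrandBiasRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.ref_id,
                r.degradome_sense,
                r.degradome_antisense,
                r.srna_sense,
                r.srna_antisense,
                r.pct_sense,
                r.pct_antisense,
                r.bias_class,
                r.tie_flag,
            )
            for r in records
        ],
        columns=[
            "ref_id",
            "degradome_sense",
            "degradome_antisense",
            "srna_sense",
            "srna_antisense",
            "pct_sense",
            "pct_antisense",
            "bias_class",
            "tie_flag",
        ],
    )
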