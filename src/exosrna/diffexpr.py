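"""RPKM normalization, 100-RPKM/10-fold differential filter, clustering."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist


def rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series | Mapping[str, int],
    library_sizes: pd.Series | Mapping[str, int],
) -> pd.DataFrame:
    """Reads per kilobase of CDS per million library-mapped reads.

    ``counts`` is CDS x condition; ``library_sizes`` are the per-library
    redundant totals mapped to the CDS set.
    """
    lengths = pd.Series(lengths).reindex(counts.index)
    library_sizes = pd.Series(library_sizes).reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every CDS needs a positive length")
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        raise ValueError("every library needs a positive mapped total")
    kb = lengths / 1000.0
    millions = library_sizes / 1e6
    return counts.div(kb, axis=0).div(millions, axis=1)


@dataclass
class DifferentialRecord:
    cds_id: str
    condition: str  # stress condition achieving the largest qualifying fold
    fold: float
    direction: str  # "up" or "down" under stress relative to reference
    max_rpkm: float


def filter_differential(
    matrix: pd.DataFrame,
    lengths: pd.Series | Mapping[str, int],
    library_sizes: pd.Series | Mapping[str, int],
    min_rpkm: float = 100.0,
    min_fold: float = 10.0,
    reference_condition: str = "normal",
) -> list[DifferentialRecord]:
    """Keep CDSs with >= min_rpkm somewhere and a >= min_fold stress change.

    Fold between a stress condition and the reference is
    max(a, b) / max(min(a, b), eps) where eps is the RPKM a single read
    would have in the smaller cell's library (a pseudo-floor so loci that
    switch off entirely still get a finite, meaningful fold).
    """
    if reference_condition not in matrix.columns:
        raise ValueError(f"reference condition {reference_condition!r} missing")
    lengths = pd.Series(lengths).reindex(matrix.index)
    library_sizes = pd.Series(library_sizes).reindex(matrix.columns)
    stress_conditions = [c for c in matrix.columns if c != reference_condition]
    records: list[DifferentialRecord] = []
    for cds_id, row in matrix.iterrows():
        max_rpkm = float(row.max())
        if max_rpkm < min_rpkm:
            continue
        best: tuple[float, str, str] | None = None
        ref_val = float(row[reference_condition])
        for cond in stress_conditions:
            val = float(row[cond])
            hi, lo = max(val, ref_val), min(val, ref_val)
            lo_lib = cond if val <= ref_val else reference_condition
            eps = 1.0 / (
                (lengths[cds_id] / 1000.0) * (library_sizes[lo_lib] / 1e6)
            )
            fold = hi / max(lo, eps)
            if fold >= min_fold and (best is None or fold > best[0]):
                direction = "up" if val > ref_val else "down"
                best = (fold, cond, direction)
        if best is not None:
            records.append(
                DifferentialRecord(
                    cds_id=cds_id,
                    condition=best[1],
                    fold=best[0],
                    direction=best[2],
                    max_rpkm=max_rpkm,
                )
            )
    return records


def cluster_and_summarize(
    records: Sequence[DifferentialRecord],
    matrix: pd.DataFrame,
    bias_by_cds: Mapping[str, str] | None = None,
    n_clusters: int | None = None,
):
    """Order differential CDSs by hierarchical clustering and tally them.

    Rows are clustered on log2(RPKM + 1) with average linkage and Euclidean
    distance; the returned matrix is reordered by the dendrogram leaves.
    The summary joins strand-bias classes when provided. Optionally returns
    flat cluster labels cut at ``n_clusters``.
    """
    if not records:
        raise ValueError("no differential records to cluster")
    ids = [r.cds_id for r in records]
    sub = matrix.loc[ids]
    logm = np.log2(sub.to_numpy(dtype=float) + 1.0)
    summary = {
        "total": len(records),
        "up": sum(1 for r in records if r.direction == "up"),
        "down": sum(1 for r in records if r.direction == "down"),
    }
    if bias_by_cds is not None:
        summary["sense_prevalent"] = sum(
            1 for r in records if bias_by_cds.get(r.cds_id) == "sense_prevalent"
        )
        summary["antisense_prevalent"] = sum(
            1
            for r in records
            if bias_by_cds.get(r.cds_id)
            in ("antisense_biased", "antisense_only")
        )
    if len(records) == 1:
        ordered = sub
        labels = np.zeros(1, dtype=int)
        return ordered, summary, labels
    link = linkage(pdist(logm, metric="euclidean"), method="average")
    order = leaves_list(link)
    ordered = sub.iloc[order]
    labels = None
    if n_clusters is not None:
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(link, t=n_clusters, criterion="maxclust")
    return ordered, summary, labels


def records_to_frame(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.cds_id, r.condition, r.fold, r.direction, r.max_rpkm)
            for r in records
        ],
        columns=["cds_id", "condition", "fold", "direction", "max_rpkm"],
    )
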