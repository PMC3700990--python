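"""End-to-end orchestration: simulate/load -> preprocess -> map -> reports."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import degradome as deg
from . import diffexpr, io, mapper, preprocess, profiles, strand_bias
from .refs import ReferenceSet
from .simulate import SimConfig, simulate_all, truth_to_frames


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    The stage defaults are the published ones: 16-32 nt sRNA size window,
    25-45 nt degradome window, 100%-identity full-length mapping, >75%
    (CDS) / >=70% (EST) degradome orientation, >=10 sRNAs per record,
    >=3x-mean peak threshold, and the 100-RPKM / 10-fold expression filter.
    """

    seed: int = 0
    out_dir: str = "run_out"
    sim: SimConfig | None = None
    # file-input mode (used when sim is None)
    srna_fastq: str | None = None
    degradome_fastq: str | None = None
    genome_fasta: str | None = None
    cds_fasta: str | None = None
    est_fasta: str | None = None
    contaminant_fasta: str | None = None
    barcode_map: dict[str, str] = field(default_factory=dict)
    adapter3: str = ""
    srna_min_len: int = 16
    srna_max_len: int = 32
    deg_min_len: int = 25
    deg_max_len: int = 45
    polya_min_tail: int = 4
    cds_orient_threshold: float = 0.75
    est_orient_threshold: float = 0.70
    min_srna: int = 10
    peak_factor_threshold: float = 3.0
    overlap_permutations: int = 999
    min_rpkm: float = 100.0
    min_fold: float = 10.0
    hotspot_top_n: int = 5
    bin_edges: tuple[int, ...] = (1, 10, 100, 1000, 10000)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Run every stage and write tables, a manifest, and truth comparisons.

    Returns the manifest dict; all outputs land under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.sim is not None:
        sim = cfg.sim
        refs, truth, (srna_records, srna_truth), (deg_records, deg_truth) = (
            simulate_all(sim)
        )
        genome, cds, est, contaminant = (
            refs.genome, refs.cds, refs.est, refs.contaminant
        )
        barcode_map, adapter3 = dict(sim.barcode_map), sim.adapter3
        genome.to_fasta(out / "genome.fasta")
        cds.to_fasta(out / "cds.fasta")
        est.to_fasta(out / "est.fasta")
        contaminant.to_fasta(out / "contaminant.fasta")
        io.write_fastq(srna_records, out / "srna_raw.fastq")
        io.write_fastq(deg_records, out / "degradome_raw.fastq")
        srna_truth.to_csv(out / "srna_truth.tsv", sep="\t", index=False)
        deg_truth.to_csv(out / "degradome_truth.tsv", sep="\t", index=False)
        for name, frame in truth_to_frames(truth).items():
            frame.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False)
        srna_reads = [seq for _rid, seq in srna_records]
        deg_reads = [seq for _rid, seq in deg_records]
    else:
        for path, label in (
            (cfg.srna_fastq, "sRNA FASTQ"),
            (cfg.degradome_fastq, "degradome FASTQ"),
            (cfg.genome_fasta, "genome FASTA"),
            (cfg.cds_fasta, "CDS FASTA"),
        ):
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"missing {label}: {path}")
        genome = ReferenceSet.from_fasta(cfg.genome_fasta, "genome")
        cds = ReferenceSet.from_fasta(cfg.cds_fasta, "cds")
        est = (
            ReferenceSet.from_fasta(cfg.est_fasta, "est")
            if cfg.est_fasta
            else ReferenceSet("est", {})
        )
        contaminant = (
            ReferenceSet.from_fasta(cfg.contaminant_fasta, "contaminant")
            if cfg.contaminant_fasta
            else ReferenceSet("contaminant", {})
        )
        barcode_map, adapter3 = dict(cfg.barcode_map), cfg.adapter3
        srna_reads = [s for _r, s in io.read_fastq(cfg.srna_fastq)]
        deg_reads = [s for _r, s in io.read_fastq(cfg.degradome_fastq)]

    # --- preprocessing -----------------------------------------------------
    srna_demux = preprocess.demultiplex_and_trim(
        srna_reads, barcode_map, adapter3
    )
    srna_libs: dict[str, preprocess.ReadLibrary] = {}
    for cond, lib in srna_demux.libraries.items():
        lib = preprocess.size_filter(lib, cfg.srna_min_len, cfg.srna_max_len)
        lib = preprocess.remove_contaminants(lib, contaminant)
        srna_libs[cond] = lib
    preprocess.counters_report(srna_libs).to_csv(
        out / "srna_preprocess_report.tsv", sep="\t", index=False
    )

    deg_demux = preprocess.demultiplex_and_trim(deg_reads, barcode_map, adapter3)
    deg_libs: dict[str, preprocess.ReadLibrary] = {}
    for cond, lib in deg_demux.libraries.items():
        lib = preprocess.trim_polya(lib, cfg.polya_min_tail)
        lib = preprocess.size_filter(lib, cfg.deg_min_len, cfg.deg_max_len)
        lib = preprocess.remove_contaminants(lib, contaminant)
        deg_libs[cond] = lib
    preprocess.counters_report(deg_libs).to_csv(
        out / "degradome_preprocess_report.tsv", sep="\t", index=False
    )

    # --- mapping and count tables -----------------------------------------
    count_tables: dict[str, dict[str, mapper.CountTable]] = {}
    srna_cds_aln: dict[str, mapper.AlignmentTable] = {}
    for kind, refset in (("genome", genome), ("cds", cds), ("est", est)):
        per_lib = {}
        for cond, lib in srna_libs.items():
            aln = mapper.map_exact(lib, refset)
            per_lib[cond] = mapper.count_by_reference(aln, lib)
            if kind == "cds":
                srna_cds_aln[cond] = aln
        count_tables[kind] = per_lib
        mapper.library_totals_table(per_lib).to_csv(
            out / f"count_totals_{kind}.tsv", sep="\t", index=False
        )

    # --- sRNA profiles ----------------------------------------------------
    dist = profiles.length_distribution(
        srna_libs, cfg.srna_min_len, cfg.srna_max_len
    )
    pd.DataFrame(
        sorted(dist.counts.items()), columns=["length", "redundant"]
    ).to_csv(out / "length_distribution.tsv", sep="\t", index=False)
    comp = profiles.first_base_composition(srna_libs)
    pd.DataFrame(
        sorted(comp.items()), columns=["base", "fraction"]
    ).to_csv(out / "first_base_composition.tsv", sep="\t", index=False)

    genome_total = mapper.combine_count_tables(
        count_tables["genome"].values()
    )
    hot = profiles.hotspot_summary(
        genome_total.redundant(), genome.lengths(),
        min(cfg.hotspot_top_n, len(genome)),
    )
    hot.to_frame().to_csv(out / "hotspot_ranking.tsv", sep="\t", index=False)
    bins = profiles.bin_references_by_count(
        genome_total.redundant(), cfg.bin_edges, n_references=len(genome)
    )
    bins.to_frame().to_csv(out / "count_bins_genome.tsv", sep="\t", index=False)

    # --- degradome mapping + strand bias ----------------------------------
    deg_pooled = preprocess.ReadLibrary(condition="degradome")
    for lib in deg_libs.values():
        deg_pooled.counts.update(lib.counts)
    deg_aln = mapper.map_exact(deg_pooled, cds)
    deg_counts = mapper.count_by_reference(deg_aln, deg_pooled)

    srna_cds_total = mapper.combine_count_tables(
        count_tables["cds"].values()
    )
    oriented = strand_bias.orient_references(
        deg_counts.per_reference, cfg.cds_orient_threshold, inclusive=False
    )
    records = strand_bias.srna_strand_profile(
        oriented,
        srna_cds_total.per_reference,
        degradome_counts=deg_counts.per_reference,
        min_srna=cfg.min_srna,
    )
    strand_bias.records_to_frame(records).to_csv(
        out / "strand_bias.tsv", sep="\t", index=False
    )
    bias_summary = strand_bias.classify_bias_summary(records)
    pd.DataFrame([bias_summary]).to_csv(
        out / "strand_bias_summary.tsv", sep="\t", index=False
    )

    # --- degradome profiling ----------------------------------------------
    pileups = deg.pileup_5prime(deg_aln, cds)
    max_len = max((cds.length(c) for c in cds), default=1)
    stop_profile = deg.stop_distance_profile(pileups, cds, max_len - 1)
    pd.DataFrame(
        {"distance_from_stop": range(len(stop_profile)),
         "mean_rel_freq": stop_profile}
    ).to_csv(out / "stop_distance_profile.tsv", sep="\t", index=False)
    peaks = deg.call_peaks(pileups, cfg.peak_factor_threshold)
    deg.peaks_to_frame(peaks).to_csv(out / "peaks.tsv", sep="\t", index=False)
    deg.peaks_to_bed(peaks, out / "peaks.bed")
    hist = deg.peak_factor_histogram(peaks)
    pd.DataFrame(
        sorted(hist.items()), columns=["factor_floor", "peaks"]
    ).to_csv(out / "peak_factor_histogram.tsv", sep="\t", index=False)

    srna_cds_pooled_rows: list[mapper.Alignment] = []
    for aln in srna_cds_aln.values():
        srna_cds_pooled_rows.extend(aln.rows)
    srna_cds_pooled = mapper.AlignmentTable(rows=srna_cds_pooled_rows)
    overlap = None
    if peaks and len(cds):
        overlap = deg.srna_peak_overlap_test(
            peaks, srna_cds_pooled, cds,
            n_permutations=cfg.overlap_permutations, seed=cfg.seed,
        )
        pd.DataFrame(
            [
                {
                    "observed_overlap": overlap.observed_overlap,
                    "mean_control_overlap": overlap.mean_control_overlap,
                    "p_value": overlap.p_value,
                    "n_permutations": overlap.n_permutations,
                }
            ]
        ).to_csv(out / "overlap_test.tsv", sep="\t", index=False)

    # --- differential expression ------------------------------------------
    conditions = list(barcode_map)
    cds_ids = sorted(
        set().union(*(t.per_reference.index for t in count_tables["cds"].values()))
    ) if count_tables["cds"] else []
    counts_mat = pd.DataFrame(0, index=cds_ids, columns=conditions, dtype=int)
    lib_sizes = {}
    for cond, table in count_tables["cds"].items():
        red = table.redundant()
        counts_mat.loc[red.index, cond] = red.astype(int)
        lib_sizes[cond] = table.redundant_mapped_total
    manifest_diff = {}
    if len(counts_mat) and all(v > 0 for v in lib_sizes.values()):
        matrix = diffexpr.rpkm(
            counts_mat, pd.Series(cds.lengths()), pd.Series(lib_sizes)
        )
        matrix.to_csv(out / "rpkm.tsv", sep="\t")
        de_records = diffexpr.filter_differential(
            matrix, pd.Series(cds.lengths()), pd.Series(lib_sizes),
            min_rpkm=cfg.min_rpkm, min_fold=cfg.min_fold,
            reference_condition=conditions[0],
        )
        diffexpr.records_to_frame(de_records).to_csv(
            out / "differential.tsv", sep="\t", index=False
        )
        manifest_diff["n_differential"] = len(de_records)
        if de_records:
            bias_map = {r.ref_id: r.bias_class for r in records}
            ordered, de_summary, _ = diffexpr.cluster_and_summarize(
                de_records, matrix, bias_by_cds=bias_map
            )
            ordered.to_csv(out / "differential_clustered.tsv", sep="\t")
            pd.DataFrame([de_summary]).to_csv(
                out / "differential_summary.tsv", sep="\t", index=False
            )

    # --- manifest ----------------------------------------------------------
    manifest = {
        "seed": cfg.seed,
        "parameters": {
            k: v
            for k, v in vars(cfg).items()
            if k not in ("sim",) and not k.startswith("_")
        },
        "simulated": cfg.sim is not None,
        "stages": {
            "srna_total_reads": srna_demux.total_reads,
            "degradome_total_reads": deg_demux.total_reads,
            "n_peaks": len(peaks),
            "n_oriented_cds": len(oriented),
            "n_strand_bias_records": len(records),
            **manifest_diff,
        },
        "checksums": {},
    }
    if cfg.sim is not None:
        manifest["parameters"]["sim"] = cfg.sim.to_dict()
    if overlap is not None:
        manifest["stages"]["overlap_p_value"] = overlap.p_value
    for path in sorted(out.glob("*.tsv")) + sorted(out.glob("*.fasta")) + sorted(
        out.glob("*.fastq")
    ) + sorted(out.glob("*.bed")):
        manifest["checksums"][path.name] = _sha256(path)
    manifest["parameters"]["bin_edges"] = list(cfg.bin_edges)
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True, default=str)
    return manifest
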