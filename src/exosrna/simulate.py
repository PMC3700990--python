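"""Synthetic reference sets, sRNA/degradome FASTQ libraries, and ground truth.

The generator plants the statistical structure the analysis stages are
meant to recover: a 21-nt-modal insert length distribution with A/U-rich 5'
bases, hotspot concentration of genomic reads, per-CDS sense/antisense
mixtures, degradome tags with a 3'-biased exonucleolytic background plus
endonucleolytic spikes (and occasional poly-A tails), contaminant reads,
and condition-specific >=10-fold expression changes. Everything is a pure
function of the config (fixed seed => byte-identical output).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .refs import ReferenceSet, revcomp

STOP_CODONS = ("TAA", "TAG", "TGA")
BASES = "ACGT"
CLASSES = ("sense_prevalent", "antisense_biased", "antisense_only", "no_srna")

# rng stream ids: one independent child stream per generation step
_STREAM_REFS, _STREAM_TRUTH, _STREAM_SRNA, _STREAM_DEGRADOME = range(4)


def _default_length_dist() -> dict[int, float]:
    dist = {
        16: 0.02, 17: 0.03, 18: 0.05, 19: 0.08, 20: 0.13, 21: 0.30,
        22: 0.13, 23: 0.08, 24: 0.05, 25: 0.04, 26: 0.03, 27: 0.02,
        28: 0.01, 29: 0.01, 30: 0.01, 31: 0.005, 32: 0.005,
    }
    assert abs(sum(dist.values()) - 1.0) < 1e-9
    return dist


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset."""

    seed: int = 0
    n_genome_contigs: int = 60
    n_cds: int = 40
    cds_length_range: tuple[int, int] = (300, 900)
    genome_contig_length_range: tuple[int, int] = (1500, 3000)
    frac_cds_with_srna: float = 0.8
    bias_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "sense_prevalent": 0.55,
            "antisense_biased": 0.20,
            "antisense_only": 0.05,
            "no_srna": 0.20,
        }
    )
    hotspot_frac_contigs: float = 0.05
    hotspot_read_share: float = 0.8
    length_dist: dict[int, float] = field(default_factory=_default_length_dist)
    first_base_dist: dict[str, float] = field(
        default_factory=lambda: {"A": 0.30, "C": 0.15, "G": 0.20, "U": 0.35}
    )
    conditions: tuple[str, ...] = ("normal", "cold", "salt", "light")
    # planted weight multiplier; realized count folds shrink below this
    # because loci compete for a fixed per-condition read budget, so the
    # default leaves headroom over the 10-fold detection rule
    fold_change_loci: int = 4
    fold_change_factor: float = 20.0
    degradome_background_rate: float = 0.10  # expected tags per nt
    degradome_3prime_bias: float = 0.01  # exponential decay toward the stop
    planted_peak_factor_range: tuple[float, float] = (5.0, 10.0)
    planted_peak_frac_cds: float = 0.5
    polya_tail_prob: float = 0.10
    polya_tail_len_range: tuple[int, int] = (4, 10)
    contaminant_read_frac: float = 0.05
    barcode_map: dict[str, str] = field(
        default_factory=lambda: {
            "normal": "ACGT", "cold": "CATG", "salt": "GTAC", "light": "TGCA"
        }
    )
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    # library composition knobs
    n_reads_per_condition: int = 3000
    cds_read_frac: float = 0.5  # of non-contaminant reads, drawn from CDSs
    out_of_range_len_frac: float = 0.05  # inserts outside 16-32 (15 or 33-35)
    class_antisense_prob: dict[str, float] = field(
        default_factory=lambda: {
            "sense_prevalent": 0.10,
            "antisense_biased": 0.80,
            "antisense_only": 1.00,
        }
    )
    degradome_antisense_frac: float = 0.10
    ambiguous_antisense_frac: float = 0.35
    ambiguous_cds_frac: float = 0.10
    n_contaminants: int = 5
    contaminant_length: int = 400

    def validate(self) -> None:
        fractions = {
            "frac_cds_with_srna": self.frac_cds_with_srna,
            "hotspot_frac_contigs": self.hotspot_frac_contigs,
            "hotspot_read_share": self.hotspot_read_share,
            "polya_tail_prob": self.polya_tail_prob,
            "contaminant_read_frac": self.contaminant_read_frac,
            "cds_read_frac": self.cds_read_frac,
            "out_of_range_len_frac": self.out_of_range_len_frac,
            "degradome_antisense_frac": self.degradome_antisense_frac,
            "ambiguous_antisense_frac": self.ambiguous_antisense_frac,
            "ambiguous_cds_frac": self.ambiguous_cds_frac,
            "planted_peak_frac_cds": self.planted_peak_frac_cds,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if set(self.bias_mixture) != set(CLASSES):
            raise ValueError("bias_mixture must cover exactly the four classes")
        if abs(sum(self.bias_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("bias_mixture must sum to 1")
        if abs(sum(self.length_dist.values()) - 1.0) > 1e-9:
            raise ValueError("length_dist must sum to 1")
        if not all(16 <= k <= 32 for k in self.length_dist):
            raise ValueError("length_dist keys must lie in 16..32")
        if set(self.first_base_dist) != set("ACGU"):
            raise ValueError("first_base_dist must be over {A,C,G,U}")
        if abs(sum(self.first_base_dist.values()) - 1.0) > 1e-9:
            raise ValueError("first_base_dist must sum to 1")
        lo, hi = self.cds_length_range
        if lo < 30 or hi < lo:
            raise ValueError("invalid cds_length_range")
        lo, hi = self.planted_peak_factor_range
        if lo < 3 or hi < lo:
            raise ValueError("planted peak factors must be >= 3")
        if self.fold_change_factor < 10:
            raise ValueError("fold_change_factor must be >= 10")
        if set(self.barcode_map) != set(self.conditions):
            raise ValueError("barcode_map must cover exactly the conditions")
        if len(self.conditions) != len(set(self.conditions)):
            raise ValueError("duplicate condition labels")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["cds_length_range"] = list(self.cds_length_range)
        out["genome_contig_length_range"] = list(self.genome_contig_length_range)
        out["planted_peak_factor_range"] = list(self.planted_peak_factor_range)
        out["polya_tail_len_range"] = list(self.polya_tail_len_range)
        out["conditions"] = list(self.conditions)
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        data = dict(data)
        for key in (
            "cds_length_range",
            "genome_contig_length_range",
            "planted_peak_factor_range",
            "polya_tail_len_range",
            "conditions",
        ):
            if key in data:
                data[key] = tuple(data[key])
        if "length_dist" in data:
            data["length_dist"] = {
                int(k): float(v) for k, v in data["length_dist"].items()
            }
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))


@dataclass
class TruthRecord:
    """Machine-readable ground truth for parameter-recovery tests."""

    cds_bias_class: dict[str, str]
    planted_peaks: list[tuple[str, int, float]]
    de_loci: dict[str, tuple[str, float, str]]  # cds -> (condition, fold, dir)
    hotspot_contigs: list[str]
    cds_locations: dict[str, tuple[str, int, int]]  # cds -> (contig, start, end)
    cds_weights: dict[str, float]
    ambiguous_cds: frozenset = frozenset()


@dataclass
class SimReferences:
    genome: ReferenceSet
    cds: ReferenceSet
    est: ReferenceSet
    contaminant: ReferenceSet


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _random_cds_seq(rng: np.random.Generator, length: int) -> str:
    """Random codons without internal stops, terminated by a stop codon."""
    assert length % 3 == 0 and length >= 6
    codons = []
    while len(codons) < length // 3 - 1:
        codon = _random_seq(rng, 3)
        if codon not in STOP_CODONS:
            codons.append(codon)
    codons.append(STOP_CODONS[int(rng.integers(0, 3))])
    return "".join(codons)


def generate_references(config: SimConfig) -> SimReferences:
    """Generate genome contigs with embedded CDSs, ESTs and contaminants.

    CDS placements are recorded (see :func:`plant_truth`); every CDS is a
    multiple of 3 nt ending in a stop codon and sits on the forward strand
    of its contig. ESTs mirror the CDS sequences (all longer than 199 nt
    given the default length range), standing in for assembled transcript
    evidence. Contaminants are independent random sequences.
    """
    config.validate()
    rng = _rng(config, _STREAM_REFS)
    lo, hi = config.genome_contig_length_range
    contigs = {
        f"contig_{i:05d}": _random_seq(rng, int(rng.integers(lo, hi + 1)))
        for i in range(config.n_genome_contigs)
    }

    clo, chi = config.cds_length_range
    cds_seqs: dict[str, str] = {}
    locations: dict[str, tuple[str, int, int]] = {}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    contig_ids = list(contigs)
    for i in range(config.n_cds):
        length = int(rng.integers(clo, chi + 1))
        length -= length % 3
        seq = _random_cds_seq(rng, length)
        placed = False
        for _attempt in range(200):
            contig_id = contig_ids[int(rng.integers(0, len(contig_ids)))]
            contig_seq = contigs[contig_id]
            if len(contig_seq) < length:
                continue
            start = int(rng.integers(0, len(contig_seq) - length + 1))
            end = start + length
            if any(s < end and start < e for s, e in occupied[contig_id]):
                continue
            contigs[contig_id] = (
                contig_seq[:start] + seq + contig_seq[end:]
            )
            occupied[contig_id].append((start, end))
            cds_id = f"cds_{i:05d}"
            cds_seqs[cds_id] = seq
            locations[cds_id] = (contig_id, start, end)
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place CDS {i}: n_cds exceeds genome capacity"
            )

    est_seqs = {
        cds_id.replace("cds_", "est_"): seq
        for cds_id, seq in cds_seqs.items()
        if len(seq) > 199
    }
    contaminants = {
        f"contaminant_{i:03d}": _random_seq(rng, config.contaminant_length)
        for i in range(config.n_contaminants)
    }
    refs = SimReferences(
        genome=ReferenceSet("genome", contigs),
        cds=ReferenceSet("cds", cds_seqs),
        est=ReferenceSet("est", est_seqs),
        contaminant=ReferenceSet("contaminant", contaminants),
    )
    refs._cds_locations = locations  # threaded to plant_truth
    return refs


def plant_truth(refs: SimReferences, config: SimConfig) -> TruthRecord:
    """Assign bias classes, hotspots, DE loci and planted degradome peaks."""
    rng = _rng(config, _STREAM_TRUTH)
    cds_ids = list(refs.cds)
    # frac_cds_with_srna fixes the no_srna mass; the producing classes share
    # the remainder in the proportions of bias_mixture.
    producing_classes = [c for c in CLASSES if c != "no_srna"]
    producing_mass = sum(config.bias_mixture[c] for c in producing_classes)
    if producing_mass == 0 or config.frac_cds_with_srna == 0:
        probs = np.array([0.0] * len(producing_classes) + [1.0])
    else:
        probs = np.array(
            [
                config.bias_mixture[c] / producing_mass
                * config.frac_cds_with_srna
                for c in producing_classes
            ]
            + [1.0 - config.frac_cds_with_srna]
        )
    classes = producing_classes + ["no_srna"]
    draws = rng.choice(len(classes), size=len(cds_ids), p=probs)
    bias = {cds_id: classes[k] for cds_id, k in zip(cds_ids, draws)}

    contig_ids = list(refs.genome)
    n_hot = max(1, int(round(config.hotspot_frac_contigs * len(contig_ids))))
    hotspots = sorted(
        rng.choice(contig_ids, size=n_hot, replace=False).tolist()
    )

    producing = [c for c in cds_ids if bias[c] != "no_srna"]
    weights = {
        cds_id: float(rng.lognormal(mean=0.0, sigma=0.75))
        for cds_id in producing
    }

    stress = [c for c in config.conditions if c != config.conditions[0]]
    de: dict[str, tuple[str, float, str]] = {}
    if producing and config.fold_change_loci:
        chosen = rng.choice(
            producing,
            size=min(config.fold_change_loci, len(producing)),
            replace=False,
        )
        for j, cds_id in enumerate(sorted(chosen.tolist())):
            cond = stress[int(rng.integers(0, len(stress)))]
            direction = "up" if j % 2 == 0 else "down"
            de[cds_id] = (cond, float(config.fold_change_factor), direction)

    flo, fhi = config.planted_peak_factor_range
    peaks: list[tuple[str, int, float]] = []
    n_peak_cds = int(round(config.planted_peak_frac_cds * len(cds_ids)))
    if n_peak_cds:
        for cds_id in sorted(
            rng.choice(cds_ids, size=n_peak_cds, replace=False).tolist()
        ):
            length = refs.cds.length(cds_id)
            if length < 80:
                continue
            pos = int(rng.integers(20, length - 45))
            factor = float(rng.uniform(flo, fhi))
            peaks.append((cds_id, pos, factor))

    n_ambiguous = int(round(config.ambiguous_cds_frac * len(cds_ids)))
    ambiguous = frozenset(
        rng.choice(cds_ids, size=n_ambiguous, replace=False).tolist()
    ) if n_ambiguous else frozenset()

    return TruthRecord(
        cds_bias_class=bias,
        planted_peaks=peaks,
        de_loci=de,
        hotspot_contigs=hotspots,
        cds_locations=dict(getattr(refs, "_cds_locations", {})),
        cds_weights=weights,
        ambiguous_cds=ambiguous,
    )


def _sample_insert(
    rng: np.random.Generator,
    source_seq: str,
    length: int,
    first_base_dist_dna: tuple[tuple[str, ...], np.ndarray],
    antisense: bool,
    avoid: list[tuple[int, int]] | None = None,
    max_tries: int = 25,
) -> tuple[str, int, str]:
    """Sample an exact substring insert with a 5'-base target distribution.

    Returns (insert, forward start coordinate, strand). Rejection sampling
    retries positions until the insert's first base matches a draw from the
    configured 5'-base distribution (keeping inserts exact substrings).
    """
    bases, probs = first_base_dist_dna
    want = bases[int(rng.choice(len(bases), p=probs))]
    n = len(source_seq)
    pick = None
    for _ in range(max_tries):
        start = int(rng.integers(0, n - length + 1))
        if avoid and any(s < start + length and start < e for s, e in avoid):
            continue
        sub = source_seq[start : start + length]
        insert = revcomp(sub) if antisense else sub
        if pick is None:
            pick = (insert, start)
        if insert[0] == want:
            pick = (insert, start)
            break
    if pick is None:  # pathological avoid-list; fall back to any position
        start = int(rng.integers(0, n - length + 1))
        sub = source_seq[start : start + length]
        pick = (revcomp(sub) if antisense else sub, start)
    return pick[0], pick[1], "-" if antisense else "+"


def generate_srna_reads(
    refs: SimReferences, truth: TruthRecord, config: SimConfig
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Multiplexed raw sRNA reads (barcode + insert + adapter) with truth.

    Returns FASTQ-ready (id, sequence) records and a per-read truth table
    with one row per record.
    """
    config.validate()
    rng = _rng(config, _STREAM_SRNA)
    fb = (
        tuple("ACGT"),
        np.array(
            [
                config.first_base_dist["A"],
                config.first_base_dist["C"],
                config.first_base_dist["G"],
                config.first_base_dist["U"],  # U == T in DNA space
            ]
        ),
    )
    lengths = np.array(sorted(config.length_dist))
    length_probs = np.array(
        [config.length_dist[int(k)] for k in lengths]
    )
    out_lengths = np.array([15, 33, 34, 35])

    producing = sorted(truth.cds_weights)
    base_weights = np.array([truth.cds_weights[c] for c in producing])

    hotspot_set = set(truth.hotspot_contigs)
    other_contigs = [c for c in refs.genome if c not in hotspot_set]
    other_lengths = np.array(
        [refs.genome.length(c) for c in other_contigs], dtype=float
    )
    cds_by_contig: dict[str, list[tuple[int, int]]] = {}
    for _cds, (contig, start, end) in truth.cds_locations.items():
        cds_by_contig.setdefault(contig, []).append((start, end))
    contaminant_ids = list(refs.contaminant)

    records: list[tuple[str, str]] = []
    truth_rows = []
    for cond in config.conditions:
        barcode = config.barcode_map[cond]
        # condition-specific CDS weights implement planted fold changes
        weights = base_weights.copy()
        for i, cds_id in enumerate(producing):
            if cds_id in truth.de_loci:
                de_cond, fold, direction = truth.de_loci[cds_id]
                if direction == "up":
                    if cond == de_cond:
                        weights[i] *= fold
                else:  # high everywhere except the stressed condition
                    if cond != de_cond:
                        weights[i] *= fold
        cds_probs = weights / weights.sum() if len(weights) else weights

        for i in range(config.n_reads_per_condition):
            if rng.random() < config.out_of_range_len_frac:
                length = int(out_lengths[int(rng.integers(0, 4))])
            else:
                length = int(rng.choice(lengths, p=length_probs))
            u = rng.random()
            if u < config.contaminant_read_frac and contaminant_ids:
                source = "contaminant"
                ref_id = contaminant_ids[
                    int(rng.integers(0, len(contaminant_ids)))
                ]
                antisense = bool(rng.random() < 0.5)
                insert, start, strand = _sample_insert(
                    rng, refs.contaminant[ref_id], length, fb, antisense
                )
            elif (
                rng.random() < config.cds_read_frac and len(producing)
            ):
                source = "cds"
                ref_id = producing[int(rng.choice(len(producing), p=cds_probs))]
                klass = truth.cds_bias_class[ref_id]
                antisense = bool(
                    rng.random() < config.class_antisense_prob[klass]
                )
                insert, start, strand = _sample_insert(
                    rng, refs.cds[ref_id], length, fb, antisense
                )
            else:
                source = "genome"
                if rng.random() < config.hotspot_read_share or not other_contigs:
                    ref_id = truth.hotspot_contigs[
                        int(rng.integers(0, len(truth.hotspot_contigs)))
                    ]
                else:
                    ref_id = other_contigs[
                        int(rng.choice(len(other_contigs),
                                       p=other_lengths / other_lengths.sum()))
                    ]
                antisense = bool(rng.random() < 0.5)
                insert, start, strand = _sample_insert(
                    rng,
                    refs.genome[ref_id],
                    length,
                    fb,
                    antisense,
                    avoid=cds_by_contig.get(ref_id),
                )
            read_id = f"srna_{cond}_{i:06d}"
            records.append((read_id, barcode + insert + config.adapter3))
            truth_rows.append(
                (read_id, cond, source, ref_id, start, strand, length, insert)
            )
    truth_df = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id", "condition", "source", "ref_id", "start", "strand",
            "insert_len", "insert",
        ],
    )
    return records, truth_df


def generate_degradome_reads(
    refs: SimReferences, truth: TruthRecord, config: SimConfig
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Raw degradome reads: 3'-biased background plus planted spikes.

    Background tag 5' positions decay exponentially away from the stop
    codon (rate ``degradome_3prime_bias``; 0 means uniform). Planted peaks
    receive enough extra tags at their position so that, against the
    realized background, the position's relative frequency is at least
    ``factor`` times the mean over nonzero positions.
    """
    config.validate()
    rng = _rng(config, _STREAM_DEGRADOME)
    records: list[tuple[str, str]] = []
    rows = []
    plo, phi = config.polya_tail_len_range
    planted_by_cds: dict[str, tuple[int, float]] = {
        cds_id: (pos, factor) for cds_id, pos, factor in truth.planted_peaks
    }
    counter = 0

    def emit(cds_id: str, pos: int, antisense: bool, planted: bool) -> bool:
        nonlocal counter
        seq = refs.cds[cds_id]
        max_len = min(45, len(seq) - pos)
        length = int(rng.integers(25, max_len + 1))

        def fragment_at(L: int) -> str:
            frag = seq[pos : pos + L]
            return revcomp(frag) if antisense else frag

        # Avoid A-terminal fragments so poly-A trimming removes exactly the
        # planted tails and never nibbles an untagged tag; tags whose every
        # admissible length ends in A (possible close to the 3' end) are
        # dropped rather than emitted with ambiguous trimming behaviour.
        fragment = fragment_at(length)
        if fragment.endswith("A"):
            for cand in range(max_len, 24, -1):
                if not fragment_at(cand).endswith("A"):
                    length = cand
                    fragment = fragment_at(cand)
                    break
            else:
                return False
        polya = bool(rng.random() < config.polya_tail_prob)
        tail = "A" * int(rng.integers(plo, phi + 1)) if polya else ""
        cond = config.conditions[int(rng.integers(0, len(config.conditions)))]
        read_id = f"deg_{counter:07d}"
        counter += 1
        records.append(
            (read_id, config.barcode_map[cond] + fragment + tail
             + config.adapter3)
        )
        rows.append(
            (read_id, cond, cds_id, pos, "-" if antisense else "+",
             length, polya, planted)
        )
        return True

    for cds_id, seq in refs.cds.items():
        length = len(seq)
        max_pos = length - 25
        if max_pos <= 0:
            continue
        anchor = length - 3
        n_bg = int(rng.poisson(config.degradome_background_rate * length))
        bg_positions: list[int] = []
        for _ in range(n_bg):
            if config.degradome_3prime_bias > 0:
                for _try in range(50):
                    d = int(
                        math.floor(
                            rng.exponential(1.0 / config.degradome_3prime_bias)
                        )
                    )
                    pos = anchor - d
                    if 0 <= pos <= max_pos:
                        break
                else:
                    pos = int(rng.integers(0, max_pos + 1))
            else:
                pos = int(rng.integers(0, max_pos + 1))
            bg_positions.append(pos)
        if cds_id in truth.ambiguous_cds:
            anti_frac = config.ambiguous_antisense_frac
        else:
            anti_frac = config.degradome_antisense_frac
        sense_emitted: list[int] = []
        for pos in bg_positions:
            anti = bool(rng.random() < anti_frac)
            if emit(cds_id, pos, antisense=anti, planted=False) and not anti:
                sense_emitted.append(pos)

        if cds_id in planted_by_cds:
            pos, factor = planted_by_cds[cds_id]
            # Size the spike from the emitted sense-strand background so the
            # planted position's relative frequency is guaranteed to be
            # >= factor x the mean over nonzero sense positions: with c
            # spike tags on background total t over nz distinct positions
            # (the spike position included), factor_realized >=
            # c * nz / (t + c), so c >= factor * t / (nz - factor).
            t = len(sense_emitted)
            nz = len(set(sense_emitted) | {pos})
            if t > 0 and nz > factor:
                n_spike = math.ceil(factor * t / (nz - factor)) + 1
            else:
                n_spike = max(5, t)
            emitted = 0
            while emitted < n_spike:
                if emit(cds_id, pos, antisense=False, planted=True):
                    emitted += 1
                else:  # A-terminal at every admissible length: give up
                    break

    truth_df = pd.DataFrame(
        rows,
        columns=[
            "read_id", "condition", "cds_id", "position", "strand",
            "tag_len", "polya", "planted",
        ],
    )
    return records, truth_df


def noise_free_cds_counts(
    refs: SimReferences, truth: TruthRecord, config: SimConfig,
    base_rpkm: float = 150.0, library_total: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Deterministic per-CDS count matrix realizing the planted fold changes.

    Library totals are equalized with a filler row so RPKM fold changes
    equal count fold changes exactly; every sRNA-producing CDS gets a base
    count worth ~``base_rpkm`` and DE loci differ by exactly their planted
    fold in the stressed condition. Returns (counts, lengths, library sizes).
    """
    conditions = list(config.conditions)
    reference = conditions[0]
    producing = sorted(truth.cds_weights)
    lengths = {c: refs.cds.length(c) for c in producing}
    counts = pd.DataFrame(0, index=producing, columns=conditions, dtype=int)
    for cds_id in producing:
        kb = lengths[cds_id] / 1000.0
        base = max(1, round(base_rpkm * kb * (library_total / 1e6)))
        row = {cond: base for cond in conditions}
        if cds_id in truth.de_loci:
            cond, fold, direction = truth.de_loci[cds_id]
            if direction == "up":
                row[cond] = int(base * fold)
            else:
                for other in conditions:
                    if other != cond:
                        row[other] = int(base * fold)
        for cond in conditions:
            counts.loc[cds_id, cond] = row[cond]
    filler_id = "filler_00000"
    col_sums = counts.sum()
    if (col_sums > library_total - 1000).any():
        raise ValueError("library_total too small for the generated counts")
    counts.loc[filler_id] = (library_total - col_sums).astype(int)
    lengths[filler_id] = 1000
    lengths_s = pd.Series(lengths).reindex(counts.index)
    lib_sizes = counts.sum()
    assert (lib_sizes == library_total).all()
    return counts, lengths_s, lib_sizes


def simulate_all(config: SimConfig):
    """Convenience wrapper: references, truth, sRNA and degradome reads."""
    refs = generate_references(config)
    truth = plant_truth(refs, config)
    srna_records, srna_truth = generate_srna_reads(refs, truth, config)
    deg_records, deg_truth = generate_degradome_reads(refs, truth, config)
    return refs, truth, (srna_records, srna_truth), (deg_records, deg_truth)


def truth_to_frames(truth: TruthRecord) -> dict[str, pd.DataFrame]:
    """Flatten a TruthRecord into TSV-ready frames."""
    return {
        "cds_bias_class": pd.DataFrame(
            sorted(truth.cds_bias_class.items()),
            columns=["cds_id", "bias_class"],
        ),
        "planted_peaks": pd.DataFrame(
            truth.planted_peaks, columns=["cds_id", "position", "factor"]
        ),
        "de_loci": pd.DataFrame(
            [
                (cds, cond, fold, direction)
                for cds, (cond, fold, direction) in sorted(truth.de_loci.items())
            ],
            columns=["cds_id", "condition", "fold", "direction"],
        ),
        "hotspot_contigs": pd.DataFrame(
            {"contig_id": truth.hotspot_contigs}
        ),
        "cds_locations": pd.DataFrame(
            [
                (cds, contig, start, end)
                for cds, (contig, start, end) in sorted(
                    truth.cds_locations.items()
                )
            ],
            columns=["cds_id", "contig_id", "start", "end"],
        ),
    }
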