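from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exosrna.refs import revcomp
from exosrna.simulate import (
    STOP_CODONS,
    SimConfig,
    generate_degradome_reads,
    generate_references,
    generate_srna_reads,
    noise_free_cds_counts,
    plant_truth,
)
from conftest import naive_scan


class TestConfig:
    def test_default_config_valid(self):
        SimConfig().validate()

    @pytest.mark.parametrize(
        "field,value",
        [
            ("frac_cds_with_srna", 1.5),
            ("hotspot_read_share", -0.1),
            ("fold_change_factor", 5.0),
            ("contaminant_read_frac", 2.0),
        ],
    )
    def test_bad_scalars_rejected(self, field, value):
        cfg = SimConfig(**{field: value})
        with pytest.raises(ValueError):
            cfg.validate()

    def test_bias_mixture_must_sum_to_one(self):
        cfg = SimConfig()
        cfg.bias_mixture["sense_prevalent"] = 0.9
        with pytest.raises(ValueError):
            cfg.validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(seed=3, n_cds=10)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = SimConfig.from_yaml(path)
        assert back == cfg


class TestReferences:
    def test_zero_cds_config(self):
        cfg = SimConfig(n_cds=0, planted_peak_frac_cds=0.0)
        refs = generate_references(cfg)
        assert len(refs.cds) == 0
        assert len(refs.genome) == cfg.n_genome_contigs > 0

    def test_determinism_byte_identical_fasta(self, tmp_path):
        cfg = SimConfig(seed=5, n_cds=12, n_genome_contigs=15)
        paths = []
        for run in (0, 1):
            refs = generate_references(cfg)
            path = tmp_path / f"genome_{run}.fasta"
            refs.genome.to_fasta(path)
            refs.cds.to_fasta(tmp_path / f"cds_{run}.fasta")
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()
        assert (tmp_path / "cds_0.fasta").read_bytes() == (
            tmp_path / "cds_1.fasta"
        ).read_bytes()

    def test_cds_extractable_at_recorded_coordinates(self, sim):
        refs, truth = sim["refs"], sim["truth"]
        assert len(truth.cds_locations) == len(refs.cds)
        for cds_id, (contig, start, end) in truth.cds_locations.items():
            # independent substring extraction
            assert refs.genome[contig][start:end] == refs.cds[cds_id]

    def test_cds_structure(self, sim):
        for seq in sim["refs"].cds.sequences.values():
            assert len(seq) % 3 == 0
            assert seq[-3:] in STOP_CODONS

    def test_est_sizes_and_content(self, sim):
        for seq in sim["refs"].est.sequences.values():
            assert len(seq) > 199

    def test_contaminant_disjoint(self, sim):
        refs = sim["refs"]
        genome_cat = " ".join(refs.genome.sequences.values())
        for seq in refs.contaminant.sequences.values():
            assert seq not in genome_cat
            assert revcomp(seq) not in genome_cat

    def test_overfull_genome_rejected(self):
        cfg = SimConfig(
            n_genome_contigs=2,
            genome_contig_length_range=(600, 700),
            n_cds=20,
            cds_length_range=(300, 400),
        )
        with pytest.raises(ValueError, match="capacity"):
            generate_references(cfg)


class TestTruth:
    def test_truth_ids_exist_and_factors(self, sim):
        refs, truth = sim["refs"], sim["truth"]
        assert set(truth.cds_bias_class) == set(refs.cds.sequences)
        for cds_id, pos, factor in truth.planted_peaks:
            assert cds_id in refs.cds
            assert 0 <= pos < refs.cds.length(cds_id)
            assert factor >= 3
        assert set(truth.hotspot_contigs) <= set(refs.genome.sequences)

    def test_bias_class_proportions_within_ci(self):
        cfg = SimConfig(
            seed=21, n_cds=250, n_genome_contigs=220,
            genome_contig_length_range=(2500, 3500),
        )
        refs = generate_references(cfg)
        truth = plant_truth(refs, cfg)
        tally = Counter(truth.cds_bias_class.values())
        producing_mass = sum(
            v for k, v in cfg.bias_mixture.items() if k != "no_srna"
        )
        for klass in cfg.bias_mixture:
            if klass == "no_srna":
                p = 1 - cfg.frac_cds_with_srna
            else:
                p = (
                    cfg.bias_mixture[klass] / producing_mass
                    * cfg.frac_cds_with_srna
                )
            lo, hi = stats.binom.interval(0.99, cfg.n_cds, p)
            assert lo <= tally.get(klass, 0) <= hi, klass


class TestSrnaReads:
    def test_truth_rows_match_record_count(self, sim):
        assert len(sim["srna_truth"]) == len(sim["srna_records"])

    def test_read_structure(self, sim):
        cfg = sim["config"]
        truth = sim["srna_truth"].set_index("read_id")
        for rid, seq in sim["srna_records"][:200]:
            row = truth.loc[rid]
            barcode = cfg.barcode_map[row["condition"]]
            assert seq == barcode + row["insert"] + cfg.adapter3

    def test_antisense_only_cds_reads_all_antisense(self, sim):
        truth = sim["truth"]
        anti_only = {
            c for c, k in truth.cds_bias_class.items() if k == "antisense_only"
        }
        frame = sim["srna_truth"]
        rows = frame[(frame["source"] == "cds") & frame["ref_id"].isin(anti_only)]
        if len(rows):
            assert (rows["strand"] == "-").all()

    def test_inserts_are_exact_substrings(self, sim):
        refs = sim["refs"]
        pools = {"cds": refs.cds, "genome": refs.genome,
                 "contaminant": refs.contaminant}
        frame = sim["srna_truth"].head(300)
        for _, row in frame.iterrows():
            source_seq = pools[row["source"]][row["ref_id"]]
            sub = source_seq[row["start"] : row["start"] + row["insert_len"]]
            expected = sub if row["strand"] == "+" else revcomp(sub)
            assert row["insert"] == expected

    def test_no_contaminant_inserts_when_frac_zero(self):
        cfg = SimConfig(seed=13, n_cds=8, n_genome_contigs=10,
                        n_reads_per_condition=150, contaminant_read_frac=0.0)
        refs = generate_references(cfg)
        truth = plant_truth(refs, cfg)
        _records, frame = generate_srna_reads(refs, truth, cfg)
        assert (frame["source"] != "contaminant").all()
        hits = naive_scan(set(frame["insert"]), refs.contaminant)
        assert hits == set()

    def test_length_mode_is_21(self, sim):
        # >= 10,000 reads: the empirical insert-length mode is stable
        frame = sim["srna_truth"]
        assert len(frame) >= 10_000
        assert frame["insert_len"].mode().iloc[0] == 21

    def test_contaminant_fraction_within_ci(self):
        cfg = SimConfig(seed=31, n_cds=10, n_genome_contigs=12,
                        n_reads_per_condition=4000)
        refs = generate_references(cfg)
        truth = plant_truth(refs, cfg)
        _records, frame = generate_srna_reads(refs, truth, cfg)
        n = len(frame)
        observed = int((frame["source"] == "contaminant").sum())
        lo, hi = stats.binom.interval(0.99, n, cfg.contaminant_read_frac)
        assert lo <= observed <= hi

    def test_determinism(self, sim):
        cfg = sim["config"]
        refs = generate_references(cfg)
        truth = plant_truth(refs, cfg)
        records, frame = generate_srna_reads(refs, truth, cfg)
        assert records == sim["srna_records"]
        pd.testing.assert_frame_equal(frame, sim["srna_truth"])


class TestDegradomeReads:
    def test_truth_rows_match_record_count(self, sim):
        assert len(sim["deg_truth"]) == len(sim["deg_records"])

    def test_empty_when_no_background_and_no_peaks(self):
        cfg = SimConfig(seed=3, n_cds=6, n_genome_contigs=8,
                        degradome_background_rate=0.0,
                        planted_peak_frac_cds=0.0)
        refs = generate_references(cfg)
        truth = plant_truth(refs, cfg)
        records, frame = generate_degradome_reads(refs, truth, cfg)
        assert records == [] and len(frame) == 0

    def test_planted_peak_exceeds_3x_mean_in_truth_pileup(self, sim):
        frame = sim["deg_truth"]
        truth = sim["truth"]
        sense = frame[frame["strand"] == "+"]
        for cds_id, pos, factor in truth.planted_peaks:
            counts = Counter(sense[sense["cds_id"] == cds_id]["position"])
            total = sum(counts.values())
            if total == 0:
                continue
            mean = total / len(counts)
            assert counts[pos] >= 3 * mean

    def test_3prime_bias_shifts_positions_toward_stop(self):
        base = dict(seed=17, n_cds=12, n_genome_contigs=14,
                    cds_length_range=(900, 1200),
                    genome_contig_length_range=(2500, 3500),
                    degradome_background_rate=1.2,
                    planted_peak_frac_cds=0.0)
        biased_cfg = SimConfig(**base, degradome_3prime_bias=0.01)
        uniform_cfg = SimConfig(**base, degradome_3prime_bias=0.0)
        dists = {}
        for name, cfg in (("biased", biased_cfg), ("uniform", uniform_cfg)):
            refs = generate_references(cfg)
            truth = plant_truth(refs, cfg)
            _records, frame = generate_degradome_reads(refs, truth, cfg)
            assert len(frame) >= 10_000
            anchors = {c: refs.cds.length(c) - 3 for c in refs.cds}
            dists[name] = float(
                (frame["cds_id"].map(anchors) - frame["position"]).mean()
            )
        assert dists["biased"] < dists["uniform"]

    def test_polya_flags_consistent(self):
        cfg = SimConfig(seed=99, n_cds=60, n_genome_contigs=70,
                        degradome_background_rate=0.5)
        refs = generate_references(cfg)
        truth = plant_truth(refs, cfg)
        _records, frame = generate_degradome_reads(refs, truth, cfg)
        n = len(frame)
        observed = int(frame["polya"].sum())
        lo, hi = stats.binom.interval(0.99, n, cfg.polya_tail_prob)
        assert lo <= observed <= hi


class TestNoiseFreeCounts:
    def test_counts_realize_planted_folds_exactly(self, sim):
        cfg, refs, truth = sim["config"], sim["refs"], sim["truth"]
        counts, lengths, lib_sizes = noise_free_cds_counts(refs, truth, cfg)
        assert (counts.sum() == lib_sizes).all()
        assert lib_sizes.nunique() == 1
        reference = cfg.conditions[0]
        for cds_id, (cond, fold, direction) in truth.de_loci.items():
            a, b = counts.loc[cds_id, cond], counts.loc[cds_id, reference]
            ratio = max(a, b) / min(a, b)
            assert ratio == pytest.approx(fold)
            assert (a > b) == (direction == "up")
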