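from collections import Counter

import numpy as np
import pytest
from scipy import stats

from exosrna import mapper
from exosrna.degradome import (
    DegradomeProfile,
    Peak,
    call_peaks,
    peak_factor_histogram,
    pileup_5prime,
    random_peak_control,
    srna_peak_overlap_test,
    stop_distance_profile,
)
from exosrna.mapper import Alignment, AlignmentTable
from exosrna.refs import ReferenceSet


def profile_from(counts: dict[int, int], cds_id="c", length=100):
    return {
        cds_id: DegradomeProfile(
            cds_id=cds_id, length=length, sense_counts=dict(counts)
        )
    }


def cds_refs(lengths: dict[str, int]) -> ReferenceSet:
    # deterministic dummy sequences ending in a stop codon
    return ReferenceSet(
        "cds", {k: "C" * (v - 3) + "TAA" for k, v in lengths.items()}
    )


class TestPileup:
    def test_sense_tag_counts_copies_at_start(self):
        refs = cds_refs({"c": 100})
        aln = AlignmentTable(
            rows=[Alignment("X" * 30, 4, "c", 10, 40, "+")]
        )
        prof = pileup_5prime(aln, refs)["c"]
        assert prof.sense_counts == {10: 4}
        assert prof.total_tags == 4

    def test_antisense_five_prime_at_end_minus_one(self):
        refs = cds_refs({"c": 100})
        aln = AlignmentTable(rows=[Alignment("X" * 30, 2, "c", 10, 40, "-")])
        prof = pileup_5prime(aln, refs)["c"]
        assert prof.sense_counts == {}
        assert prof.antisense_counts == {39: 2}

    def test_empty_profile(self):
        prof = pileup_5prime(AlignmentTable(), cds_refs({"c": 60}))["c"]
        assert prof.total_tags == 0
        assert prof.rel_freq() == {}

    def test_rel_freq_sums_to_one(self):
        prof = DegradomeProfile("c", 100, {1: 5, 9: 3, 50: 2})
        assert sum(prof.rel_freq().values()) == pytest.approx(1.0, abs=1e-12)

    def test_pileup_matches_truth_recount(self, sim, deg_libs):
        """Pipeline pileup equals an independent recount of the truth table."""
        refs = sim["refs"]
        pooled = Counter()
        for lib in deg_libs.values():
            pooled.update(lib.counts)
        profiles = pileup_5prime(
            mapper.map_exact(pooled, refs.cds), refs.cds
        )
        truth = sim["deg_truth"]
        expected_sense: dict[str, Counter] = {}
        expected_anti: dict[str, Counter] = {}
        for _, row in truth.iterrows():
            if row["strand"] == "+":
                expected_sense.setdefault(row["cds_id"], Counter())[
                    row["position"]
                ] += 1
            else:
                # antisense 5' end on forward coords = position + length - 1
                expected_anti.setdefault(row["cds_id"], Counter())[
                    row["position"] + row["tag_len"] - 1
                ] += 1
        for cds_id, prof in profiles.items():
            assert prof.sense_counts == dict(
                expected_sense.get(cds_id, {})
            ), cds_id
            assert prof.antisense_counts == dict(
                expected_anti.get(cds_id, {})
            ), cds_id


class TestStopDistance:
    def test_two_cds_hand_example(self):
        refs = cds_refs({"a": 50, "b": 50})
        profiles = {
            "a": DegradomeProfile("a", 50, {47: 7}),  # 47 = stop anchor, d=0
            "b": DegradomeProfile("b", 50, {}),
        }
        out = stop_distance_profile(profiles, refs, max_distance=5)
        assert out[0] == pytest.approx(0.5)
        assert out[1:].sum() == 0

    def test_uniform_closed_form(self):
        length = 60
        refs = cds_refs({"a": length})
        counts = {i: 1 for i in range(length)}
        profiles = {"a": DegradomeProfile("a", length, counts)}
        out = stop_distance_profile(profiles, refs, max_distance=length - 4)
        # anchor = length-3; distances 0..length-4 each carry 1/(L*N)
        assert np.allclose(out, 1.0 / (length * 1))

    def test_total_mass_bound(self, sim, deg_libs):
        refs = sim["refs"]
        pooled = Counter()
        for lib in deg_libs.values():
            pooled.update(lib.counts)
        profiles = pileup_5prime(mapper.map_exact(pooled, refs.cds), refs.cds)
        max_len = max(refs.cds.length(c) for c in refs.cds)
        out = stop_distance_profile(profiles, refs.cds, max_len)
        n_with_tags = sum(1 for p in profiles.values() if p.total_tags > 0)
        assert out.sum() <= 1.0 + 1e-9
        assert out.sum() == pytest.approx(n_with_tags / len(refs.cds))

    def test_bias_enriches_near_stop(self, sim, deg_libs):
        refs = sim["refs"]
        pooled = Counter()
        for lib in deg_libs.values():
            pooled.update(lib.counts)
        profiles = pileup_5prime(mapper.map_exact(pooled, refs.cds), refs.cds)
        out = stop_distance_profile(profiles, refs.cds, 599)
        assert out[:100].sum() > out[100:200].sum()


class TestCallPeaks:
    def test_hand_arithmetic(self):
        profiles = profile_from({0: 10, 1: 1, 2: 1, 3: 1, 4: 1, 5: 1})
        peaks = call_peaks(profiles)
        assert len(peaks) == 1
        peak = peaks[0]
        assert peak.position == 0
        assert peak.rel_freq == pytest.approx(10 / 15)
        assert peak.factor == pytest.approx(4.0)

    def test_uniform_counts_yield_no_peaks(self):
        profiles = profile_from({i: 3 for i in range(20)})
        assert call_peaks(profiles) == []

    def test_threshold_equality_retained(self):
        # three nonzero positions, counts 6,2,1: freq(6)=6/9, mean=1/3 -> 2.0
        profiles = profile_from({0: 6, 1: 2, 2: 1})
        peaks = call_peaks(profiles, factor_threshold=2.0)
        assert [p.position for p in peaks] == [0]

    def test_scale_invariance(self):
        base = {0: 9, 3: 1, 7: 1, 9: 1}
        a = call_peaks(profile_from(base))
        b = call_peaks(profile_from({k: v * 7 for k, v in base.items()}))
        assert [(p.position, p.factor) for p in a] == [
            (p.position, p.factor) for p in b
        ]

    def test_all_positions_mean_mode(self):
        profiles = profile_from({0: 2, 1: 1}, length=300)
        # nonzero mean: freq(0)=2/3, mean=1/2, factor 1.33 -> no peak
        assert call_peaks(profiles, mean_over="nonzero") == []
        # all-positions mean: mean=1/300, factor = 200 -> peak
        assert len(call_peaks(profiles, mean_over="all")) == 2

    def test_zero_tag_cds_yields_nothing(self):
        profiles = profile_from({})
        assert call_peaks(profiles) == []

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            call_peaks(profile_from({0: 1}), factor_threshold=1.0)

    def test_planted_peaks_recovered(self, sim, deg_libs):
        refs, truth = sim["refs"], sim["truth"]
        pooled = Counter()
        for lib in deg_libs.values():
            pooled.update(lib.counts)
        profiles = pileup_5prime(mapper.map_exact(pooled, refs.cds), refs.cds)
        called = {(p.cds_id, p.position) for p in call_peaks(profiles)}
        planted = {(c, p) for c, p, _f in truth.planted_peaks}
        recovered = planted & called
        assert len(recovered) >= 0.9 * len(planted)


class TestHistogram:
    def test_example_bins(self):
        peaks = [
            Peak("c", 0, 1, 0.1, 3.2),
            Peak("c", 1, 1, 0.1, 4.9),
            Peak("c", 2, 1, 0.1, 13.7),
        ]
        hist = peak_factor_histogram(peaks)
        assert hist[3] == 1 and hist[4] == 1 and hist[13] == 1
        assert sum(hist.values()) == 3

    def test_empty(self):
        hist = peak_factor_histogram([])
        assert set(hist) == set(range(3, 14))
        assert all(v == 0 for v in hist.values())

    def test_matches_floor_binning(self, sim, deg_libs):
        refs = sim["refs"]
        pooled = Counter()
        for lib in deg_libs.values():
            pooled.update(lib.counts)
        peaks = call_peaks(
            pileup_5prime(mapper.map_exact(pooled, refs.cds), refs.cds)
        )
        hist = peak_factor_histogram(peaks)
        brute = Counter(min(int(np.floor(p.factor)), 13) for p in peaks)
        assert hist == {b: brute.get(b, 0) for b in range(3, 14)}


class TestRandomControl:
    def test_count_conservation_and_determinism(self):
        refs = cds_refs({"a": 500, "b": 1500})
        one = random_peak_control(50, refs, rng=123)
        two = random_peak_control(50, refs, rng=123)
        assert len(one) == 50
        assert one == two

    def test_length_weighted_placement(self):
        refs = cds_refs({"a": 1000, "b": 3000})
        placements = random_peak_control(10_000, refs, rng=5)
        on_a = sum(1 for cds_id, _pos in placements if cds_id == "a")
        lo, hi = stats.binom.interval(0.99, 10_000, 0.25)
        assert lo <= on_a <= hi

    def test_positions_in_range(self):
        refs = cds_refs({"a": 100})
        for _cds, pos in random_peak_control(500, refs, rng=1):
            assert 0 <= pos < 100


class TestOverlapTest:
    def test_interval_covers_peak(self):
        refs = cds_refs({"c": 100})
        srna = AlignmentTable(rows=[Alignment("X" * 21, 1, "c", 10, 31, "+")])
        peaks = [Peak("c", 15, 1, 0.5, 5.0)]
        result = srna_peak_overlap_test(peaks, srna, refs, 99, seed=0)
        assert result.observed_overlap == 1

    def test_no_srnas_gives_p_one(self):
        refs = cds_refs({"c": 100})
        peaks = [Peak("c", 15, 1, 0.5, 5.0)]
        result = srna_peak_overlap_test(peaks, AlignmentTable(), refs, 99, 0)
        assert result.observed_overlap == 0
        assert result.p_value == 1.0

    def test_invalid_permutations(self):
        refs = cds_refs({"c": 100})
        with pytest.raises(ValueError):
            srna_peak_overlap_test([], AlignmentTable(), refs, 0, 0)

    def test_determinism(self):
        refs = cds_refs({"c": 2000})
        rng = np.random.default_rng(9)
        rows = [
            Alignment("X" * 21, 1, "c", int(s), int(s) + 21, "+")
            for s in rng.integers(0, 1979, size=100)
        ]
        srna = AlignmentTable(rows=rows)
        peaks = [Peak("c", int(p), 1, 0.1, 4.0) for p in rng.integers(0, 2000, 30)]
        a = srna_peak_overlap_test(peaks, srna, refs, 199, seed=42)
        b = srna_peak_overlap_test(peaks, srna, refs, 199, seed=42)
        assert a.p_value == b.p_value
        assert (a.control_overlaps == b.control_overlaps).all()
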