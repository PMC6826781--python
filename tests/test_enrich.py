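"""Coverage placement, interval scanning, scoring, span and the filter."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from germscan import enrich, synth
from germscan.errors import EstimationError, ParameterError

from conftest import random_dna


class TestComputeCoverage:
    def test_single_noiseless_read_covers_exactly_its_span(self):
        ref = random_dna(1000, seed=1)
        read = ref[200:300]
        profiles, unplaced = enrich.compute_coverage(
            [read], [enrich.MapSeq("s", ref)], k=31
        )
        depth = profiles["s"].depth
        assert unplaced == 0
        assert (depth[200:300] == 1).all()
        assert depth.sum() == 100

    def test_simulated_forty_fold_reads_recover_mean_depth(self):
        ref = random_dna(10_000, seed=2)
        reads = synth.simulate_reads(
            [("s", ref)],
            synth.ReadSimConfig(mean_coverage=40, error_rate=0.0, paired=False, seed=3),
        )
        profiles, unplaced = enrich.compute_coverage(reads, [enrich.MapSeq("s", ref)])
        mean = profiles["s"].depth[100:-100].mean()  # interior, no edge effects
        assert abs(mean - 40) / 40 < 0.05
        assert unplaced == 0

    def test_read_without_shared_seed_counts_as_unplaced(self):
        ref = random_dna(500, seed=4)
        alien = random_dna(100, seed=990)
        assert not set(
            alien[i : i + 31] for i in range(70)
        ) & set(ref[i : i + 31] for i in range(470))
        profiles, unplaced = enrich.compute_coverage(
            [alien], [enrich.MapSeq("s", ref)]
        )
        assert unplaced == 1 and profiles["s"].depth.sum() == 0

    def test_reverse_complement_reads_place_identically(self):
        from germscan.seqs import revcomp

        ref = random_dna(400, seed=5)
        read = ref[100:200]
        p1, _ = enrich.compute_coverage([read], [enrich.MapSeq("s", ref)])
        p2, _ = enrich.compute_coverage([revcomp(read)], [enrich.MapSeq("s", ref)])
        assert (p1["s"].depth == p2["s"].depth).all()

    def test_circular_target_wraps_read_bases_without_loss(self):
        unit = random_dna(40, seed=6)
        read = (unit * 4)[13 : 13 + 100]  # 100 bases from the tandem array
        profiles, unplaced = enrich.compute_coverage(
            [read], [enrich.MapSeq("u", unit, circular=True)]
        )
        assert unplaced == 0
        assert profiles["u"].depth.sum() == 100  # every base lands on the circle

    def test_seed_stride_preserves_placement(self):
        ref = random_dna(2000, seed=7)
        reads = [ref[i : i + 100] for i in range(0, 1900, 37)]
        full, _ = enrich.compute_coverage(reads, [enrich.MapSeq("s", ref)])
        strided, _ = enrich.compute_coverage(
            reads, [enrich.MapSeq("s", ref)], seed_stride=7
        )
        assert (full["s"].depth == strided["s"].depth).all()


class TestModalDepth:
    def _profile(self, depths):
        return {"s": enrich.CoverageProfile("s", np.asarray(depths, dtype=np.int64))}

    def test_uniform_depth(self):
        assert enrich.modal_depth(self._profile([40] * 100)) == 40

    def test_mode_ignores_bases_below_min_depth(self):
        depths = [0] * 500 + [40] * 100 + [80] * 10
        assert enrich.modal_depth(self._profile(depths), min_depth=1) == 40

    def test_tie_breaks_toward_larger_depth(self):
        assert enrich.modal_depth(self._profile([3] * 5 + [9] * 5), min_depth=1) == 9

    def test_min_depth_above_everything_is_an_error(self):
        with pytest.raises(EstimationError):
            enrich.modal_depth(self._profile([1, 2, 3]), min_depth=10)


def _profiles(d1, d2):
    a = {"s": enrich.CoverageProfile("s", np.asarray(d1, dtype=np.int64))}
    b = {"s": enrich.CoverageProfile("s", np.asarray(d2, dtype=np.int64))}
    return a, b


class TestScanIntervals:
    def test_twelve_thousand_eligible_bases_split_5000_5000_2000(self):
        a, b = _profiles([20] * 12_000, [20] * 12_000)
        ivs = enrich.scan_intervals(a, b, enrich.EnrichmentParams())
        assert [iv.n_eligible for iv in ivs] == [5000, 5000, 2000]
        assert [(iv.start, iv.end) for iv in ivs] == [
            (0, 5000), (5000, 10_000), (10_000, 12_000)
        ]

    def test_no_eligible_bases_no_intervals(self):
        a, b = _profiles([5] * 1000, [5] * 1000)
        assert enrich.scan_intervals(a, b) == []

    def test_eligibility_is_an_or_of_the_two_minima(self):
        a, b = _profiles([20] * 100 + [0] * 100, [0] * 100 + [20] * 100)
        ivs = enrich.scan_intervals(a, b)
        assert sum(iv.n_eligible for iv in ivs) == 200

    def test_depths_above_cap_contribute_the_cap(self):
        params = enrich.EnrichmentParams(max_depth_1=100.0)
        a, b = _profiles([1000] * 600, [20] * 600)
        (iv,) = enrich.scan_intervals(a, b, params)
        assert iv.mean_depth_1 == 100.0

    def test_eligible_interval_lengths_conserve_eligible_bases(self):
        rng = np.random.default_rng(0)
        d1 = rng.integers(0, 30, size=20_000)
        d2 = rng.integers(0, 30, size=20_000)
        a, b = _profiles(d1, d2)
        ivs = enrich.scan_intervals(a, b)
        eligible = int(((d1 >= 10) | (d2 >= 10)).sum())
        assert sum(iv.n_eligible for iv in ivs) == eligible

    def test_mismatched_sequence_sets_rejected(self):
        a, _ = _profiles([1], [1])
        with pytest.raises(ParameterError):
            enrich.scan_intervals(a, {}, enrich.EnrichmentParams())


class TestEnrichmentScore:
    def test_equal_standardized_coverage_scores_zero(self):
        assert enrich.enrichment_score(80, 40, 80, 40) == pytest.approx(0.0)

    def test_standardized_ratio_sixty_four_scores_six(self):
        assert enrich.enrichment_score(64 * 73, 73, 73, 73) == pytest.approx(6.0)

    def test_zero_somatic_mean_is_floored_and_finite(self):
        score = enrich.enrichment_score(730, 0.0, 73, 73, floor=1.0)
        assert math.isfinite(score)
        assert score == pytest.approx(math.log2(730 / 1.0))

    def test_nonpositive_modal_depth_rejected(self):
        with pytest.raises(ParameterError):
            enrich.enrichment_score(10, 10, 0, 73)


class TestEstimateSpan:
    def test_modal_depth_sequence_spans_its_own_length(self):
        assert enrich.estimate_span(1000, 73, 73) == pytest.approx(1000)

    def test_zero_depth_zero_span(self):
        assert enrich.estimate_span(1000, 0, 73) == 0.0

    def test_double_depth_doubles_span(self):
        assert enrich.estimate_span(5000, 146, 73) == pytest.approx(10_000)

    @given(
        st.floats(1, 1e5), st.floats(0, 1e6), st.floats(0.5, 4.0), st.floats(0.5, 4.0)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_homogeneity_in_length_and_depth(self, length, depth, a, b):
        base = enrich.estimate_span(length, depth, 73)
        assert enrich.estimate_span(a * length, b * depth, 73) == pytest.approx(
            a * b * base, rel=1e-9
        )


class TestGermlineFilter:
    def _iv(self, score, span):
        iv = enrich.EnrichmentInterval("s", 0, 100, 100, 1, 1, 1)
        iv.enrichment_score = score
        iv.estimated_span = span
        return iv

    def test_strictly_above_both_thresholds_kept(self):
        kept = enrich.filter_germline([self._iv(5.1, 41_000)])
        assert len(kept) == 1

    def test_boundary_score_rejected_even_with_huge_span(self):
        assert enrich.filter_germline([self._iv(5.0, 100_000)]) == []

    def test_boundary_span_rejected_even_with_huge_score(self):
        assert enrich.filter_germline([self._iv(8.0, 40_000)]) == []

    def test_epsilon_above_both_kept_and_order_preserved(self):
        ivs = [
            self._iv(5.0 + 1e-9, 40_001),
            self._iv(4.0, 50_000),
            self._iv(7.0, 45_000),
        ]
        kept = enrich.filter_germline(ivs)
        assert kept == [ivs[0], ivs[2]]

    def test_unscored_intervals_rejected(self):
        iv = enrich.EnrichmentInterval("s", 0, 10, 10, 1, 1, 1)
        with pytest.raises(ParameterError):
            enrich.filter_germline([iv])


def test_bedgraph_roundtrip(tmp_path):
    rng = np.random.default_rng(1)
    depth = rng.integers(0, 50, size=3000)
    profiles = {"s1": enrich.CoverageProfile("s1", depth.astype(np.int64))}
    path = tmp_path / "cov.bedgraph"
    enrich.write_bedgraph(profiles, path)
    back = enrich.read_bedgraph(path, {"s1": 3000})
    assert (back["s1"].depth == depth).all()
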