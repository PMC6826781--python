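"""Tandem-unit detection, inverted cassettes, scaffold assignment, ranking."""

import numpy as np
import pytest

from germscan import annotate, synth
from germscan.assembly import RepeatConsensus
from germscan.enrich import CoverageProfile
from germscan.errors import ParameterError
from germscan.seqs import revcomp

from conftest import random_dna
from test_merge import mutate


def brute_force_period_scores(seq: str, pmin: int, pmax: int) -> dict[int, float]:
    """Oracle: direct self-match fraction for every candidate period."""
    out = {}
    for p in range(pmin, min(pmax, len(seq) - 1) + 1):
        pairs = [(seq[i], seq[i + p]) for i in range(len(seq) - p)]
        if pairs:
            out[p] = sum(a == b for a, b in pairs) / len(pairs)
    return out


class TestDetectCoreUnit:
    def test_perfect_tandem_array(self):
        unit = random_dna(20, seed=1)
        ann = annotate.detect_core_unit(unit * 10)
        assert ann.core_unit_length == 20
        assert ann.periodicity_score == 1.0
        assert ann.core_consensus == unit

    def test_noisy_37bp_unit_detected_and_score_matches_oracle(self):
        unit = random_dna(37, seed=2)
        arr = "".join(mutate(unit, 1, seed=10 + i) for i in range(12))  # ~3% noise
        ann = annotate.detect_core_unit(arr)
        assert ann.core_unit_length == 37
        assert ann.periodicity_score >= 0.9
        oracle = brute_force_period_scores(arr, 5, 200)
        assert ann.periodicity_score == pytest.approx(oracle[37])

    def test_random_sequence_has_no_qualifying_period(self):
        ann = annotate.detect_core_unit(random_dna(1000, seed=3))
        assert ann.core_unit_length is None
        assert ann.periodicity_score < 0.8

    def test_rotation_invariance_of_the_detected_period(self):
        unit = random_dna(24, seed=4)
        arr = unit * 8
        periods = set()
        for shift in (0, 5, 11, 17, 23):
            rot = arr[shift:] + arr[:shift]
            periods.add(annotate.detect_core_unit(rot).core_unit_length)
        assert periods == {24}

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ParameterError):
            annotate.detect_core_unit("ACGTACG")

    def test_consensus_majority_vote_repairs_sparse_noise(self):
        unit = random_dna(15, seed=5)
        arr = unit + mutate(unit, 1, seed=6) + unit + unit
        ann = annotate.detect_core_unit(arr)
        assert ann.core_unit_length == 15
        assert ann.core_consensus == unit


class TestInvertedCassettes:
    def test_constructed_palindrome_found_as_one_pair(self):
        s = random_dna(300, seed=7)
        pairs = annotate.find_inverted_cassettes(s + revcomp(s))
        assert len(pairs) == 1
        (a, b) = pairs[0]
        assert a[0] < 300 <= b[0]
        assert (a[1] - a[0]) >= 250 and (b[1] - b[0]) >= 250

    def test_pure_forward_tandem_has_no_cassettes(self):
        unit = random_dna(30, seed=8)
        assert annotate.find_inverted_cassettes(unit * 20) == []

    def test_synthetic_cassette_positions_match_truth_within_10bp(self):
        spec = synth.FamilySpec(
            "f", synth.make_repeat_unit(30, 0.5, seed=9), 60,
            inverted_cassette_prob=0.0, cassette_size=10,
        )
        fwd, units, _ = synth.expand_tandem_array(spec, 40, seed=10)
        # build: 600 bp forward block, inverted 300 bp cassette, forward tail
        block = fwd[:600]
        cassette = revcomp(fwd[600:900])
        arr = block + cassette + fwd[900:1200]
        pairs = annotate.find_inverted_cassettes(arr, min_cassette=150)
        assert pairs, "inverted cassette missed"
        found = min(
            pairs, key=lambda ab: abs(ab[1][0] - 600)
        )
        assert abs(found[1][0] - 600) <= 10 and abs(found[1][1] - 900) <= 10

    def test_output_mirrors_under_reverse_complement(self):
        s = random_dna(250, seed=11)
        text = s + revcomp(s) + random_dna(100, seed=12)
        fwd_pairs = annotate.find_inverted_cassettes(text, min_cassette=150)
        rc_pairs = annotate.find_inverted_cassettes(revcomp(text), min_cassette=150)
        n = len(text)
        mirrored = sorted(
            tuple(sorted([(n - b1, n - b0), (n - a1, n - a0)]))
            for (a0, a1), (b0, b1) in fwd_pairs
        )
        def within(x, y, tol=15):
            return all(abs(p - q) <= tol for (p0, p1), (q0, q1) in zip(x, y)
                       for p, q in ((p0, q0), (p1, q1)))
        assert len(rc_pairs) == len(mirrored)
        for got, want in zip(sorted(rc_pairs), mirrored):
            assert within(got, want)


class TestAssignScaffold:
    def _scaffolds(self, repeat, seed=13):
        a = random_dna(3000, seed=seed)
        b = random_dna(3000, seed=seed + 1)
        # plant the repeat 5 times in A, 2 times in B
        for i, pos in enumerate([200, 800, 1400, 2000, 2600]):
            a = a[:pos] + repeat + a[pos + len(repeat):]
        for pos in (500, 1500):
            b = b[:pos] + repeat + b[pos + len(repeat):]
        return [("scafA", a), ("scafB", b)]

    def test_majority_scaffold_wins(self):
        repeat = RepeatConsensus(id="r", sequence=random_dna(120, seed=14))
        scaffolds = self._scaffolds(repeat.sequence)
        asn = annotate.assign_scaffold(repeat, scaffolds)
        assert asn.scaffold_id == "scafA"
        assert asn.hit_count >= 5
        assert asn.fraction_bases_aligned >= 0.8

    def test_result_invariant_to_scaffold_order(self):
        repeat = RepeatConsensus(id="r", sequence=random_dna(120, seed=15))
        scaffolds = self._scaffolds(repeat.sequence, seed=16)
        a = annotate.assign_scaffold(repeat, scaffolds)
        b = annotate.assign_scaffold(repeat, list(reversed(scaffolds)))
        assert (a.scaffold_id, a.hit_count) == (b.scaffold_id, b.hit_count)

    def test_absent_repeat_is_unassigned(self):
        repeat = RepeatConsensus(id="r", sequence=random_dna(120, seed=17))
        scaffolds = [("scafA", random_dna(2000, seed=18))]
        asn = annotate.assign_scaffold(repeat, scaffolds)
        assert asn.scaffold_id is None and asn.hit_count == 0

    def test_empty_scaffold_set_rejected(self):
        with pytest.raises(ParameterError):
            annotate.assign_scaffold(
                RepeatConsensus(id="r", sequence="ACGT" * 30), []
            )


class TestSomaticRanking:
    def _profiles(self, depths):
        return {
            sid: CoverageProfile(sid, np.full(100, d, dtype=np.int64))
            for sid, d in depths.items()
        }

    def test_highest_somatic_depth_ranks_first(self):
        lib = [RepeatConsensus(id=i, sequence="ACGT" * 10) for i in ("X", "Y", "Z")]
        prof = self._profiles({"X": 500, "Y": 50, "Z": 5})
        assert annotate.rank_by_somatic_coverage(lib, prof, top_n=1) == [("X", 500.0)]

    def test_ties_break_lexicographically(self):
        lib = [RepeatConsensus(id=i, sequence="ACGT" * 10) for i in ("b", "a")]
        prof = self._profiles({"a": 50, "b": 50})
        assert [i for i, _ in annotate.rank_by_somatic_coverage(lib, prof, 2)] == ["a", "b"]

    def test_missing_profile_counts_as_zero_depth(self):
        lib = [RepeatConsensus(id=i, sequence="ACGT" * 10) for i in ("a", "b")]
        prof = self._profiles({"a": 10})
        ranked = annotate.rank_by_somatic_coverage(lib, prof, 2)
        assert ranked == [("a", 10.0), ("b", 0.0)]
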