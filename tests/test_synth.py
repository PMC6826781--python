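"""Synthetic genome/read generator: units, arrays, genome pairs, reads."""

import math

import numpy as np
import pytest

from germscan import synth
from germscan.errors import ParameterError
from germscan.seqs import revcomp


class TestRepeatUnit:
    def test_deterministic_and_exact_length(self):
        a = synth.make_repeat_unit(20, 0.5, seed=1)
        b = synth.make_repeat_unit(20, 0.5, seed=1)
        assert a == b and len(a) == 20 and set(a) <= set("ACGT")
        assert synth.make_repeat_unit(20, 0.5, seed=2) != a

    @pytest.mark.parametrize("length", [13, 57])
    def test_core_size_bounds(self, length):
        assert len(synth.make_repeat_unit(length, 0.5, seed=3)) == length

    def test_length_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            synth.make_repeat_unit(4, 0.5, seed=1)
        with pytest.raises(ParameterError):
            synth.make_repeat_unit(501, 0.5, seed=1)


def _spec(unit, **kw):
    defaults = dict(
        family_id="f", unit_seq=unit, copies_germline=10, copies_somatic=0,
        indel_rate=0.0, substitution_rate=0.0, inverted_cassette_prob=0.0,
        cassette_size=5,
    )
    defaults.update(kw)
    return synth.FamilySpec(**defaults)


class TestTandemArray:
    def test_noiseless_concatenation(self):
        unit = synth.make_repeat_unit(20, 0.5, seed=4)
        arr, units, cassettes = synth.expand_tandem_array(_spec(unit), 10, seed=1)
        assert arr == unit * 10
        assert len(arr) == 200 and len(units) == 10
        assert all(st == "+" for _, _, st in units)
        assert [arr[a:b] for a, b, _ in units] == [unit] * 10
        assert cassettes == []

    def test_single_copy_is_identity(self):
        unit = synth.make_repeat_unit(15, 0.5, seed=5)
        arr, units, _ = synth.expand_tandem_array(_spec(unit), 1, seed=2)
        assert arr == unit and units == [(0, 15, "+")]

    def test_indel_disrupted_length_within_analytic_bounds(self):
        # each junction independently gains or loses 1-3 bp with p=0.05;
        # bound total length by mean +- 6 sd of the compound binomial
        unit = synth.make_repeat_unit(20, 0.5, seed=6)
        copies = 1000
        arr, units, _ = synth.expand_tandem_array(
            _spec(unit, indel_rate=0.05), copies, seed=7
        )
        n_junc = copies - 1  # junctions inside cassettes only
        # per junction: +-{1,2,3} with prob 0.05, mean 0, var 0.05*(1+4+9)/3
        sd = math.sqrt(n_junc * 0.05 * (1 + 4 + 9) / 3)
        assert abs(len(arr) - copies * 20) <= 6 * sd + 3 * copies / 5  # cassette edges
        assert len(units) == copies

    def test_inverted_cassettes_recorded_and_reverse_complemented(self):
        unit = synth.make_repeat_unit(20, 0.5, seed=8)
        arr, units, cassettes = synth.expand_tandem_array(
            _spec(unit, inverted_cassette_prob=1.0, cassette_size=5), 10, seed=9
        )
        assert len(cassettes) == 2  # every cassette inverted
        for a, b in cassettes:
            assert revcomp(arr[a:b]) == unit * 5
        assert all(st == "-" for _, _, st in units)
        assert all(revcomp(arr[a:b]) == unit for a, b, _ in units)

    def test_placements_tile_without_overlap(self):
        unit = synth.make_repeat_unit(17, 0.5, seed=10)
        arr, units, _ = synth.expand_tandem_array(
            _spec(unit, indel_rate=0.1, substitution_rate=0.02,
                  inverted_cassette_prob=0.3), 200, seed=11
        )
        last = 0
        for a, b, _ in units:
            assert 0 <= a < b <= len(arr)
            assert a >= last
            last = b


class TestGenomePair:
    def test_shared_only_family_content_identical(self):
        unit = synth.make_repeat_unit(25, 0.5, seed=12)
        fam = _spec(unit, copies_germline=100, copies_somatic=100)
        germ, soma, truth = synth.build_genome_pair([fam], 50_000, 1, seed=1)
        assert [n for n, _ in germ] == [n for n, _ in soma]
        assert truth.realized_copies("f") == (100, 100)
        (g_arr,), (s_arr,) = truth.germline, truth.somatic
        assert (g_arr.start, g_arr.end) == (s_arr.start, s_arr.end)
        assert germ[0][1][g_arr.start : g_arr.end] == soma[0][1][s_arr.start : s_arr.end]

    def test_restricted_family_adds_span_only_to_germline(self):
        unit = synth.make_repeat_unit(30, 0.5, seed=13)
        fam = _spec(unit, copies_germline=2000, copies_somatic=0)
        germ, soma, truth = synth.build_genome_pair([fam], 200_000, 1, seed=2)
        span = truth.planted_span("f")
        assert abs(span - 60_000) < 2_000  # ~60 kb, +- junction indels
        assert truth.somatic == []
        g_seq, s_seq = germ[0][1], soma[0][1]
        arr = truth.germline[0]
        assert g_seq[: arr.start] == s_seq[: arr.start]
        assert g_seq[arr.start : arr.end] != s_seq[arr.start : arr.end]

    def test_placements_stay_within_each_sequence(self):
        fams = [
            _spec(synth.make_repeat_unit(20, 0.5, seed=14), family_id="a",
                  copies_germline=300, n_arrays=2),
            _spec(synth.make_repeat_unit(30, 0.5, seed=15), family_id="b",
                  copies_germline=200, copies_somatic=200, n_arrays=2),
        ]
        germ, _, truth = synth.build_genome_pair(fams, 100_000, 2, seed=3)
        seq_len = {n: len(s) for n, s in germ}
        seen = {n: [] for n in seq_len}
        for arr in truth.germline:
            assert 0 <= arr.start < arr.end <= seq_len[arr.seq_id]
            seen[arr.seq_id].append((arr.start, arr.end))
        for ivs in seen.values():
            ivs.sort()
            for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
                assert a1 <= b0  # arrays never overlap

    def test_overflow_rejected(self):
        fam = _spec(synth.make_repeat_unit(30, 0.5, seed=16), copies_germline=1000)
        with pytest.raises(ParameterError):
            synth.build_genome_pair([fam], 20_000, 1, seed=1)

    def test_truth_expected_score_reproducible_from_counts(self):
        unit = synth.make_repeat_unit(20, 0.5, seed=17)
        fam = _spec(unit, copies_germline=640, copies_somatic=10)
        _, _, truth = synth.build_genome_pair([fam], 60_000, 1, seed=4)
        g, s = truth.realized_copies("f")
        assert truth.expected_score("f", 40.0) == pytest.approx(
            math.log2((g * 40.0) / (s * 40.0))
        )
        fam2 = _spec(unit, family_id="r", copies_germline=640, copies_somatic=0)
        _, _, t2 = synth.build_genome_pair([fam2], 60_000, 1, seed=4)
        assert t2.expected_score("r", 40.0) == pytest.approx(math.log2(640 * 40.0))


class TestReadSimulator:
    def test_read_count_matches_coverage(self):
        genome = [("chr1", synth.make_repeat_unit(500, 0.5, seed=18) * 2000)]  # 1 Mb
        cfg = synth.ReadSimConfig(
            read_length=100, mean_coverage=40, error_rate=0.0, paired=False, seed=1
        )
        reads = synth.simulate_reads(genome, cfg)
        expect = 400_000
        sd = math.sqrt(expect)
        assert abs(len(reads) - expect) <= 6 * sd + 1

    def test_noiseless_reads_are_genome_substrings(self):
        genome = [("chr1", synth.make_repeat_unit(200, 0.5, seed=19) * 50)]
        cfg = synth.ReadSimConfig(mean_coverage=2, error_rate=0.0, paired=True, seed=2)
        reads = synth.simulate_reads(genome, cfg)
        text = genome[0][1]
        for r in reads[:200]:
            assert r in text or revcomp(r) in text

    def test_same_seed_gives_byte_identical_fastq(self, tmp_path):
        genome = [("chr1", synth.make_repeat_unit(300, 0.5, seed=20) * 20)]
        cfg = synth.ReadSimConfig(mean_coverage=5, seed=3)
        p1, p2 = tmp_path / "a.fq", tmp_path / "b.fq"
        synth.simulate_reads(genome, cfg, out_path=p1)
        synth.simulate_reads(genome, cfg, out_path=p2)
        assert p1.read_bytes() == p2.read_bytes()
        synth.simulate_reads(genome, synth.ReadSimConfig(mean_coverage=5, seed=4), out_path=p2)
        assert p1.read_bytes() != p2.read_bytes()

    def test_read_longer_than_sequence_rejected(self):
        genome = [("chr1", "ACGT" * 10)]
        with pytest.raises(ParameterError):
            synth.simulate_reads(genome, synth.ReadSimConfig(read_length=100, seed=1))

    def test_error_rate_bounds_enforced(self):
        with pytest.raises(ParameterError):
            synth.ReadSimConfig(error_rate=0.5)
        with pytest.raises(ParameterError):
            synth.ReadSimConfig(mean_coverage=0)
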