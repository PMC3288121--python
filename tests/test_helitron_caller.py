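import random

import pytest

from heliscan import helitron_caller as hc
from heliscan import motif_engine as me
from heliscan.motif_engine import TerminusHit
from heliscan.sequence_io import GenomeSequence, GenomicInterval, reverse_complement

from _oracles import brute_force_pairing
from conftest import random_dna


def _hit(start, end, end_type, family="helA", strand="+", seq_id="chr1", level="strict"):
    return TerminusHit(
        interval=GenomicInterval(seq_id, start, end, strand),
        family=family,
        end_type=end_type,
        pass_level=level,
        matched_text="N/A",
    )


def _sorted(hits):
    return sorted(hits, key=me.hit_sort_key)


class TestPairTermini:
    def test_simple_pair_under_span_limit(self):
        hits = _sorted([_hit(1_000, 1_017, "five_prime"), _hit(14_971, 15_000, "three_prime")])
        calls = hc.pair_termini(hits)
        assert len(calls) == 1
        assert (calls[0].interval.start, calls[0].interval.end) == (1_000, 15_000)

    def test_span_limit_is_strict(self):
        hits = _sorted([_hit(0, 17, "five_prime"), _hit(24_971, 25_000, "three_prime")])
        assert hc.pair_termini(hits) == []
        # exactly at the limit is also excluded ("less than 20 kb")
        hits = _sorted([_hit(0, 17, "five_prime"), _hit(19_971, 20_000, "three_prime")])
        assert hc.pair_termini(hits) == []

    def test_multiple_three_hits_extend_to_farthest(self):
        hits = _sorted(
            [
                _hit(0, 17, "five_prime"),
                _hit(1_971, 2_000, "three_prime"),
                _hit(7_971, 8_000, "three_prime"),
            ]
        )
        calls = hc.pair_termini(hits)
        assert len(calls) == 1
        call = calls[0]
        assert call.interval.end == 8_000
        assert [t.interval.end for t in call.three_hits] == [2_000, 8_000]
        assert call.multi_termini_3 == 2

    def test_no_family_or_strand_mixing(self):
        hits = _sorted(
            [
                _hit(0, 17, "five_prime", family="helA"),
                _hit(971, 1_000, "three_prime", family="helB"),
                _hit(1_971, 2_000, "three_prime", family="helA", strand="-"),
            ]
        )
        assert hc.pair_termini(hits) == []

    def test_unsorted_input_rejected(self):
        hits = [_hit(5_000, 5_017, "five_prime"), _hit(100, 129, "three_prime")]
        with pytest.raises(ValueError, match="sorted"):
            hc.pair_termini(hits)

    def test_three_hit_shared_by_two_five_hits(self):
        # a 3'-hit in range of two upstream 5'-hits is assigned to both
        hits = _sorted(
            [
                _hit(0, 17, "five_prime"),
                _hit(500, 517, "five_prime"),
                _hit(3_971, 4_000, "three_prime"),
            ]
        )
        calls = hc.pair_termini(hits)
        assert len(calls) == 2
        assert {c.interval.start for c in calls} == {0, 500}
        assert all(c.interval.end == 4_000 for c in calls)
        assert calls[0].multi_termini_5 == 2

    def test_minus_strand_pairing(self):
        # minus strand: 5'-terminus sits at higher genome coordinates
        hits = _sorted(
            [
                _hit(1_000, 1_029, "three_prime", strand="-"),
                _hit(5_000, 5_017, "five_prime", strand="-"),
            ]
        )
        calls = hc.pair_termini(hits)
        assert len(calls) == 1
        assert (calls[0].interval.start, calls[0].interval.end) == (1_000, 5_017)
        assert calls[0].interval.strand == "-"

    def test_orphan_five_hit_logged(self, caplog):
        import logging

        with caplog.at_level(logging.INFO, "heliscan.helitron_caller"):
            assert hc.pair_termini([_hit(0, 17, "five_prime")]) == []
        assert any("orphan" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(10))
    def test_against_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        hits = []
        for _ in range(40):
            start = rng.randrange(0, 60_000)
            end = start + rng.randrange(15, 30)
            hits.append(
                _hit(
                    start,
                    end,
                    rng.choice(["five_prime", "three_prime"]),
                    family=rng.choice(["helA", "helB"]),
                    strand=rng.choice(["+", "-"]),
                )
            )
        hits = _sorted(hits)
        calls = hc.pair_termini(hits)
        got = sorted(
            (
                c.interval.seq_id,
                c.interval.start,
                c.interval.end,
                c.interval.strand,
                c.family,
                c.multi_termini_3,
            )
            for c in calls
        )
        assert got == brute_force_pairing(hits)

    def test_determinism_under_hit_reordering(self, rng):
        hits = []
        for _ in range(30):
            start = rng.randrange(0, 40_000)
            hits.append(
                _hit(start, start + 20, rng.choice(["five_prime", "three_prime"]))
            )
        a = hc.pair_termini(_sorted(hits))
        rng.shuffle(hits)
        b = hc.pair_termini(_sorted(hits))
        assert [(c.interval, c.multi_termini_3) for c in a] == [
            (c.interval, c.multi_termini_3) for c in b
        ]


class TestAnnotateFlanks:
    def _call(self, start, end, strand="+"):
        five = _hit(start, start + 17, "five_prime", strand=strand)
        three = _hit(end - 29, end, "three_prime", strand=strand)
        return hc.HelitronCall(
            interval=GenomicInterval("chr1", start, end, strand),
            family="helA",
            five_hit=five,
            three_hits=(three,),
        )

    def test_at_insertion_true(self, rng):
        seq = random_dna(rng, 200)
        seq = seq[:49] + "A" + seq[50:150] + "T" + seq[151:]
        call = hc.annotate_flanks(self._call(50, 150), GenomeSequence("chr1", seq))
        assert (call.flank_upstream_base, call.flank_downstream_base) == ("A", "T")
        assert call.at_insertion

    def test_non_at_flanks(self, rng):
        seq = "G" * 50 + random_dna(rng, 100) + "T" * 50
        call = hc.annotate_flanks(self._call(50, 150), GenomeSequence("chr1", seq))
        assert not call.at_insertion
        assert call.flank_upstream_base == "G"

    def test_contig_edge_missing_flank(self, rng):
        seq = random_dna(rng, 150)
        call = hc.annotate_flanks(self._call(0, 100), GenomeSequence("chr1", seq))
        assert call.flank_upstream_base is None
        assert not call.at_insertion

    def test_minus_strand_orientation(self, rng):
        # genome ...A[element]T... reads A/T strand-oriented on minus too
        seq = random_dna(rng, 200)
        seq = seq[:49] + "A" + seq[50:150] + "T" + seq[151:]
        call = hc.annotate_flanks(self._call(50, 150, "-"), GenomeSequence("chr1", seq))
        assert (call.flank_upstream_base, call.flank_downstream_base) == ("A", "T")
        assert call.at_insertion


class TestDetectHairpin:
    def _call_on(self, seq, strand="+"):
        n = len(seq)
        five = _hit(0, 17, "five_prime", strand=strand)
        three = _hit(n - 29, n, "three_prime", strand=strand)
        return hc.HelitronCall(
            interval=GenomicInterval("chr1", 0, n, strand),
            family="helA",
            five_hit=five,
            three_hits=(three,),
        )

    def test_planted_perfect_palindrome(self, rng):
        stem = "GATTCCGA"
        palindrome = stem + reverse_complement(stem)  # 16 bp, 8 bp stem
        body = random_dna(rng, 300)
        # AA guards stop the stem extending past the planted palindrome
        seq = body + "AA" + palindrome + "AA" + random_dna(rng, 9)
        call = self._call_on(seq)
        hp = hc.detect_hairpin(call, GenomeSequence("chr1", seq), max_mismatch=0)
        assert hp is not None
        assert hp.stem_length == 8
        assert hp.mismatches == 0
        assert hp.distance_to_3prime == 11

    def test_homopolymer_window_none(self):
        seq = "ATCTGTACTACAAAAAA" + "A" * 200
        call = self._call_on(seq)
        assert hc.detect_hairpin(call, GenomeSequence("chr1", seq)) is None

    def test_tie_broken_toward_3prime(self, rng):
        stem = "GATTCCGA"
        pal = stem + reverse_complement(stem)
        seq = random_dna(rng, 200) + "AA" + pal + "AACCAA" + pal + "AAGG"
        call = self._call_on(seq)
        hp = hc.detect_hairpin(call, GenomeSequence("chr1", seq), max_mismatch=0)
        assert hp is not None
        assert hp.distance_to_3prime == 4  # nearer palindrome wins the tie


class TestPutativeAutonomous:
    def _call_len(self, length):
        five = _hit(0, 17, "five_prime")
        three = _hit(length - 29, length, "three_prime")
        return hc.HelitronCall(
            interval=GenomicInterval("chr1", 0, length, "+"),
            family="helA",
            five_hit=five,
            three_hits=(three,),
        )

    def test_long_call_empty_mask(self):
        assert hc.flag_putative_autonomous(self._call_len(12_000), [])

    def test_long_call_masked(self):
        mask = [GenomicInterval("chr1", 5_000, 9_000)]
        assert not hc.flag_putative_autonomous(self._call_len(12_000), mask)

    def test_short_call(self):
        assert not hc.flag_putative_autonomous(self._call_len(8_000), [])
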