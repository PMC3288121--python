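import random

import pytest

from heliscan import homology_engine as hom
from heliscan import synthetic_genome as sg
from heliscan.sequence_io import GenomeSequence, GenomicInterval, reverse_complement

from _oracles import smith_waterman_score
from conftest import random_dna


def _plant(bg: str, inserts: dict[int, str]) -> str:
    out, last = [], 0
    for pos in sorted(inserts):
        out.append(bg[last:pos])
        out.append(inserts[pos])
        last = pos
    out.append(bg[last:])
    return "".join(out)


class TestLocalSearch:
    def test_exact_copy(self, rng):
        query = random_dna(rng, 400)
        g = _plant(random_dna(rng, 20_000), {8_000: query})
        hits = hom.local_search(query, g)
        assert len(hits) == 1
        h = hits[0]
        assert h.identity == pytest.approx(100.0)
        assert h.coverage == pytest.approx(100.0)
        assert (h.subject_interval.start, h.subject_interval.end) == (8_000, 8_400)

    def test_mutated_copy_identity(self, rng):
        query = random_dna(rng, 1_000)
        (mut, realized), = sg.mutate_copies(query, 1, 0.10, seed=42)
        g = _plant(random_dna(rng, 20_000), {5_000: mut})
        hits = hom.local_search(query, g, min_identity=70)
        assert hits
        assert hits[0].identity == pytest.approx(realized, abs=2.0)

    def test_absent_query(self, rng):
        g = random_dna(rng, 20_000)
        assert hom.local_search(random_dna(rng, 300), g, min_identity=80) == []

    def test_minus_strand_copy_found(self, rng):
        query = random_dna(rng, 500)
        g = _plant(random_dna(rng, 10_000), {4_000: reverse_complement(query)})
        hits = hom.local_search(query, g)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].identity == pytest.approx(100.0)

    def test_short_query_rejected(self, rng):
        with pytest.raises(ValueError, match="seed size"):
            hom.local_search("ACGTAC", random_dna(rng, 1_000))

    @pytest.mark.parametrize("seed", range(4))
    def test_score_matches_dp_oracle(self, seed):
        # on short sequences the seeded search must reach the full DP score
        rng = random.Random(seed)
        query = random_dna(rng, 150)
        subject = _plant(
            random_dna(rng, 1_200),
            {400: sg.mutate_copies(query, 1, 0.05, seed=seed)[0][0]},
        )
        hits = hom.local_search(query, subject, min_len_bp=20, min_identity=50)
        assert hits
        oracle = smith_waterman_score(subject, query)
        assert hits[0].score == pytest.approx(oracle)


class TestSeedDiscovery:
    def test_planted_full_copy(self, rng):
        seed_el = random_dna(rng, 1_200)
        g = _plant(random_dna(rng, 30_000), {9_000: seed_el})
        cands = hom.seed_discovery([seed_el], g)
        assert [(c.start, c.end) for c in cands] == [(9_000, 10_200)]

    def test_five_probe_only_no_candidate(self, rng):
        seed_el = random_dna(rng, 1_200)
        g = _plant(random_dna(rng, 30_000), {9_000: seed_el[:300]})
        assert hom.seed_discovery([seed_el], g) == []

    def test_two_copies_far_apart(self, rng):
        seed_el = random_dna(rng, 1_000)
        g = _plant(random_dna(rng, 80_000), {10_000: seed_el, 40_000: seed_el})
        cands = hom.seed_discovery([seed_el], g)
        # second planted copy shifts by the first copy's length
        assert [(c.start, c.end) for c in cands] == [
            (10_000, 11_000), (41_000, 42_000),
        ]


class TestValidateBoundaries:
    def _genome_with_copies(self, rng, n_copies, element_len=1_200, flank=15_000):
        el = random_dna(rng, element_len)
        bg = random_dna(rng, flank * (n_copies + 1))
        inserts = {flank * (i + 1): el for i in range(n_copies)}
        g = _plant(bg, inserts)
        truth = [
            GenomicInterval("g", flank * (i + 1) + i * element_len,
                            flank * (i + 1) + (i + 1) * element_len)
            for i in range(n_copies)
        ]
        # force the first flank column on each side to differ across copies,
        # otherwise the planted edge is genuinely ambiguous
        chars = list(g)
        for i, iv in enumerate(truth):
            chars[iv.start - 1] = "CTGA"[i % 4]
            chars[iv.end] = "GACT"[i % 4]
        return GenomeSequence("g", "".join(chars)), truth

    def test_exact_boundaries_recovered(self, rng):
        genome, truth = self._genome_with_copies(rng, 3)
        trimmed = [GenomicInterval("g", iv.start + 25, iv.end - 25) for iv in truth]
        res = hom.validate_boundaries(trimmed, genome)
        assert res.resolved
        assert [(iv.start, iv.end) for iv in res.intervals] == [
            (iv.start, iv.end) for iv in truth
        ]

    def test_shared_flank_within_window(self, rng):
        # 5 bp of shared flank by chance: boundary within the window width
        genome, truth = self._genome_with_copies(rng, 3)
        seq = genome.residues
        chars = list(seq)
        for iv in truth:
            chars[iv.end : iv.end + 5] = "ACGTA"
        genome = GenomeSequence("g", "".join(chars))
        trimmed = [GenomicInterval("g", iv.start + 25, iv.end - 25) for iv in truth]
        res = hom.validate_boundaries(trimmed, genome)
        assert res.resolved
        for got, want in zip(res.intervals, truth):
            assert abs(got.end - want.end) <= 10

    def test_single_copy_flagged(self, rng):
        genome, truth = self._genome_with_copies(rng, 1)
        res = hom.validate_boundaries([truth[0]], genome)
        assert not res.resolved
        assert res.note == "single copy"

    def test_identical_flanks_unresolvable(self, rng):
        # tandem-duplication-like: identical flanks never diverge
        el = random_dna(rng, 500)
        unit = random_dna(rng, 300) + el + random_dna(rng, 300)
        g = unit * 3
        genome = GenomeSequence("g", g)
        copies = [
            GenomicInterval("g", i * len(unit) + 300, i * len(unit) + 800)
            for i in range(3)
        ]
        res = hom.validate_boundaries(copies, genome, max_extend=250)
        assert not res.resolved
        assert "diverge" in res.note


class TestCountCopies:
    def test_verbatim_copies(self, rng):
        el = random_dna(rng, 800)
        inserts = {5_000 + i * 4_000: el for i in range(5)}
        g = _plant(random_dna(rng, 40_000), inserts)
        tiers = hom.count_copies(el, g)
        assert tiers[0].copy_count == 5  # (95, 95)

    def test_diverged_copies_in_relaxed_tiers(self, rng):
        el = random_dna(rng, 800)
        inserts = {5_000 + i * 4_000: el for i in range(5)}
        for i, (c, ident) in enumerate(sg.mutate_copies(el, 3, 0.13, seed=8)):
            assert 83 < ident < 92
            inserts[26_000 + i * 4_000] = c
        g = _plant(random_dna(rng, 45_000), inserts)
        tiers = hom.count_copies(el, g)
        assert tiers[0].copy_count == 5  # strict: only exact copies
        assert tiers[2].copy_count == 8  # (85, 85): all eight
        assert tiers[3].copy_count == 8

    def test_no_copies(self, rng):
        el = random_dna(rng, 500)
        tiers = hom.count_copies(el, random_dna(rng, 20_000))
        assert [t.copy_count for t in tiers] == [0, 0, 0, 0]

    def test_tier_monotonicity(self, rng):
        el = random_dna(rng, 600)
        inserts = {4_000 + i * 3_000: sg.mutate_copies(el, 1, rng.choice([0, 0.02, 0.08, 0.15]), seed=i)[0][0] for i in range(6)}
        g = _plant(random_dna(rng, 40_000), inserts)
        counts = [t.copy_count for t in hom.count_copies(el, g)]
        assert counts == sorted(counts)

    def test_strand_symmetry(self, rng):
        el = random_dna(rng, 700)
        inserts = {5_000: el, 12_000: reverse_complement(el)}
        g = _plant(random_dna(rng, 25_000), inserts)
        fwd = [t.copy_count for t in hom.count_copies(el, g)]
        rev = [t.copy_count for t in hom.count_copies(el, reverse_complement(g))]
        assert fwd == rev
        assert fwd[0] == 2

    def test_default_tiers_match_published_layout(self):
        tiers = hom.default_tiers()
        assert [t.label for t in tiers] == [
            "coverage>95% and identities>95%",
            "coverage>90% and identities>90%",
            "coverage>85% and identities>85%",
            "coverage>200 bp and identities>80%",
        ]

    def test_tier_validation(self):
        with pytest.raises(ValueError):
            hom.CopyTier(min_identity=90)
        with pytest.raises(ValueError):
            hom.CopyTier(min_identity=90, min_coverage=95, min_length=200)
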