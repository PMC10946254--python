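import numpy as np
import pytest

import pamscan as ps
from pamscan.genome_io import Contig, Genome
from pamscan.specificity import NON_SPECIFIC, SPECIFIC, ULTRA_SPECIFIC
from pamscan.synthetic_data import Plant, SynthSpec, make_decoy, make_genome, make_related_pair

from _reference import naive_offtargets, revcomp


def keys(hits):
    return {h.key for h in hits}


def embed(seq, seed, length=5000, position=1000, strand="+", genome_id="comp"):
    return make_genome(
        SynthSpec(seed=seed, length=length, genome_id=genome_id,
                  plants=(Plant(seq, position=position, strand=strand),))
    )


@pytest.fixture()
def anchor():
    return ps.Target("anchor", "focal", "c1", 0, "+", "TTTC" + "GATTACAGATTACAGATTACA")


class TestFindOfftargets:
    def test_planted_exact_copy_found_at_distance_zero(self, anchor):
        comp = embed(anchor.sequence, seed=21)
        hits = [h for h in ps.find_offtargets(anchor, comp, max_mm=5) if h.start == 1000]
        assert [(h.mismatches, h.strand) for h in hits] == [(0, "+")]
        assert hits[0].site_sequence == anchor.sequence

    def test_reverse_strand_plant_found(self, anchor):
        comp = embed(anchor.sequence, seed=22, strand="-")
        hits = [h for h in ps.find_offtargets(anchor, comp, max_mm=0) if h.start == 1000]
        assert [(h.mismatches, h.strand) for h in hits] == [(0, "-")]

    def test_two_mismatch_decoy_counted(self, anchor):
        decoy = make_decoy(anchor, 2, preserve_pam=True, seed=1)
        comp = embed(decoy, seed=23)
        hits = [h for h in ps.find_offtargets(anchor, comp, max_mm=5) if h.start == 1000]
        assert [h.mismatches for h in hits] == [2]

    def test_broken_pam_decoy_invisible_unless_pam_waived(self, anchor):
        decoy = make_decoy(anchor, 2, preserve_pam=False, seed=1)
        comp = embed(decoy, seed=24)
        assert [h for h in ps.find_offtargets(anchor, comp, max_mm=5) if h.start == 1000] == []
        relaxed = ps.find_offtargets(anchor, comp, max_mm=5, require_pam=False)
        assert any(h.start == 1000 and h.mismatches == 2 for h in relaxed)

    def test_empty_comparator_contig_gives_no_hits(self, anchor):
        comp = Genome("empty", [Contig("c1", "ACGT")])
        assert ps.find_offtargets(anchor, comp) == []

    def test_no_hit_when_nothing_within_five(self, anchor):
        # the selection condition for a usable marker: silence within 5 mm
        comp = make_genome(SynthSpec(seed=77, length=3000, genome_id="far"))
        ref = naive_offtargets(anchor.protospacer, [("chr1", comp.contigs[0].sequence)], 5)
        assume_clear = ref == []
        hits = ps.find_offtargets(anchor, comp, max_mm=5)
        assert keys(hits) == {(c, s, st, m) for c, s, st, m in ref}
        if assume_clear:
            assert hits == []

    def test_planted_decoy_ladder_matches_brute_force(self, anchor):
        plants = tuple(
            Plant(make_decoy(anchor, d, preserve_pam=True, seed=d), position=500 + 400 * i,
                  strand="+" if i % 2 else "-")
            for i, d in enumerate([0, 1, 2, 3, 4, 5] * 3)
        )
        comp = make_genome(SynthSpec(seed=31, length=50_000, genome_id="c", plants=plants))
        fast = ps.find_offtargets(anchor, comp, max_mm=5)
        brute = ps.brute_force_offtargets(anchor, comp, max_mm=5)
        assert keys(fast) == keys(brute)
        assert len(fast) >= 18

    def test_hit_order_deterministic(self, anchor):
        comp = embed(anchor.sequence, seed=25)
        hits = ps.find_offtargets(anchor, comp, max_mm=5)
        assert hits == sorted(hits, key=lambda h: (h.contig_name, h.start, h.strand))


class TestBruteForce:
    def test_matches_pure_python_reference(self, anchor):
        for seed in (1, 2, 3):
            comp = make_genome(SynthSpec(seed=seed, length=1500, genome_id="c"))
            contigs = [(c.name, c.sequence) for c in comp.contigs]
            for mm in (0, 3, 5):
                for rp in (True, False):
                    got = keys(ps.brute_force_offtargets(anchor, comp, max_mm=mm, require_pam=rp))
                    ref = set(naive_offtargets(anchor.protospacer, contigs, mm, require_pam=rp))
                    assert got == ref

    def test_cap_enforced(self, anchor):
        comp = Genome("big", [Contig("c1", "A" * 2000)])
        with pytest.raises(ValueError, match="cap"):
            ps.brute_force_offtargets(anchor, comp, cap=1000)

    def test_exact_search_degenerate_parameters(self, anchor):
        # max_mm=0, no PAM requirement: any 4 bases may precede the protospacer
        comp = embed("ACGG" + anchor.protospacer, seed=26)
        hits = ps.brute_force_offtargets(anchor, comp, max_mm=0, require_pam=False)
        assert any(h.start == 1000 and h.mismatches == 0 for h in hits)


class TestEquivalenceAndInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_randomized_fast_equals_brute(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(2_000, 30_000))
        gc = float(rng.uniform(0.3, 0.7))
        focal = make_genome(SynthSpec(seed=seed + 1000, length=L, gc=gc, genome_id="f"))
        targets = ps.enumerate_targets(focal)
        if not targets:
            pytest.skip("no spontaneous target in this draw")
        target = targets[int(rng.integers(len(targets)))]
        comp = make_genome(SynthSpec(seed=seed + 2000, length=L, gc=gc, genome_id="c"))
        max_mm = int(rng.integers(0, 6))
        require_pam = bool(rng.integers(2))
        fast = ps.find_offtargets(target, comp, max_mm=max_mm, require_pam=require_pam)
        brute = ps.brute_force_offtargets(target, comp, max_mm=max_mm, require_pam=require_pam)
        assert keys(fast) == keys(brute)

    def test_monotone_in_max_mm(self, anchor):
        comp = make_genome(SynthSpec(seed=41, length=20_000, genome_id="c"))
        prev = set()
        for d in range(6):
            cur = {h.key[:3] for h in ps.find_offtargets(anchor, comp, max_mm=d)}
            assert prev <= cur
            prev = cur

    def test_strand_symmetry_of_hits(self, anchor):
        comp = embed(anchor.sequence, seed=42, length=4000)
        L = len(comp.contigs[0].sequence)
        rc = Genome("rc", [Contig("chr1", revcomp(comp.contigs[0].sequence))])
        fwd = ps.find_offtargets(anchor, comp, max_mm=5)
        rev = ps.find_offtargets(anchor, rc, max_mm=5)
        mirrored = {(L - 25 - h.start, {"+": "-", "-": "+"}[h.strand], h.mismatches) for h in rev}
        assert {(h.start, h.strand, h.mismatches) for h in fwd} == mirrored

    def test_pam_requirement_only_removes_hits(self, anchor):
        comp = make_genome(SynthSpec(seed=43, length=20_000, genome_id="c"))
        strict = {h.key for h in ps.find_offtargets(anchor, comp, max_mm=5, require_pam=True)}
        loose = {h.key for h in ps.find_offtargets(anchor, comp, max_mm=5, require_pam=False)}
        assert strict <= loose


class TestHistogram:
    def test_planted_copy_and_decoy(self, anchor):
        decoy3 = make_decoy(anchor, 3, preserve_pam=True, seed=2)
        comp = make_genome(
            SynthSpec(seed=51, length=8000, genome_id="c",
                      plants=(Plant(anchor.sequence, position=1000),
                              Plant(decoy3, position=3000)))
        )
        hist = ps.mismatch_histogram(anchor, comp, max_mm=5)
        ref = naive_offtargets(anchor.protospacer, [("chr1", comp.contigs[0].sequence)], 5)
        expected = [0] * 6
        for *_, mm in ref:
            expected[mm] += 1
        assert hist == expected
        assert hist[0] >= 1 and hist[3] >= 1

    def test_self_exclusion_removes_own_locus_only(self):
        island = "TTTG" + "CAGTCGATTGACCTAGCATGC"
        g = make_genome(SynthSpec(seed=52, length=6000, genome_id="own",
                                  plants=(Plant(island, position=2000),)))
        (t,) = [x for x in ps.enumerate_targets(g) if x.sequence == island]
        with_self = ps.mismatch_histogram(t, g, exclude_self_site=False)
        without = ps.mismatch_histogram(t, g, exclude_self_site=True)
        assert with_self[0] == without[0] + 1
        assert with_self[1:] == without[1:]

    def test_histogram_sums_to_hit_count(self, anchor):
        comp = make_genome(SynthSpec(seed=53, length=30_000, genome_id="c"))
        hist = ps.mismatch_histogram(anchor, comp, max_mm=5)
        assert sum(hist) == len(ps.find_offtargets(anchor, comp, max_mm=5))


class TestScreen:
    def test_no_comparators_is_an_error(self, anchor):
        with pytest.raises(ValueError, match="no comparators"):
            ps.screen_specific([anchor], [])

    def test_identical_comparator_makes_everything_non_specific(self):
        g = make_genome(SynthSpec(seed=61, length=10_000, genome_id="f"))
        twin = Genome("twin", g.contigs)
        targets = ps.enumerate_targets(g)
        profiles = ps.screen_specific(targets[:50], [twin])
        assert {p.specificity_class for p in profiles} == {NON_SPECIFIC}
        assert all(p.min_distance["twin"] == 0 for p in profiles)

    def test_distance_three_neighbour_is_specific_not_ultra(self, anchor):
        decoy3 = make_decoy(anchor, 3, preserve_pam=True, seed=3)
        comp = embed(decoy3, seed=62, length=3000)
        contigs = [(c.name, c.sequence) for c in comp.contigs]
        ref = naive_offtargets(anchor.protospacer, contigs, 5)
        if min(mm for *_, mm in ref) != 3:
            pytest.skip("background produced an extra close site in this draw")
        (profile,) = ps.screen_specific([anchor], [comp])
        assert profile.specificity_class == SPECIFIC
        assert profile.min_distance["comp"] == 3

    def test_planted_island_recovered_as_ultra_specific(self):
        island = "TTTG" + "CAGTCGATTGACCTAGCATGC"
        spec = SynthSpec(seed=63, length=50_000, genome_id="focal",
                         plants=(Plant(island, position=25_000),), pair_identity=0.9)
        focal, partner = make_related_pair(spec)
        targets = [t for t in ps.enumerate_targets(focal) if t.start == 25_000 and t.strand == "+"]
        assert len(targets) == 1
        (profile,) = ps.screen_specific(targets, [partner])
        brute = ps.brute_force_offtargets(targets[0], partner, max_mm=5)
        assert brute == []
        assert profile.specificity_class == ULTRA_SPECIFIC

    def test_screen_histograms_match_single_queries(self, anchor):
        comp = make_genome(SynthSpec(seed=64, length=20_000, genome_id="c"))
        (profile,) = ps.screen_specific([anchor], [comp], exclude_self_site=False)
        assert profile.per_genome_hist["c"] == ps.mismatch_histogram(anchor, comp, max_mm=5)

    def test_cumulative_counts_non_decreasing(self, tiny_genome):
        targets = ps.enumerate_targets(tiny_genome)[:20]
        comp = make_genome(SynthSpec(seed=65, length=20_000, genome_id="c"))
        for p in ps.screen_specific(targets, [comp]):
            hist = p.per_genome_hist["c"]
            assert all(c >= 0 for c in hist)
            cum = np.cumsum(hist)
            assert (np.diff(cum) >= 0).all()
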