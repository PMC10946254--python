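import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pamscan as ps
from pamscan.genome_io import Contig, Genome, Region
from pamscan.synthetic_data import Plant, SynthSpec, make_genome

from _reference import naive_enumerate, revcomp


class TestEnumerate:
    def test_single_forward_site(self):
        g = Genome("g", [Contig("c1", "TTTG" + "A" * 21)])
        (t,) = ps.enumerate_targets(g)
        assert (t.strand, t.start, t.copy_number) == ("+", 0, 1)
        assert t.sequence == "TTTG" + "A" * 21
        assert t.pam == "TTTG" and t.protospacer == "A" * 21

    def test_poly_t_has_no_sites(self):
        # forward windows start TTTT (fails V); reverse complement is poly-A
        g = Genome("g", [Contig("c1", "T" * 30)])
        assert ps.enumerate_targets(g) == []

    def test_short_contig_contributes_nothing(self):
        g = Genome("g", [Contig("c1", "TTTG" + "A" * 21), Contig("c2", "TTTGAA")])
        assert len(ps.enumerate_targets(g)) == 1

    def test_k_below_minimum_errors(self, tiny_genome):
        with pytest.raises(ValueError):
            ps.enumerate_targets(tiny_genome, k=4)

    def test_n_window_skipped(self):
        g = Genome("g", [Contig("c1", "TTTG" + "A" * 10 + "N" + "A" * 10)])
        assert ps.enumerate_targets(g) == []

    def test_marker_sequences_recovered_verbatim(self, marker_table):
        # each published marker, embedded alone in an A/T-free background,
        # is found at its planted locus on the forward strand; one catalog
        # entry is 26 nt as printed, so recovery is over the 25-bp window
        for row in marker_table.itertuples(index=False):
            seq = row.target_sequence
            background = ("GC" * 300)[:500]
            contig = background + seq + background
            g = Genome(row.species, [Contig("c1", contig)])
            found = {
                (t.start, t.strand, t.sequence) for t in ps.enumerate_targets(g)
            }
            assert (500, "+", seq[:25]) in found

    def test_matches_naive_oracle_seeded(self):
        g = make_genome(SynthSpec(seed=42, length=10_000, genome_id="g"))
        contigs = [(c.name, c.sequence) for c in g.contigs]
        expected = sorted(naive_enumerate(contigs))
        got = sorted((t.contig_name, t.start, t.strand, t.sequence) for t in ps.enumerate_targets(g))
        assert got == expected

    def test_strand_symmetry(self, tiny_genome):
        k = 25
        fwd = ps.enumerate_targets(tiny_genome)
        rc_genome = Genome(
            "rc", [Contig(c.name, revcomp(c.sequence)) for c in tiny_genome.contigs]
        )
        rev = ps.enumerate_targets(rc_genome)
        L = len(tiny_genome.contigs[0].sequence)
        flipped = {(L - k - t.start, {"+": "-", "-": "+"}[t.strand], t.sequence) for t in rev}
        assert {(t.start, t.strand, t.sequence) for t in fwd} == flipped

    def test_copy_number_counts_planted_copies(self):
        site = "TTTC" + "GATTACAGATTACAGATTACA"
        plants = (
            Plant(site, position=100),
            Plant(site, position=400),
            Plant(site, position=800, strand="-"),
        )
        g = make_genome(SynthSpec(seed=5, length=2000, plants=plants))
        copies = [t.copy_number for t in ps.enumerate_targets(g) if t.sequence == site]
        assert len(copies) == 3 and set(copies) == {3}

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20), length=st.integers(25, 2000), gc=st.floats(0.2, 0.8))
    def test_property_agrees_with_naive_oracle(self, seed, length, gc):
        g = make_genome(SynthSpec(seed=seed, length=length, gc=gc, genome_id="g"))
        contigs = [(c.name, c.sequence) for c in g.contigs]
        expected = sorted(naive_enumerate(contigs))
        targets = ps.enumerate_targets(g)
        got = sorted((t.contig_name, t.start, t.strand, t.sequence) for t in targets)
        assert got == expected
        for t in targets:
            assert len(t.sequence) == 25
            assert t.sequence.startswith("TTT") and t.sequence[3] in "ACG"
            assert t.copy_number >= 1
            window = g.contigs[0].sequence[t.start : t.start + 25]
            assert t.sequence == (window if t.strand == "+" else revcomp(window))


class TestLibraryStats:
    def test_spacing_arithmetic(self):
        g = Genome("g", [Contig("c1", "A" * 1000)])
        targets = [
            ps.Target(f"t{i}", "g", "c1", i, "+", "TTTG" + "A" * 21) for i in range(10)
        ]
        stats = ps.library_stats(g, targets)
        assert stats.n_target_sites == 10
        assert stats.mean_spacing_bp == 100.0

    def test_zero_sites_gives_nan_not_error(self):
        g = Genome("g", [Contig("c1", "A" * 100)])
        stats = ps.library_stats(g, [])
        assert math.isnan(stats.mean_spacing_bp)

    def test_distinct_not_above_sites(self, tiny_genome):
        targets = ps.enumerate_targets(tiny_genome)
        stats = ps.library_stats(tiny_genome, targets)
        assert stats.n_distinct_sequences <= stats.n_target_sites == len(targets)

    def test_spacing_near_closed_form(self):
        # i.i.d. genome: site count ~ 2(L-24)p with p = qT^3 (1-qT)
        L = 200_000
        g = make_genome(SynthSpec(seed=7, length=L, gc=0.5, genome_id="g"))
        stats = ps.library_stats(g, ps.enumerate_targets(g))
        q_t = 0.25
        expected = L / (2 * (L - 24) * q_t**3 * (1 - q_t))
        assert abs(stats.mean_spacing_bp - expected) / expected < 0.15


class TestFilterByRegion:
    def _target(self, start):
        return ps.Target(f"t{start}", "g", "c1", start, "+", "TTTG" + "A" * 21)

    def test_exact_containment_kept(self):
        assert ps.filter_by_region([self._target(100)], [Region("c1", 100, 125)]) != []

    def test_partial_overlap_dropped(self):
        assert ps.filter_by_region([self._target(100)], [Region("c1", 101, 200)]) == []

    def test_planted_target_inside_region_selected(self):
        island = "TTTG" + "CAGTCGATTGACCTAGCATGC"
        plants = (Plant(island, position=1000), Plant(island, position=3000),
                  Plant(island, position=4000))
        g = make_genome(SynthSpec(seed=9, length=5000, plants=plants))
        targets = [t for t in ps.enumerate_targets(g) if t.sequence == island]
        assert len(targets) == 3
        kept = ps.filter_by_region(targets, [Region("chr1", 990, 1100, "ITS")])
        assert [t.start for t in kept] == [1000]


class TestExtractFlanks:
    def _genome_and_target(self, contig_len, start):
        seq = ("ACGT" * (contig_len // 4 + 1))[:contig_len]
        seq = seq[:start] + "TTTG" + "A" * 21 + seq[start + 25 :]
        g = Genome("g", [Contig("c1", seq)])
        t = ps.Target("t", "g", "c1", start, "+", "TTTG" + "A" * 21)
        return g, t

    def test_interior_window_unclipped(self):
        g, t = self._genome_and_target(2000, 600)
        amp = ps.extract_flanks(g, t, flank=500)
        assert (amp.start, amp.end, amp.clipped) == (100, 1125, False)
        assert len(amp.sequence) == 1025

    def test_edge_window_clipped(self):
        g, t = self._genome_and_target(2000, 10)
        amp = ps.extract_flanks(g, t, flank=500)
        assert (amp.start, amp.end, amp.clipped) == (0, 535, True)

    def test_zero_flank_is_window(self):
        g, t = self._genome_and_target(2000, 600)
        amp = ps.extract_flanks(g, t, flank=0)
        assert amp.sequence == t.sequence

    def test_foreign_target_rejected(self):
        g, t = self._genome_and_target(2000, 600)
        other = ps.Target("t", "other", "c1", 600, "+", t.sequence)
        with pytest.raises(ValueError, match="does not belong"):
            ps.extract_flanks(g, other)
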