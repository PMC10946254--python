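"""End-to-end validation experiments run entirely on synthetic fixtures.

Each function regenerates its inputs from a seed, runs the production
code path, measures the outcome against an independent check (the
brute-force window scan, planted ground truth, or a closed-form
expectation) and returns plain numbers. The test suite and the
reproduction script both call these; nothing here reads external data
beyond the packaged marker-target table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import load_marker_targets
from .crrna import design_crrna
from .genome_io import Contig, Genome
from .detection_sim import DetectionAssay, simulate_cas12a, simulate_panel
from .specificity import ULTRA_SPECIFIC, brute_force_offtargets, find_offtargets, screen_specific
from .synthetic_data import Plant, SynthSpec, make_decoy, make_genome, make_related_pair
from .target_library import Target, enumerate_targets, library_stats

ISLAND = "TTTG" + "CAGTCGATTGACCTAGCATGC"


def _subseed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


@dataclass(frozen=True)
class OracleCheck:
    n_instances: int
    n_agreeing: int

    @property
    def agreement_fraction(self) -> float:
        return self.n_agreeing / self.n_instances


def offtarget_oracle_check(
    seed: int, n_instances: int = 100, min_len: int = 2_000, max_len: int = 50_000
) -> OracleCheck:
    """Randomized equivalence of the indexed off-target search against the
    brute-force window scan: exact set equality of
    (contig, start, strand, mismatches) per instance."""
    rng = np.random.default_rng(seed)
    agree = 0
    done = 0
    while done < n_instances:
        L = int(rng.integers(min_len, max_len + 1))
        gc = float(rng.uniform(0.3, 0.7))
        focal = make_genome(SynthSpec(seed=_subseed(rng), length=L, gc=gc, genome_id="f"))
        targets = enumerate_targets(focal)
        if not targets:
            continue
        target = targets[int(rng.integers(len(targets)))]
        comp = make_genome(SynthSpec(seed=_subseed(rng), length=L, gc=gc, genome_id="c"))
        max_mm = int(rng.integers(0, 6))
        require_pam = bool(rng.integers(2))
        fast = find_offtargets(target, comp, max_mm=max_mm, require_pam=require_pam)
        brute = brute_force_offtargets(target, comp, max_mm=max_mm, require_pam=require_pam)
        if {h.key for h in fast} == {h.key for h in brute}:
            agree += 1
        done += 1
    return OracleCheck(n_instances=done, n_agreeing=agree)


@dataclass(frozen=True)
class IslandRecovery:
    n_seeds: int
    n_recovered: int
    n_ultra_calls: int
    n_false_ultra: int
    n_spot_checked_non_ultra: int
    n_missed_ultra: int

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_seeds


def island_recovery(
    seed: int,
    n_seeds: int = 20,
    length: int = 100_000,
    identity: float = 0.9,
    spot_check: int = 25,
) -> IslandRecovery:
    """Planted-truth screen on related genome pairs.

    Each replicate builds a pair at the given identity with one private
    target island in the focal copy, screens every focal target against
    the partner, and checks (a) the island is called ultra-specific,
    (b) every ultra-specific call is confirmed hit-free by the brute-force
    oracle, (c) a spot-checked sample of non-ultra calls really does have
    an oracle hit.
    """
    rng = np.random.default_rng(seed)
    recovered = 0
    n_ultra = n_false = n_spot = n_missed = 0
    for _ in range(n_seeds):
        rep_seed = _subseed(rng)
        pos = length // 2
        spec = SynthSpec(
            seed=rep_seed, length=length, genome_id="focal",
            plants=(Plant(ISLAND, position=pos),), pair_identity=identity,
        )
        focal, partner = make_related_pair(spec)
        targets = enumerate_targets(focal)
        profiles = screen_specific(targets, [partner])
        by_id = dict(zip((t.target_id for t in targets), profiles))

        island_id = f"focal|chr1|{pos}|+"
        if by_id.get(island_id) is not None and by_id[island_id].specificity_class == ULTRA_SPECIFIC:
            recovered += 1

        ultra = [t for t, p in zip(targets, profiles) if p.specificity_class == ULTRA_SPECIFIC]
        n_ultra += len(ultra)
        for t in ultra:
            if brute_force_offtargets(t, partner, max_mm=5):
                n_false += 1

        non_ultra = [t for t, p in zip(targets, profiles) if p.specificity_class != ULTRA_SPECIFIC]
        if non_ultra:
            picks = rng.choice(len(non_ultra), size=min(spot_check, len(non_ultra)), replace=False)
            for i in picks:
                n_spot += 1
                if not brute_force_offtargets(non_ultra[int(i)], partner, max_mm=5):
                    n_missed += 1
    return IslandRecovery(n_seeds, recovered, n_ultra, n_false, n_spot, n_missed)


@dataclass(frozen=True)
class DiscriminationResult:
    activated_at_0: bool
    best_mm_exact: int
    activated_at_3: bool
    best_mm_decoy: int
    panel_size: int
    panel_activated: int
    panel_positive_first: bool
    mixture_activated: bool


def _embed(seq: str, seed: int, length: int = 1_000, position: int = 400) -> str:
    g = make_genome(SynthSpec(seed=seed, length=length, plants=(Plant(seq, position=position),)))
    return g.contigs[0].sequence


def discrimination_truth_table(seed: int) -> DiscriminationResult:
    """The qualitative Cas12a discrimination logic on constructed
    amplicons: activation on the exact target, silence on a verified
    3-mismatch neighbour, a 13-substrate panel with exactly one positive,
    and a positive-in-negative mixture."""
    markers = load_marker_targets()
    gl_seq = markers.loc[
        markers["species"] == "Ganoderma lucidum", "target_sequence"
    ].item()
    target = Target("gl", "gl_genome", "c1", 0, "+", gl_seq)
    crrna = design_crrna(target)
    rng = np.random.default_rng(seed)

    exact = simulate_cas12a(DetectionAssay(crrna, _embed(gl_seq, _subseed(rng))))

    # a 3-mismatch, PAM-intact neighbour; re-draw until the background adds
    # no closer site (verified by the brute-force oracle)
    while True:
        decoy = make_decoy(target, 3, preserve_pam=True, seed=_subseed(rng))
        substrate = _embed(decoy, _subseed(rng))
        comp_genome = Genome("sub", [Contig("c1", substrate)])
        hits = brute_force_offtargets(target, comp_genome, max_mm=21)
        if min(h.mismatches for h in hits) == 3:
            break
    near = simulate_cas12a(DetectionAssay(crrna, substrate))

    substrates = [("species_00", _embed(gl_seq, _subseed(rng)))]
    for i in range(1, 13):
        neg = make_genome(SynthSpec(seed=_subseed(rng), length=1_000)).contigs[0].sequence
        substrates.append((f"species_{i:02d}", neg))
    panel = simulate_panel(crrna, substrates)

    mixture = substrates[1][1] + substrates[0][1]
    mixed = simulate_cas12a(DetectionAssay(crrna, mixture))

    return DiscriminationResult(
        activated_at_0=exact.activated,
        best_mm_exact=exact.best_hit.mismatches,
        activated_at_3=near.activated,
        best_mm_decoy=near.best_hit.mismatches,
        panel_size=len(panel),
        panel_activated=int(panel["activated"].sum()),
        panel_positive_first=bool(panel.loc[0, "activated"]),
        mixture_activated=mixed.activated,
    )


@dataclass(frozen=True)
class MarkerCheck:
    n_markers: int
    n_pam_pass: int
    gl_spacer: str
    gl_spacer_matches: bool


GL_EXPECTED_SPACER = "UAGGCUUGGACUUGGAGGCUU"


def marker_pattern_check() -> MarkerCheck:
    """PAM conformance of the packaged marker catalog and the derived
    G. lucidum spacer."""
    markers = load_marker_targets()
    n_pass = sum(
        seq.startswith("TTT") and seq[3] in "ACG" for seq in markers["target_sequence"]
    )
    gl_seq = markers.loc[markers["species"] == "Ganoderma lucidum", "target_sequence"].item()
    crrna = design_crrna(Target("gl", "g", "c1", 0, "+", gl_seq))
    return MarkerCheck(
        n_markers=len(markers),
        n_pam_pass=n_pass,
        gl_spacer=crrna.spacer_rna,
        gl_spacer_matches=crrna.spacer_rna == GL_EXPECTED_SPACER,
    )


@dataclass(frozen=True)
class SpacingCheck:
    length: int
    n_sites: int
    observed_spacing_bp: float
    expected_spacing_bp: float

    @property
    def relative_deviation(self) -> float:
        return abs(self.observed_spacing_bp - self.expected_spacing_bp) / self.expected_spacing_bp


def spacing_closed_form(seed: int, length: int = 200_000, gc: float = 0.5) -> SpacingCheck:
    """Mean target spacing on an i.i.d. genome against the closed form
    L / (2 (L-24) p), p = q_T^3 (1 - q_T)."""
    g = make_genome(SynthSpec(seed=seed, length=length, gc=gc, genome_id="iid"))
    stats = library_stats(g, enumerate_targets(g))
    q_t = (1 - gc) / 2
    p = q_t**3 * (1 - q_t)
    expected = length / (2 * (length - 24) * p)
    return SpacingCheck(length, stats.n_target_sites, stats.mean_spacing_bp, expected)
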