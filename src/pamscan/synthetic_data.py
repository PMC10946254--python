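"""Seeded synthetic genomes, planted targets/decoys and related-genome
pairs.

The generator emulates the study conditions every other module is tested
under: i.i.d. background sequence with controllable GC (no repeat families
or GC skew — see the repeats preset for a deliberate near-duplicate
stressor), target sites planted on either strand, decoy sites at exact
Hamming distances with intact or broken PAM, and pairs of closely related
genomes produced by independent per-base substitution at rate
1 - identity (substitution only: the screening world is Hamming, no
indels).

All randomness flows through ``numpy.random.default_rng`` seeded from the
spec, so fixtures are byte-identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import BASES, revcomp
from .genome_io import Contig, Genome
from .target_library import PAM_LENGTH, Target


@dataclass(frozen=True)
class Plant:
    """A sequence to write into the background at a fixed locus."""

    sequence: str
    contig: str = "chr1"
    position: int = 0
    strand: str = "+"

    @property
    def interval(self) -> tuple[int, int]:
        return (self.position, self.position + len(self.sequence))


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic genome (single contig)."""

    seed: int
    length: int
    gc: float = 0.5
    genome_id: str = "synth"
    contig_name: str = "chr1"
    plants: tuple[Plant, ...] = ()
    pair_identity: float | None = None

    def __post_init__(self) -> None:
        if self.length < 25:
            raise ValueError("length must be at least 25")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        ivals = sorted(p.interval for p in self.plants)
        for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
            if b0 < a1:
                raise ValueError(f"planted intervals overlap: [{a0},{a1}) and [{b0},{b1})")
        for p in self.plants:
            if p.position < 0 or p.position + len(p.sequence) > self.length:
                raise ValueError(f"plant at {p.position} does not fit in length {self.length}")


def _base_probs(gc: float) -> np.ndarray:
    # order A, C, G, T; GC split equally within GC, AT within AT
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def _draw_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    return rng.choice(4, size=n, p=_base_probs(gc)).astype(np.uint8)


def make_genome(spec: SynthSpec) -> Genome:
    """i.i.d. background at the requested GC with plants written in
    (reverse-complemented first for strand '-')."""
    rng = np.random.default_rng([spec.seed, 0])
    codes = _draw_codes(rng, spec.length, spec.gc)
    seq = list(_codes_to_str(codes))
    for p in spec.plants:
        planted = p.sequence if p.strand == "+" else revcomp(p.sequence)
        seq[p.position : p.position + len(planted)] = planted
    return Genome(spec.genome_id, [Contig(spec.contig_name, "".join(seq))])


def make_decoy(target: Target, n_mismatch: int, preserve_pam: bool = True, seed: int = 0) -> str:
    """A k-mer whose post-PAM segment sits at Hamming distance exactly
    ``n_mismatch`` from the target's protospacer. The PAM is kept intact
    when ``preserve_pam``, else forced to TTTT (fails the V position)."""
    proto = list(target.protospacer)
    if not 0 <= n_mismatch <= len(proto):
        raise ValueError(f"n_mismatch must be in [0, {len(proto)}]")
    rng = np.random.default_rng([seed, len(proto), n_mismatch])
    positions = rng.choice(len(proto), size=n_mismatch, replace=False)
    for pos in positions:
        alternatives = [b for b in BASES if b != proto[pos]]
        proto[pos] = alternatives[rng.integers(len(alternatives))]
    pam = target.pam if preserve_pam else "T" * PAM_LENGTH
    return pam + "".join(proto)


def make_related_pair(spec: SynthSpec, identity: float | None = None) -> tuple[Genome, Genome]:
    """A focal genome and a diverged partner at the given expected
    identity.

    The partner starts as the focal sequence with each background base
    independently substituted with probability 1 - identity (to a uniform
    different base). Planted intervals are masked from mutation in the
    focal copy and deleted outright from the partner, so each plant is a
    private island of the focal genome — ground truth for specificity
    screening.
    """
    identity = spec.pair_identity if identity is None else identity
    if identity is None or not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    focal = make_genome(spec)
    seq = focal.contigs[0].sequence
    L = len(seq)

    planted_mask = np.zeros(L, dtype=bool)
    for p in spec.plants:
        planted_mask[p.position : p.position + len(p.sequence)] = True

    rng = np.random.default_rng([spec.seed, 1])
    mutate = (rng.random(L) < (1 - identity)) & ~planted_mask
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    code_of = {ord(b): i for i, b in enumerate(BASES)}
    lookup = np.zeros(256, dtype=np.uint8)
    for byte, i in code_of.items():
        lookup[byte] = i
    base_codes = lookup[codes]
    shifts = rng.integers(1, 4, size=L)
    new_codes = (base_codes + shifts) % 4
    out = codes.copy()
    idx = np.flatnonzero(mutate)
    base_bytes = np.frombuffer(BASES.encode(), dtype=np.uint8)
    out[idx] = base_bytes[new_codes[idx]]
    partner_seq = out.tobytes().decode()

    partner_seq = "".join(ch for ch, planted in zip(partner_seq, planted_mask) if not planted)
    partner = Genome(
        f"{spec.genome_id}_rel",
        [Contig(spec.contig_name, partner_seq)],
    )
    focal = Genome(spec.genome_id, focal.contigs)
    return focal, partner


# ---------------------------------------------------------------------------
# presets: ready-made fixture bundles with truth tables


@dataclass(frozen=True)
class Preset:
    """A named fixture bundle: genomes plus a truth table describing what
    was planted where (used by tests and written next to CLI output)."""

    name: str
    genomes: tuple[Genome, ...]
    truth: pd.DataFrame


_TRUTH_COLS = ["genome_id", "contig", "position", "strand", "sequence", "kind", "distance"]


def _truth(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=_TRUTH_COLS)


def preset_basic(seed: int, length: int = 20_000, gc: float = 0.5) -> Preset:
    """One genome with a single planted forward-strand target."""
    plant = Plant("TTTG" + "ACGTC" * 4 + "A", position=length // 2)
    spec = SynthSpec(seed=seed, length=length, gc=gc, genome_id="basic", plants=(plant,))
    genome = make_genome(spec)
    rows = [
        {"genome_id": "basic", "contig": plant.contig, "position": plant.position,
         "strand": "+", "sequence": plant.sequence, "kind": "target", "distance": 0}
    ]
    return Preset("basic", (genome,), _truth(rows))


def preset_decoys(seed: int, length: int = 50_000, gc: float = 0.5) -> Preset:
    """A focal genome with one planted target, and a decoy genome carrying
    sites at every distance 0..5 plus one PAM-broken distance-2 decoy."""
    target_seq = "TTTC" + "GATTACAGATTACAGATTACA"
    focal_plant = Plant(target_seq, position=1000)
    focal = make_genome(
        SynthSpec(seed=seed, length=length, gc=gc, genome_id="decoy_focal", plants=(focal_plant,))
    )
    anchor = Target(
        target_id="planted", genome_id="decoy_focal", contig_name="chr1",
        start=1000, strand="+", sequence=target_seq,
    )
    rows = [
        {"genome_id": "decoy_focal", "contig": "chr1", "position": 1000, "strand": "+",
         "sequence": target_seq, "kind": "target", "distance": 0}
    ]
    plants = []
    pos = 2000
    for d in range(6):
        strand = "+" if d % 2 == 0 else "-"
        decoy = make_decoy(anchor, d, preserve_pam=True, seed=seed * 100 + d)
        plants.append(Plant(decoy, position=pos, strand=strand))
        rows.append(
            {"genome_id": "decoy_comp", "contig": "chr1", "position": pos, "strand": strand,
             "sequence": decoy, "kind": "decoy_pam_intact", "distance": d}
        )
        pos += 200
    broken = make_decoy(anchor, 2, preserve_pam=False, seed=seed * 100 + 42)
    plants.append(Plant(broken, position=pos))
    rows.append(
        {"genome_id": "decoy_comp", "contig": "chr1", "position": pos, "strand": "+",
         "sequence": broken, "kind": "decoy_pam_broken", "distance": 2}
    )
    comp = make_genome(
        SynthSpec(seed=seed + 1, length=length, gc=gc, genome_id="decoy_comp", plants=tuple(plants))
    )
    return Preset("decoys", (focal, comp), _truth(rows))


def preset_related_pair(
    seed: int, length: int = 100_000, identity: float = 0.9, gc: float = 0.5
) -> Preset:
    """A pair of closely related genomes with one private target island in
    the focal copy (absent from the partner)."""
    island = "TTTG" + "CAGTCGATTGACCTAGCATGC"
    plant = Plant(island, position=length // 2)
    spec = SynthSpec(
        seed=seed, length=length, gc=gc, genome_id="focal", plants=(plant,), pair_identity=identity
    )
    focal, partner = make_related_pair(spec)
    rows = [
        {"genome_id": "focal", "contig": "chr1", "position": plant.position, "strand": "+",
         "sequence": island, "kind": "unique_island", "distance": 0}
    ]
    return Preset("related-pair", (focal, partner), _truth(rows))


def preset_repeats(seed: int, unit: int = 2_000, copies: int = 8, gc: float = 0.5) -> Preset:
    """A genome built from tandem near-duplicate blocks (each copy lightly
    mutated), stressing the candidate index with many close off-targets."""
    rng = np.random.default_rng([seed, 7])
    unit_codes = _draw_codes(rng, unit, gc)
    blocks = []
    for _ in range(copies):
        b = unit_codes.copy()
        nmut = rng.integers(5, 15)
        pos = rng.choice(unit, size=nmut, replace=False)
        b[pos] = (b[pos] + rng.integers(1, 4, size=nmut)) % 4
        blocks.append(b)
    seq = _codes_to_str(np.concatenate(blocks))
    genome = Genome("repeats", [Contig("chr1", seq)])
    return Preset("repeats", (genome,), _truth([]))


PRESETS = {
    "basic": preset_basic,
    "decoys": preset_decoys,
    "related-pair": preset_related_pair,
    "repeats": preset_repeats,
}
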