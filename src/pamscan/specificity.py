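"""Mismatch-tolerant, PAM-anchored search of targets against comparator
genomes, per-genome mismatch histograms and specificity classification.

Distances are Hamming distances over the protospacer only (the k-4 bases
after the PAM); candidate sites must themselves carry an intact PAM unless
``require_pam=False``, in which case every window is compared over its
post-PAM segment whatever its first four bases are. Sites containing N
never match at any distance.

Two search paths with one contract:

* :func:`find_offtargets` — the production path. Candidate sites are
  collected once per comparator genome (PAM-anchored windows on both
  strands, gathered into a code matrix) and each query reduces to one
  vectorized row-wise mismatch count against that matrix.
* :func:`brute_force_offtargets` — the oracle: a plain scan of every
  window with positionwise comparison, organised completely differently
  (per-offset sweeps over the whole sequence). Used by tests; capped at
  1 Mb to keep misuse obvious.

The two must agree exactly — set equality of (contig, start, strand,
mismatches) — and the test suite enforces this on randomized instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, find_pam_sites, pam_match_tables, revcomp, window_has_n
from .genome_io import Genome
from .target_library import PAM_LENGTH, Target

DEFAULT_MAX_MM = 5
DEFAULT_SPECIFIC_MIN_DISTANCE = 3

SPECIFIC = "specific"
ULTRA_SPECIFIC = "ultra_specific"
NON_SPECIFIC = "non_specific"


@dataclass(frozen=True)
class OffTargetHit:
    """A PAM-bearing site within a bounded Hamming distance of a target's
    protospacer. ``start`` is the leftmost forward-strand coordinate of the
    k-bp window; ``site_sequence`` is strand-oriented (PAM first)."""

    target_id: str
    comparator_genome_id: str
    contig_name: str
    start: int
    strand: str
    site_sequence: str
    mismatches: int

    @property
    def key(self) -> tuple[str, int, str, int]:
        return (self.contig_name, self.start, self.strand, self.mismatches)


@dataclass
class SpecificityProfile:
    """Per-comparator mismatch histograms and the derived verdict for one
    target.

    ``min_distance[g]`` is the smallest distance with a nonzero count in
    genome ``g``, or None when no site lies within ``max_mm``.
    ``specificity_class`` is ``ultra_specific`` when no comparator has any
    hit at all, ``specific`` when every comparator's nearest site is at
    least ``specific_min_distance`` away, else ``non_specific``.
    """

    target_id: str
    per_genome_hist: dict[str, list[int]]
    min_distance: dict[str, int | None] = field(default_factory=dict)
    specificity_class: str = NON_SPECIFIC

    def __post_init__(self) -> None:
        if not self.min_distance:
            self.min_distance = {
                g: next((d for d, c in enumerate(h) if c > 0), None)
                for g, h in self.per_genome_hist.items()
            }


class _StrandBlock:
    """Candidate sites on one strand of one contig: forward-coordinate
    starts, the oriented sequence to slice site sequences from, and the
    encoded post-PAM segment matrix."""

    __slots__ = ("contig_name", "strand", "starts", "oriented", "seg", "contig_len", "k")

    def __init__(self, contig_name: str, strand: str, starts: np.ndarray,
                 oriented: str, oriented_positions: np.ndarray, k: int):
        self.contig_name = contig_name
        self.strand = strand
        self.starts = starts
        self.oriented = oriented
        self.contig_len = len(oriented)
        self.k = k
        enc = encode(oriented)
        if len(starts):
            idx = oriented_positions[:, None] + np.arange(PAM_LENGTH, k)[None, :]
            self.seg = enc[idx]
        else:
            self.seg = np.zeros((0, k - PAM_LENGTH), dtype=np.uint8)

    def site_sequence(self, row: int) -> str:
        if self.strand == "+":
            p = int(self.starts[row])
        else:
            p = self.contig_len - self.k - int(self.starts[row])
        return self.oriented[p : p + self.k]


class GenomeIndex:
    """Candidate-site index of one comparator genome for a fixed (k, PAM).

    Holds PAM-anchored site blocks eagerly and all-window blocks (for
    ``require_pam=False`` queries) lazily.
    """

    def __init__(self, genome: Genome, k: int = 25, pam: str = "TTTV"):
        self.genome = genome
        self.k = k
        self.pam = pam
        tables = pam_match_tables(pam)
        self.blocks: list[_StrandBlock] = []
        self._site_lookup: dict[tuple[str, int, str], tuple[int, int]] = {}
        for contig in genome.contigs:
            fwd = contig.sequence
            if len(fwd) < k:
                continue
            L = len(fwd)
            enc_f = encode(fwd)
            pos_f = find_pam_sites(enc_f, k, tables)
            self.blocks.append(_StrandBlock(contig.name, "+", pos_f, fwd, pos_f, k))
            rc = revcomp(fwd)
            pos_r = find_pam_sites(encode(rc), k, tables)
            starts_r = (L - k - pos_r).astype(np.int64)
            self.blocks.append(_StrandBlock(contig.name, "-", starts_r, rc, pos_r, k))
        for bi, block in enumerate(self.blocks):
            for row, start in enumerate(block.starts):
                self._site_lookup[(block.contig_name, int(start), block.strand)] = (bi, row)
        self._all_blocks: list[_StrandBlock] | None = None

    @property
    def all_window_blocks(self) -> list[_StrandBlock]:
        """Blocks covering every N-free window regardless of PAM."""
        if self._all_blocks is None:
            blocks = []
            for contig in self.genome.contigs:
                fwd = contig.sequence
                if len(fwd) < self.k:
                    continue
                L = len(fwd)
                enc_f = encode(fwd)
                pos_f = np.flatnonzero(~window_has_n(enc_f, self.k)).astype(np.int64)
                blocks.append(_StrandBlock(contig.name, "+", pos_f, fwd, pos_f, self.k))
                rc = revcomp(fwd)
                pos_r = np.flatnonzero(~window_has_n(encode(rc), self.k)).astype(np.int64)
                starts_r = (L - self.k - pos_r).astype(np.int64)
                blocks.append(_StrandBlock(contig.name, "-", starts_r, rc, pos_r, self.k))
            self._all_blocks = blocks
        return self._all_blocks

    def locate(self, contig_name: str, start: int, strand: str) -> tuple[int, int] | None:
        """(block, row) of a PAM-anchored site by coordinates, if indexed."""
        return self._site_lookup.get((contig_name, start, strand))


def _query_blocks(index: GenomeIndex, require_pam: bool) -> list[_StrandBlock]:
    return index.blocks if require_pam else index.all_window_blocks


def _proto_codes(target: Target, k: int) -> np.ndarray:
    if len(target.sequence) != k:
        raise ValueError(
            f"target {target.target_id!r} has k={len(target.sequence)}, index was built for k={k}"
        )
    proto = encode(target.protospacer)
    if (proto == 4).any():
        raise ValueError(f"target {target.target_id!r} protospacer contains N")
    return proto


def find_offtargets(
    target: Target,
    comparator: Genome,
    max_mm: int = DEFAULT_MAX_MM,
    require_pam: bool = True,
    pam: str = "TTTV",
    index: GenomeIndex | None = None,
) -> list[OffTargetHit]:
    """All sites in ``comparator`` (both strands) within ``max_mm``
    protospacer mismatches of ``target``, PAM-matched unless disabled.

    Pass a prebuilt :class:`GenomeIndex` to amortize the per-genome scan
    over many targets. Hits are sorted by (contig order, start, strand).
    """
    k = len(target.sequence)
    if not 0 <= max_mm <= k - PAM_LENGTH:
        raise ValueError(f"max_mm must be in [0, {k - PAM_LENGTH}]")
    if index is None:
        index = GenomeIndex(comparator, k=k, pam=pam)
    proto = _proto_codes(target, index.k)

    per_contig: dict[str, list[OffTargetHit]] = {}
    for block in _query_blocks(index, require_pam):
        if not len(block.starts):
            continue
        mm = np.count_nonzero(block.seg != proto, axis=1)
        for row in np.flatnonzero(mm <= max_mm):
            hit = OffTargetHit(
                target_id=target.target_id,
                comparator_genome_id=comparator.genome_id,
                contig_name=block.contig_name,
                start=int(block.starts[row]),
                strand=block.strand,
                site_sequence=block.site_sequence(int(row)),
                mismatches=int(mm[row]),
            )
            per_contig.setdefault(block.contig_name, []).append(hit)

    hits: list[OffTargetHit] = []
    contig_order = [c.name for c in comparator.contigs]
    for name in contig_order:
        group = per_contig.get(name, [])
        group.sort(key=lambda h: (h.start, h.strand, h.mismatches))
        hits.extend(group)
    return hits


def brute_force_offtargets(
    target: Target,
    comparator: Genome,
    max_mm: int = DEFAULT_MAX_MM,
    require_pam: bool = True,
    pam: str = "TTTV",
    cap: int = 1_000_000,
) -> list[OffTargetHit]:
    """Oracle with the same contract as :func:`find_offtargets`: a plain
    scan of every window with positionwise comparison, no candidate
    indexing. Refuses genomes above ``cap`` bp."""
    if comparator.total_length > cap:
        raise ValueError(f"comparator exceeds brute-force cap of {cap} bp")
    k = len(target.sequence)
    if not 0 <= max_mm <= k - PAM_LENGTH:
        raise ValueError(f"max_mm must be in [0, {k - PAM_LENGTH}]")
    proto = _proto_codes(target, k)
    tables = pam_match_tables(pam)

    hits: list[OffTargetHit] = []
    for contig in comparator.contigs:
        fwd = contig.sequence
        if len(fwd) < k:
            continue
        L = len(fwd)
        found: list[tuple[int, int, int, str]] = []  # (start, strand_key, mm, oriented)
        for strand_key, oriented in ((0, fwd), (1, revcomp(fwd))):
            enc = encode(oriented)
            n = L - k + 1
            mm = np.zeros(n, dtype=np.int32)
            for j in range(PAM_LENGTH, k):
                mm += enc[j : j + n] != proto[j - PAM_LENGTH]
            ok = mm <= max_mm
            if require_pam:
                for j, table in enumerate(tables):
                    ok &= table[enc[j : j + n]]
            ok &= ~window_has_n(enc, k)
            for p in np.flatnonzero(ok):
                start = int(p) if strand_key == 0 else L - k - int(p)
                found.append((start, strand_key, int(mm[p]), oriented[p : p + k]))
        found.sort()
        for start, strand_key, d, site_seq in found:
            hits.append(
                OffTargetHit(
                    target_id=target.target_id,
                    comparator_genome_id=comparator.genome_id,
                    contig_name=contig.name,
                    start=start,
                    strand="+" if strand_key == 0 else "-",
                    site_sequence=site_seq,
                    mismatches=d,
                )
            )
    return hits


def mismatch_histogram(
    target: Target,
    comparator: Genome,
    max_mm: int = DEFAULT_MAX_MM,
    exclude_self_site: bool = False,
    require_pam: bool = True,
    index: GenomeIndex | None = None,
) -> list[int]:
    """Counts of hits at exactly distance 0..max_mm.

    With ``exclude_self_site`` and the comparator being the target's own
    genome, the target's own locus (identified by coordinates, so exact
    duplicate copies elsewhere still count) is removed from its bin.
    """
    hits = find_offtargets(target, comparator, max_mm=max_mm, require_pam=require_pam, index=index)
    hist = [0] * (max_mm + 1)
    self_key = (target.contig_name, target.start, target.strand)
    excluding = exclude_self_site and comparator.genome_id == target.genome_id
    for h in hits:
        if excluding and (h.contig_name, h.start, h.strand) == self_key:
            continue
        hist[h.mismatches] += 1
    return hist


def _classify(min_distances: dict[str, int | None], specific_min_distance: int) -> str:
    if all(d is None for d in min_distances.values()):
        return ULTRA_SPECIFIC
    if all(d is None or d >= specific_min_distance for d in min_distances.values()):
        return SPECIFIC
    return NON_SPECIFIC


def screen_specific(
    targets: list[Target],
    comparators: list[Genome],
    max_mm: int = DEFAULT_MAX_MM,
    specific_min_distance: int = DEFAULT_SPECIFIC_MIN_DISTANCE,
    require_pam: bool = True,
    exclude_self_site: bool = True,
    pam: str = "TTTV",
    indexes: dict[str, GenomeIndex] | None = None,
) -> list[SpecificityProfile]:
    """Screen a target library against comparator genomes.

    For each target a per-comparator mismatch histogram is built and the
    target classified: ``ultra_specific`` (no comparator hit within
    ``max_mm`` at all), ``specific`` (every comparator's nearest site is
    at least ``specific_min_distance`` away) or ``non_specific``. If a
    comparator is the target's own genome and ``exclude_self_site`` is
    set, the target's own locus is discounted.
    """
    if not comparators:
        raise ValueError("no comparators")
    if not 0 <= specific_min_distance <= max_mm + 1:
        raise ValueError("specific_min_distance must be in [0, max_mm + 1]")
    if not targets:
        return []
    k = len(targets[0].sequence)

    if indexes is None:
        indexes = {}
    for g in comparators:
        if g.genome_id not in indexes:
            indexes[g.genome_id] = GenomeIndex(g, k=k, pam=pam)

    profiles = []
    for t in targets:
        proto = _proto_codes(t, k)
        hists: dict[str, list[int]] = {}
        for g in comparators:
            idx = indexes[g.genome_id]
            hist = np.zeros(max_mm + 1, dtype=np.int64)
            excluding = exclude_self_site and g.genome_id == t.genome_id
            # the self locus is only discountable if it is an indexed candidate
            self_loc = idx.locate(t.contig_name, t.start, t.strand) if excluding else None
            for bi, block in enumerate(_query_blocks(idx, require_pam)):
                if not len(block.starts):
                    continue
                mm = np.count_nonzero(block.seg != proto, axis=1)
                close = mm[mm <= max_mm]
                if len(close):
                    hist += np.bincount(close, minlength=max_mm + 1)
                if self_loc is not None and require_pam and self_loc[0] == bi:
                    d = int(mm[self_loc[1]])
                    if d <= max_mm:
                        hist[d] -= 1
            if self_loc is not None and not require_pam:
                # in all-window mode the self window is at distance 0 by the
                # Target invariant (its slice equals its own sequence)
                hist[0] -= 1
            hists[g.genome_id] = [int(c) for c in hist]
        profile = SpecificityProfile(t.target_id, hists)
        profile.specificity_class = _classify(profile.min_distance, specific_min_distance)
        profiles.append(profile)
    return profiles
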