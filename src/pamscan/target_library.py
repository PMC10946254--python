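"""Genome-wide enumeration of PAM-anchored candidate targets.

A *target* is a k-mer (default k=25) whose first four bases match the
Cas12a PAM (default TTTV, V = A/C/G). Both strands are scanned: a
reverse-strand target at forward coordinate ``start`` is the reverse
complement of the forward slice ``[start, start+k)``. All overlapping
windows are kept — enumeration slides one base at a time — and the
per-sequence copy number counts exact occurrences of the full k-mer over
both strands of the source genome.

Windows containing N are skipped: a mismatch count against N is undefined.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from ._seq import encode, find_pam_sites, pam_match_tables, revcomp
from .genome_io import Genome, Region, intersect_check

DEFAULT_K = 25
DEFAULT_PAM = "TTTV"
PAM_LENGTH = 4


@dataclass
class Target:
    """One PAM-anchored candidate site.

    ``start`` is the leftmost forward-strand coordinate of the k-bp window
    regardless of strand; ``sequence`` is the strand-oriented k-mer (PAM
    first). ``pam`` and ``protospacer`` are derived slices; ``copy_number``
    counts occurrences of ``sequence`` in the source genome on both strands
    (at least 1: the site itself).
    """

    target_id: str
    genome_id: str
    contig_name: str
    start: int
    strand: str
    sequence: str
    copy_number: int = 1
    pam: str = field(init=False)
    protospacer: str = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.pam = self.sequence[:PAM_LENGTH]
        self.protospacer = self.sequence[PAM_LENGTH:]

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass(frozen=True)
class LibraryStats:
    """Summary of an enumerated target library.

    ``n_target_sites`` counts positions (occurrences on both strands), not
    distinct sequences; ``mean_spacing_bp`` is genome length divided by the
    site count — the 'one target per X bp' density figure — and is NaN for
    an empty library.
    """

    genome_id: str
    n_target_sites: int
    n_distinct_sequences: int
    mean_spacing_bp: float


@dataclass(frozen=True)
class Amplicon:
    """A target window plus flanking genomic context on the forward strand."""

    target_id: str
    contig_name: str
    start: int
    end: int
    sequence: str
    clipped: bool


def enumerate_targets(genome: Genome, k: int = DEFAULT_K, pam: str = DEFAULT_PAM) -> list[Target]:
    """Enumerate every PAM-anchored, N-free k-window on both strands.

    Returns targets sorted by (contig order, start, strand; '+' first) with
    copy numbers filled in. Contigs shorter than k contribute nothing.
    """
    if k < 5:
        raise ValueError(f"k must be at least 5, got {k}")
    if k < len(pam) + 1:
        raise ValueError(f"k={k} leaves no protospacer after a {len(pam)}-bp PAM")
    tables = pam_match_tables(pam)

    raw: list[tuple[int, int, int, str]] = []  # (contig_idx, start, strand_key, sequence)
    for ci, contig in enumerate(genome.contigs):
        fwd = contig.sequence
        if len(fwd) < k:
            continue
        enc_f = encode(fwd)
        for p in find_pam_sites(enc_f, k, tables):
            raw.append((ci, int(p), 0, fwd[p : p + k]))
        rc = revcomp(fwd)
        enc_r = encode(rc)
        L = len(fwd)
        for p in find_pam_sites(enc_r, k, tables):
            raw.append((ci, L - k - int(p), 1, rc[p : p + k]))

    raw.sort(key=lambda r: (r[0], r[1], r[2]))
    counts = Counter(seq for _, _, _, seq in raw)

    targets = []
    for ci, start, sk, seq in raw:
        strand = "+" if sk == 0 else "-"
        contig_name = genome.contigs[ci].name
        targets.append(
            Target(
                target_id=f"{genome.genome_id}|{contig_name}|{start}|{strand}",
                genome_id=genome.genome_id,
                contig_name=contig_name,
                start=start,
                strand=strand,
                sequence=seq,
                copy_number=counts[seq],
            )
        )
    return targets


def library_stats(genome: Genome, targets: list[Target]) -> LibraryStats:
    """Site count, distinct-sequence count and mean spacing for a library."""
    n = len(targets)
    distinct = len({t.sequence for t in targets})
    spacing = genome.total_length / n if n else math.nan
    return LibraryStats(genome.genome_id, n, distinct, spacing)


def filter_by_region(targets: list[Target], regions: list[Region], genome: Genome | None = None) -> list[Target]:
    """Keep targets whose full window is contained in at least one region.

    Partial overlap is not enough: the screened unit is the whole k-mer.
    Regions naming unknown contigs are dropped with a warning when a genome
    is supplied for validation.
    """
    if genome is not None:
        regions = intersect_check(regions, genome)
    kept = []
    for t in targets:
        for r in regions:
            if r.contig_name == t.contig_name and r.start <= t.start and t.end <= r.end:
                kept.append(t)
                break
    return kept


def extract_flanks(genome: Genome, target: Target, flank: int = 500) -> Amplicon:
    """Forward-strand slice of the target window plus up to ``flank`` bp on
    each side — the amplicon context used for primer design. ``clipped`` is
    set when a contig edge truncated either flank."""
    if target.genome_id != genome.genome_id or target.contig_name not in genome:
        raise ValueError(f"target {target.target_id!r} does not belong to genome {genome.genome_id!r}")
    if flank < 0:
        raise ValueError("flank must be non-negative")
    contig = genome.contig(target.contig_name)
    lo = max(0, target.start - flank)
    hi = min(len(contig), target.end + flank)
    clipped = lo != target.start - flank or hi != target.end + flank
    return Amplicon(target.target_id, contig.name, lo, hi, contig.sequence[lo:hi], clipped)
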