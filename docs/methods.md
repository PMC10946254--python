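# Methods

## Model and procedure

The package treats diagnostic target discovery as an exact combinatorial
problem over strings. A candidate **target** is any k-bp window (default
k = 25; configurable 23–27) on either strand of the focal genome whose
first four bases match the Cas12a PAM `TTTV` (IUPAC patterns are accepted,
`TTTV` is the default). The window decomposes into the 4-bp PAM and the
(k−4)-nt **protospacer**; the crRNA spacer is the protospacer's RNA
transcript. **Specificity** of a target against a comparator genome is the
minimum Hamming distance between its protospacer and the post-PAM segment
of any PAM-intact window on either comparator strand, searched within a
budget `max_mm` (default 5). Classification thresholds are biological:
sites at distance ≥ 3 from a guide do not activate Cas12a in the
validating experiments, so `specific_min_distance` defaults to 3;
`ultra_specific` encodes the stricter condition that nothing lies within
the 5-mismatch search budget at all. Detection is modelled as a binary
verdict: Cas12a activates iff some PAM-matched substrate site is within
`activation_max_mm` mismatches of the spacer.

Assumptions worth stating plainly:

* **Mismatches only.** Distances are Hamming; bulge/indel off-targets are
  outside the model, consistent with a fixed-length window search.
* **PAM-required candidates.** Off-target sites must carry an intact TTTV
  PAM (the convention of PAM-anchored off-target searchers). The
  alternative reading — compare every window regardless of PAM — is
  exposed as `require_pam=False` (CLI `--mm-over-25`) for sensitivity
  analysis, and provably only adds hits.
* **Both strands, all overlaps.** Site counts are positional: overlapping
  windows each count, and density statistics divide genome length by the
  positional count. Distinct-sequence counts are reported separately. The
  published per-species spacing figures are only consistent with a
  two-strand scan, which is therefore the fixed behavior, not an option.
* **N handling.** Any window containing N is excluded from enumeration and
  from off-target candidacy at every distance; mismatch counts against N
  are undefined. Ambiguity codes other than N are rejected at input unless
  the caller opts into mapping them to N.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 25 bp | window length; protospacer = k − 4 |
| `pam` | `TTTV` | Cas12a PAM, IUPAC pattern, anchored at window start |
| `max_mm` | 5 | Hamming search budget against comparators |
| `specific_min_distance` | 3 | minimum cross-genome distance for `specific` |
| `activation_max_mm` | 2 | detection threshold (see below) |
| `flank` | 500 bp | amplicon context extracted around a target |

`activation_max_mm = 2` is an extrapolation bracketed by experiment:
activation is demonstrated at 0 mismatches and ruled out at 3, behavior at
1–2 being unobserved. Two is the largest threshold consistent with both
observations; it is configurable and the detection module's monotonicity
in the threshold is a tested invariant.

## Algorithms and numerical choices

The production off-target search builds, once per comparator genome, an
index of PAM-anchored candidate windows per contig and strand (positions
plus a base-code matrix of post-PAM segments); each query is then a
vectorized row-wise mismatch count with hits at `mm ≤ max_mm`. The oracle,
`brute_force_offtargets`, is a plain scan of every window with
positionwise comparison organised as per-offset sweeps, sharing no
traversal logic with the indexed path, and is capped at 1 Mb. The two are
required to agree exactly — set equality of (contig, start, strand,
mismatches) — and the suite enforces this on randomized instances; a
third, pure-Python naive scanner in the test tree cross-checks the oracle
itself at small sizes. Hit order is deterministic (contig order, start,
strand) so reports are byte-identical across runs; data files never embed
timestamps.

Self-site handling: when a target is screened against its own genome, its
own locus is identified by coordinates (not sequence) so exact duplicate
copies elsewhere still count; exclusion of the self site defaults on in
screening. Copy numbers count exact k-mer occurrences over both strands;
because k is odd, no window equals its own reverse complement and no
palindrome double-count correction is needed. Degenerate inputs behave
conservatively: contigs shorter than k contribute nothing, an empty target
library yields NaN spacing rather than an error, substrates shorter than k
are trivially non-activating.

## Synthetic data: what it emulates and what it does not

`synthetic_data` generates i.i.d. background sequence at a requested GC
(GC split equally between G and C, AT between A and T), plants sequences
at fixed loci on either strand, builds decoys at exact Hamming distances
with intact or deliberately broken (TTTT) PAMs, and derives related-genome
pairs by independent per-base substitution at rate 1 − identity — a
substitution-only model matching the Hamming world of the screen. Planted
islands are masked from mutation in the focal copy and deleted from the
partner, giving exact ground truth for specificity calls. All randomness
comes from seeded `numpy` PCG64 generators; fixtures are byte-stable
across platforms.

Real genomes are not i.i.d.: repeat families, GC skew, and rDNA arrays
produce clustered near-duplicate sites that this background lacks. A
`repeats` preset (tandem near-duplicate blocks) deliberately stresses the
index with many close off-targets, but passing tests demonstrate
correctness of the search and classification machinery, not that any
particular real genome contains usable markers. Genome-scale published
counts (hundreds of thousands of sites per fungal genome, cross-species
specific-target tallies) require the pinned assemblies themselves and are
out of desk-scale scope; the package computes them when pointed at the
FASTA files.

## Validation problem sizes

The packaged validation experiments (shared by the test suite and
`scripts/acceptance.py`) use: 100 randomized oracle-equivalence instances
on genomes of 2–50 kb across `max_mm` 0–5 with the PAM requirement on and
off; 20 related-pair replicates at 100 kb and 90% identity with every
ultra-specific call re-checked by the oracle and 25 non-ultra calls per
replicate spot-checked; a 13-amplicon discrimination panel; and a 200-kb
genome for the density closed form L / (2(L−24)·q_T³(1−q_T)), where the
observed mean spacing must sit within 15% (sampling noise at that length
is well under 5%).

## Known limitations

* No bulge/indel off-target model, no activity scoring (CFD/MIT-style),
  and no fluorescence-kinetics model — the detection verdict is binary.
* crRNA derivation emits no scaffold/repeat sequence; callers who know
  their ortholog's repeat can prepend it. Composition flags never filter.
* The amplification step is modelled only as flank extraction; primer
  design and chemistry are out of scope.
* Brute-force search is intentionally capped; the indexed path has no cap
  but holds per-genome candidate matrices in memory (~21 bytes per
  PAM site, plus the all-window matrix only when `require_pam=False`).
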