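"""Qualitative in-silico model of Cas12a target recognition.

Given a crRNA and a double-stranded DNA substrate (forward strand
supplied; both strands are scanned), the model predicts a binary
activation verdict: Cas12a activates — and its collateral ssDNA cleavage
would produce fluorescence — when some PAM-matched site in the substrate
lies within ``activation_max_mm`` protospacer mismatches of the spacer.

The default threshold of 2 mismatches is an extrapolation bracketed by
experiment: activation is demonstrated at 0 mismatches and ruled out at 3,
while behavior at 1-2 is unobserved; 2 is the largest threshold consistent
with both observations and is configurable. No fluorescence-intensity
model is attempted: kinetics are instrument- and chemistry-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .crrna import CrRNA
from .genome_io import Contig, Genome
from .specificity import find_offtargets
from .target_library import PAM_LENGTH, Target

DEFAULT_ACTIVATION_MAX_MM = 2

_SUBSTRATE_CONTIG = "substrate"


@dataclass
class DetectionAssay:
    """One crRNA against one dsDNA substrate."""

    crrna: CrRNA
    substrate: str
    activation_max_mm: int = DEFAULT_ACTIVATION_MAX_MM
    require_pam: bool = True
    pam: str = "TTTV"

    def __post_init__(self) -> None:
        if not 0 <= self.activation_max_mm <= len(self.crrna.spacer_dna):
            raise ValueError("activation_max_mm out of range")


@dataclass(frozen=True)
class BestHit:
    position: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class DetectionResult:
    activated: bool
    best_hit: BestHit | None
    rationale: str


def simulate_cas12a(assay: DetectionAssay) -> DetectionResult:
    """Scan both strands of the substrate for PAM-matched sites and apply
    the activation threshold to the minimum-mismatch site (ties broken by
    leftmost forward-strand coordinate, '+' before '-')."""
    spacer = assay.crrna.spacer_dna
    k = len(spacer) + PAM_LENGTH
    substrate = assay.substrate.upper()
    if len(substrate) < k:
        return DetectionResult(False, None, f"substrate shorter than {k} bp; no site possible")

    # reuse the off-target search with the spacer as a pseudo-target
    pseudo = Target(
        target_id=assay.crrna.crrna_id,
        genome_id="assay",
        contig_name=_SUBSTRATE_CONTIG,
        start=0,
        strand="+",
        sequence="TTTA" + spacer,  # placeholder PAM; only the protospacer is compared
    )
    genome = Genome("assay", [Contig(_SUBSTRATE_CONTIG, substrate)])
    hits = find_offtargets(
        pseudo, genome, max_mm=len(spacer), require_pam=assay.require_pam, pam=assay.pam
    )
    if not hits:
        return DetectionResult(False, None, "no PAM-matched site in substrate")

    best = min(hits, key=lambda h: (h.mismatches, h.start, h.strand))
    best_hit = BestHit(best.start, best.strand, best.mismatches)
    activated = best.mismatches <= assay.activation_max_mm
    rationale = (
        f"best site at position {best.start} ({best.strand}) with {best.mismatches} "
        f"mismatch(es); threshold {assay.activation_max_mm} -> "
        + ("activated" if activated else "not activated")
    )
    return DetectionResult(activated, best_hit, rationale)


def simulate_panel(
    crrna: CrRNA,
    substrates: dict[str, str] | list[tuple[str, str]],
    activation_max_mm: int = DEFAULT_ACTIVATION_MAX_MM,
    require_pam: bool = True,
) -> pd.DataFrame:
    """Run one crRNA against a named panel of substrates (e.g. one amplicon
    per candidate species). Row order follows input order; columns are
    substrate, activated, best_mismatches (NA when no site exists)."""
    items = list(substrates.items()) if isinstance(substrates, dict) else list(substrates)
    rows = []
    for name, seq in items:
        res = simulate_cas12a(
            DetectionAssay(crrna, seq, activation_max_mm=activation_max_mm, require_pam=require_pam)
        )
        rows.append(
            {
                "substrate": name,
                "activated": res.activated,
                "best_mismatches": res.best_hit.mismatches if res.best_hit else pd.NA,
            }
        )
    return pd.DataFrame(rows, columns=["substrate", "activated", "best_mismatches"]).astype(
        {"best_mismatches": "Int64"}
    )
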