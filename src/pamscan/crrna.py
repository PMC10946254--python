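"""crRNA spacer derivation from targets.

The spacer is the target's protospacer (the k-mer minus its 4-bp PAM)
transcribed to the RNA alphabet. No scaffold/repeat sequence is emitted
— an optional ``scaffold`` string is prepended verbatim if the caller
supplies one. Composition flags (long homopolymer, extreme GC) are
advisory annotations only; they never filter targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import gc_fraction, max_homopolymer_run
from .target_library import Target

FLAG_HOMOPOLYMER = "homopolymer_run_ge5"
FLAG_EXTREME_GC = "extreme_gc"

HOMOPOLYMER_RUN = 5
GC_LOW, GC_HIGH = 0.2, 0.8


@dataclass(frozen=True)
class CrRNA:
    """A guide spacer: DNA form (= protospacer) and its RNA transcript."""

    crrna_id: str
    target_id: str
    spacer_dna: str
    spacer_rna: str
    gc_fraction: float
    flags: frozenset[str] = field(default_factory=frozenset)


def design_crrna(target: Target, scaffold: str = "") -> CrRNA:
    """Derive the crRNA for a target: strip the PAM, transcribe T->U.

    ``scaffold``, if given, is prepended to the RNA spacer as-is (5' side),
    for users who know their Cas12a ortholog's repeat.
    """
    spacer_dna = target.protospacer
    spacer_rna = scaffold + spacer_dna.replace("T", "U")
    gc = gc_fraction(spacer_dna)
    flags = set()
    if max_homopolymer_run(spacer_dna) >= HOMOPOLYMER_RUN:
        flags.add(FLAG_HOMOPOLYMER)
    if not GC_LOW <= gc <= GC_HIGH:
        flags.add(FLAG_EXTREME_GC)
    return CrRNA(
        crrna_id=f"{target.target_id}|crrna",
        target_id=target.target_id,
        spacer_dna=spacer_dna,
        spacer_rna=spacer_rna,
        gc_fraction=gc,
        flags=frozenset(flags),
    )
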