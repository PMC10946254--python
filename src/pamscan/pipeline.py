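"""Composite workflow: enumerate -> (region filter) -> screen -> crRNA
design -> (detection simulation), with a machine-readable run manifest.

The manifest records every parameter, the SHA-256 of every input file and
the package version, so any reported count is attributable to an exact
input. Data files never contain timestamps: reruns with identical inputs
and configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .crrna import design_crrna
from .detection_sim import simulate_panel
from .genome_io import (
    read_fasta,
    read_regions,
    write_histograms_long,
    write_profiles_table,
    write_targets_table,
)
from .specificity import screen_specific
from .target_library import enumerate_targets, extract_flanks, filter_by_region, library_stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of the composite workflow.

    ``k`` may range over 23-27; the protospacer length follows as k-4.
    Defaults mirror the screening conditions the method was validated
    under: 25-bp targets, TTTV PAM, off-target search within 5 mismatches,
    specificity at minimum distance 3, activation threshold 2, 500-bp
    amplicon flanks.
    """

    focal_fasta: str
    comparator_fastas: list[str] = field(default_factory=list)
    out_dir: str = "pamscan_out"
    regions_path: str | None = None
    k: int = 25
    pam: str = "TTTV"
    max_mm: int = 5
    specific_min_distance: int = 3
    activation_max_mm: int = 2
    flank: int = 500
    simulate_detection: bool = False
    iupac_to_n: bool = False

    def __post_init__(self) -> None:
        if not 23 <= self.k <= 27:
            raise ValueError("k must be in 23..27")
        if not 0 <= self.max_mm <= self.k - 4:
            raise ValueError("max_mm out of range")
        if not 0 <= self.activation_max_mm <= self.k - 4:
            raise ValueError("activation_max_mm out of range")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the workflow and return the manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def stage(name: str):
        logger.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                return False

        return _Ctx()

    with stage("build-library"):
        focal = read_fasta(config.focal_fasta, iupac_to_n=config.iupac_to_n)
        targets = enumerate_targets(focal, k=config.k, pam=config.pam)
        stats = library_stats(focal, targets)
        write_targets_table(targets, out / "targets.tsv")
        with open(out / "library_stats.tsv", "w") as fh:
            fh.write("genome_id\tn_target_sites\tn_distinct_sequences\tmean_spacing_bp\n")
            spacing = "NA" if stats.n_target_sites == 0 else f"{stats.mean_spacing_bp:.4f}"
            fh.write(
                f"{stats.genome_id}\t{stats.n_target_sites}\t{stats.n_distinct_sequences}\t{spacing}\n"
            )
        stages.append({"name": "build-library", "n_targets": len(targets)})

    with stage("filter-regions"):
        if config.regions_path:
            regions = read_regions(config.regions_path)
            targets = filter_by_region(targets, regions, genome=focal)
            write_targets_table(targets, out / "targets_in_regions.tsv")
        stages.append({"name": "filter-regions", "n_targets": len(targets)})

    with stage("screen"):
        comparators = [
            read_fasta(p, iupac_to_n=config.iupac_to_n) for p in config.comparator_fastas
        ]
        if comparators:
            profiles = screen_specific(
                targets,
                comparators,
                max_mm=config.max_mm,
                specific_min_distance=config.specific_min_distance,
                pam=config.pam,
            )
            write_profiles_table(profiles, out / "profiles.tsv", max_mm=config.max_mm)
            write_histograms_long(profiles, out / "histograms.tsv")
            keep = {p.target_id for p in profiles if p.specificity_class != "non_specific"}
            targets = [t for t in targets if t.target_id in keep]
            write_targets_table(targets, out / "specific_targets.tsv")
        stages.append({"name": "screen", "n_specific": len(targets)})

    with stage("design-crrna"):
        crrnas = [design_crrna(t) for t in targets]
        with open(out / "crrnas.tsv", "w") as fh:
            fh.write("crrna_id\ttarget_id\tspacer_dna\tspacer_rna\tgc_fraction\tflags\n")
            for c in crrnas:
                fh.write(
                    f"{c.crrna_id}\t{c.target_id}\t{c.spacer_dna}\t{c.spacer_rna}\t"
                    f"{c.gc_fraction:.4f}\t{','.join(sorted(c.flags)) or '-'}\n"
                )
        stages.append({"name": "design-crrna", "n_crrnas": len(crrnas)})

    with stage("simulate-detect"):
        n_activated = 0
        if config.simulate_detection and crrnas:
            substrates = []
            for t in targets:
                amp = extract_flanks(focal, t, flank=config.flank)
                substrates.append((t.target_id, amp.sequence))
            table = simulate_panel(
                crrnas[0], substrates, activation_max_mm=config.activation_max_mm
            )
            table.to_csv(out / "verdicts.tsv", sep="\t", index=False)
            n_activated = int(table["activated"].sum())
        stages.append({"name": "simulate-detect", "n_activated": n_activated})

    inputs = {Path(config.focal_fasta).name: _sha256(config.focal_fasta)}
    for p in config.comparator_fastas:
        inputs[Path(p).name] = _sha256(p)
    if config.regions_path:
        inputs[Path(config.regions_path).name] = _sha256(config.regions_path)

    manifest = {
        "tool": "pamscan",
        "version": __version__,
        "parameters": asdict(config),
        "inputs_sha256": inputs,
        "stages": stages,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
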