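"""pamscan: PAM-anchored target enumeration and cross-genome specificity
screening for CRISPR-Cas12a species identification.

The workflow: slide a 25-bp window over a focal genome (both strands),
keep windows beginning with the Cas12a TTTV PAM (candidate *targets*),
search each target's 21-nt protospacer against comparator genomes
tolerating up to five mismatches at PAM-intact sites, classify targets by
their minimum cross-genome distance, derive crRNA spacers, and predict
Cas12a activation against amplicon substrates.
"""

from importlib import resources

import pandas as pd

__version__ = "0.1.0"

from .crrna import CrRNA, design_crrna
from .detection_sim import (
    DetectionAssay,
    DetectionResult,
    simulate_cas12a,
    simulate_panel,
)
from .genome_io import (
    Contig,
    Genome,
    Region,
    read_fasta,
    read_regions,
    read_targets_table,
    write_fasta,
    write_profiles_table,
    write_targets_table,
)
from .pipeline import RunConfig, run_pipeline
from .specificity import (
    GenomeIndex,
    OffTargetHit,
    SpecificityProfile,
    brute_force_offtargets,
    find_offtargets,
    mismatch_histogram,
    screen_specific,
)
from .synthetic_data import (
    Plant,
    SynthSpec,
    make_decoy,
    make_genome,
    make_related_pair,
)
from .target_library import (
    LibraryStats,
    Target,
    enumerate_targets,
    extract_flanks,
    filter_by_region,
    library_stats,
)


def load_marker_targets() -> pd.DataFrame:
    """Published species-specific Cas12a marker targets for 13 fungal
    species (columns: species, target_sequence). Two entries are known to
    deviate from 25 nt as printed in their source; the PAM pattern, not
    the length, is the validated property."""
    with resources.files("pamscan").joinpath("data/marker_targets.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


__all__ = [
    "__version__",
    "Contig", "Genome", "Region", "Target", "LibraryStats",
    "OffTargetHit", "SpecificityProfile", "GenomeIndex",
    "CrRNA", "DetectionAssay", "DetectionResult",
    "Plant", "SynthSpec", "RunConfig",
    "read_fasta", "write_fasta", "read_regions",
    "read_targets_table", "write_targets_table", "write_profiles_table",
    "enumerate_targets", "library_stats", "filter_by_region", "extract_flanks",
    "find_offtargets", "brute_force_offtargets", "mismatch_histogram", "screen_specific",
    "design_crrna", "simulate_cas12a", "simulate_panel",
    "make_genome", "make_decoy", "make_related_pair",
    "run_pipeline", "load_marker_targets",
]
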