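"""Reading and writing the standard formats the pipeline touches.

Coordinates are 0-based, half-open everywhere inside the package. BED is
the native convention; GFF3 start coordinates are converted (minus one) at
the boundary. FASTA input is normalized to uppercase A/C/G/T/N; other IUPAC
ambiguity codes are rejected by default because silently converting them
can hide assembly artifacts — pass ``iupac_to_n=True`` to map them to N.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import IUPAC_SETS

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_AMBIGUOUS = set(IUPAC_SETS) - _VALID


@dataclass(frozen=True)
class Contig:
    """A named DNA sequence over {A,C,G,T,N}, uppercase."""

    name: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    """An ordered collection of contigs under one species tag."""

    genome_id: str
    contigs: list[Contig]
    _by_name: dict[str, Contig] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError(f"genome {self.genome_id!r} has no contigs")
        names = [c.name for c in self.contigs]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValueError(f"duplicate contig name {dup!r} in genome {self.genome_id!r}")
        self._by_name = {c.name: c for c in self.contigs}

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def contig(self, name: str) -> Contig:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name


@dataclass(frozen=True)
class Region:
    """A 0-based half-open interval on a named contig."""

    contig_name: str
    start: int
    end: int
    label: str = "region"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad region interval [{self.start}, {self.end})")


def _normalize(seq: str, contig_name: str, iupac_to_n: bool) -> str:
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    out = []
    for i, b in enumerate(seq):
        if b in _VALID:
            out.append(b)
        elif b in _AMBIGUOUS and iupac_to_n:
            out.append("N")
        else:
            raise ValueError(
                f"illegal residue {b!r} at contig {contig_name!r} position {i}"
                + ("" if b in _AMBIGUOUS else " (not an IUPAC DNA code)")
            )
    return "".join(out)


def read_fasta(path: str | Path, genome_id: str | None = None, iupac_to_n: bool = False) -> Genome:
    """Read a (multi-)FASTA file into a Genome.

    Contigs keep file order; sequences are uppercased. ``genome_id``
    defaults to the file stem.
    """
    path = Path(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        seen.add(rec.id)
        contigs.append(Contig(rec.id, _normalize(str(rec.seq), rec.id, iupac_to_n)))
    if not contigs:
        raise ValueError(f"no sequences in {path}")
    return Genome(genome_id or path.stem, contigs)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.name, description="") for c in genome.contigs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_regions(path: str | Path, format: str | None = None) -> list[Region]:
    """Read regions from BED or GFF3 into 0-based half-open intervals.

    ``format`` is "bed" or "gff3"; inferred from the file suffix when
    omitted. GFF3 1-based inclusive starts are converted by subtracting 1.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "gff3" if suffix in {".gff", ".gff3"} else "bed"
    format = format.lower()
    if format not in {"bed", "gff3"}:
        raise ValueError(f"unknown region format {format!r}")

    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if format == "bed" and line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if format == "bed":
                    if len(fields) < 3:
                        raise ValueError("fewer than 3 columns")
                    contig, start, end = fields[0], int(fields[1]), int(fields[2])
                    label = fields[3] if len(fields) > 3 else "region"
                else:
                    if len(fields) < 9:
                        raise ValueError("fewer than 9 columns")
                    contig = fields[0]
                    start = int(fields[3]) - 1
                    end = int(fields[4])
                    label = _gff3_label(fields[8]) or fields[2]
                regions.append(Region(contig, start, end, label))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed {format.upper()} line: {exc}") from None
    return regions


def _gff3_label(attributes: str) -> str | None:
    for key in ("Name", "ID"):
        for part in attributes.split(";"):
            if part.strip().startswith(key + "="):
                return part.strip()[len(key) + 1 :]
    return None


TARGET_COLUMNS = [
    "target_id", "genome_id", "contig_name", "start", "end",
    "strand", "sequence", "pam", "protospacer", "copy_number",
]

PROFILE_COLUMNS = [
    "target_id", "comparator_genome_id", "min_distance", "specificity_class",
]


def write_targets_table(targets: Sequence, path: str | Path, bed_path: str | Path | None = None) -> None:
    """Write targets as a fixed-column TSV plus a BED6 companion.

    BED score column carries the own-genome copy number. ``bed_path``
    defaults to the TSV path with a ``.bed`` suffix.
    """
    path = Path(path)
    rows = [
        {
            "target_id": t.target_id,
            "genome_id": t.genome_id,
            "contig_name": t.contig_name,
            "start": t.start,
            "end": t.start + len(t.sequence),
            "strand": t.strand,
            "sequence": t.sequence,
            "pam": t.pam,
            "protospacer": t.protospacer,
            "copy_number": t.copy_number,
        }
        for t in targets
    ]
    df = pd.DataFrame(rows, columns=TARGET_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    bed_path = Path(bed_path) if bed_path is not None else path.with_suffix(".bed")
    with open(bed_path, "w") as fh:
        for r in rows:
            fh.write(
                f"{r['contig_name']}\t{r['start']}\t{r['end']}\t"
                f"{r['target_id']}\t{r['copy_number']}\t{r['strand']}\n"
            )


def read_targets_table(path: str | Path) -> list:
    """Read a targets TSV written by :func:`write_targets_table`."""
    from .target_library import Target  # local import avoids a cycle

    df = pd.read_csv(path, sep="\t", dtype={"start": int, "copy_number": int})
    targets = []
    for row in df.itertuples(index=False):
        targets.append(
            Target(
                target_id=row.target_id,
                genome_id=row.genome_id,
                contig_name=row.contig_name,
                start=int(row.start),
                strand=row.strand,
                sequence=row.sequence,
                copy_number=int(row.copy_number),
            )
        )
    return targets


def write_profiles_table(profiles: Sequence, path: str | Path, max_mm: int = 5) -> None:
    """One TSV row per target x comparator genome: min distance, class and
    the per-distance hit counts (columns mm0..mm<max_mm>)."""
    rows = []
    for p in profiles:
        for genome_id, hist in p.per_genome_hist.items():
            row = {
                "target_id": p.target_id,
                "comparator_genome_id": genome_id,
                "min_distance": p.min_distance[genome_id],
                "specificity_class": p.specificity_class,
            }
            for d in range(max_mm + 1):
                row[f"mm{d}"] = hist[d] if d < len(hist) else 0
            rows.append(row)
    cols = PROFILE_COLUMNS + [f"mm{d}" for d in range(max_mm + 1)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_histograms_long(profiles: Sequence, path: str | Path) -> None:
    """Long-format histogram export: target_id, genome_id, distance, count."""
    rows = []
    for p in profiles:
        for genome_id, hist in p.per_genome_hist.items():
            for d, count in enumerate(hist):
                rows.append(
                    {"target_id": p.target_id, "genome_id": genome_id, "distance": d, "count": count}
                )
    pd.DataFrame(rows, columns=["target_id", "genome_id", "distance", "count"]).to_csv(
        path, sep="\t", index=False
    )


def intersect_check(regions: Iterable[Region], genome: Genome) -> list[Region]:
    """Drop (with a warning) regions naming contigs absent from the genome;
    error on regions overrunning their contig."""
    kept = []
    for r in regions:
        if r.contig_name not in genome:
            warnings.warn(f"region {r.label!r} references unknown contig {r.contig_name!r}; ignored")
            continue
        if r.end > len(genome.contig(r.contig_name)):
            raise ValueError(
                f"region {r.label!r} [{r.start}, {r.end}) overruns contig {r.contig_name!r}"
            )
        kept.append(r)
    return kept
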