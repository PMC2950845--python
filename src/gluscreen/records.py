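"""Core record types and plain-text I/O shared across the package.

Coordinates are 0-based, half-open everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted on input; X is allowed and scored 0 by the aligner
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

REGION_TYPES = ("S1", "S2", "M1", "M2", "TM", "P", "SIGNAL", "DOMAIN")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with identifier and free-text description."""

    protein_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.protein_id}: non-standard residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RegionAnnotation:
    """A typed half-open interval on a protein, optionally scored.

    ``region_type`` is one of S1/S2/M1/M2/TM/P/SIGNAL/DOMAIN; ``score`` carries
    an E-value or probability depending on the annotation source.
    """

    region_type: str
    start: int
    end: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.region_type not in REGION_TYPES:
            raise ValueError(f"unknown region type {self.region_type!r}")
        if not (0 <= self.start <= self.end):
            raise ValueError(
                f"bad interval [{self.start}, {self.end}) for {self.region_type}"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GroundTruth:
    """Planted architecture of one synthetic protein."""

    protein_id: str
    label: str  # channel-g1 | channel-g2 | soluble-binder | permease | random
    regions: tuple[RegionAnnotation, ...] = field(default_factory=tuple)

    def region(self, region_type: str) -> Optional[RegionAnnotation]:
        for r in self.regions:
            if r.region_type == region_type:
                return r
        return None


ARCHITECTURES = (
    "channel-g1",
    "channel-g2",
    "soluble-binder",
    "permease",
    "random",
)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinRecord(rec.id, str(rec.seq).upper(), desc))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_lineage(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a lineage TSV (protein_id, superkingdom, phylum) into a mapping."""
    lineage: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("protein_id", "superkingdom"):
            if col not in idx:
                raise ValueError(f"lineage TSV missing column {col!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            pid = parts[idx["protein_id"]]
            lineage[pid] = {
                "superkingdom": parts[idx["superkingdom"]],
                "phylum": parts[idx["phylum"]] if "phylum" in idx else "",
            }
    return lineage


def write_lineage(
    lineage: Mapping[str, Mapping[str, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tsuperkingdom\tphylum\n")
        for pid in sorted(lineage):
            row = lineage[pid]
            fh.write(f"{pid}\t{row['superkingdom']}\t{row.get('phylum', '')}\n")


def write_ground_truth(
    truths: Sequence[GroundTruth], path: str | Path
) -> None:
    """TSV: protein_id, label, region_type, start, end (one row per region)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tlabel\tregion_type\tstart\tend\n")
        for gt in truths:
            if not gt.regions:
                fh.write(f"{gt.protein_id}\t{gt.label}\t.\t.\t.\n")
            for r in gt.regions:
                fh.write(
                    f"{gt.protein_id}\t{gt.label}\t{r.region_type}"
                    f"\t{r.start}\t{r.end}\n"
                )


def read_ground_truth(path: str | Path) -> list[GroundTruth]:
    rows: dict[str, tuple[str, list[RegionAnnotation]]] = {}
    order: list[str] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            pid, label, rtype, start, end = line.rstrip("\n").split("\t")
            if pid not in rows:
                rows[pid] = (label, [])
                order.append(pid)
            if rtype != ".":
                rows[pid][1].append(
                    RegionAnnotation(rtype, int(start), int(end))
                )
    return [
        GroundTruth(pid, rows[pid][0], tuple(rows[pid][1])) for pid in order
    ]
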