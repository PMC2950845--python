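"""Packaged reference inputs: probe segments and the transcribed study tables.

The two probe segments are the halves of the extracellular glutamate-binding
domain (S1, 57 aa; S2, 69 aa) of a functionally characterized cyanobacterial
glutamate-gated channel. The tables are the published annotation list of the
100 candidate proteins, the Group 1 / Group 2 channel gene list, and the human
iGluR reference list; they are transcribed as printed, including apparent
inconsistencies (e.g. entry #42, a "glutamate-gated potassium channel", sits
in Group 2 while #94, "K channel, pore region", sits in Group 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .records import VALID_RESIDUES


class FixtureIntegrityError(RuntimeError):
    """Packaged data does not match its documented invariants."""


S1_LENGTH = 57
S2_LENGTH = 69

#: default key-residue anchors: the S1 Arg contacting the ligand α-carboxy
#: group and the S2 Asp contacting the α-amino group (0-based probe offsets).
S1_ARG_ANCHOR = 5
S2_ASP_ANCHOR = 5


@dataclass(frozen=True)
class ProbeSet:
    s1_sequence: str
    s2_sequence: str

    def __post_init__(self) -> None:
        if len(self.s1_sequence) != S1_LENGTH:
            raise FixtureIntegrityError(
                f"S1 probe length {len(self.s1_sequence)} != {S1_LENGTH}"
            )
        if len(self.s2_sequence) != S2_LENGTH:
            raise FixtureIntegrityError(
                f"S2 probe length {len(self.s2_sequence)} != {S2_LENGTH}"
            )
        for name, seq in (("S1", self.s1_sequence), ("S2", self.s2_sequence)):
            bad = set(seq) - (VALID_RESIDUES - {"X"})
            if bad:
                raise FixtureIntegrityError(
                    f"{name} probe has non-standard residues {sorted(bad)}"
                )


@dataclass(frozen=True)
class StudyTables:
    #: (annotation_category, protein_numbers, count)
    annotation_table: tuple[tuple[str, tuple[int, ...], int], ...]
    #: (protein_number, group_label, description, accession)
    group_table: tuple[tuple[int, int, str, str], ...]
    #: (subtype, name, accession, length_aa)
    human_iglur_table: tuple[tuple[str, str, str, int], ...]

    def __post_init__(self) -> None:
        for category, numbers, count in self.annotation_table:
            if count != len(numbers):
                raise FixtureIntegrityError(
                    f"annotation row {category!r}: count {count} != "
                    f"{len(numbers)} listed protein numbers"
                )
        for number, group, _, _ in self.group_table:
            if group not in (1, 2):
                raise FixtureIntegrityError(f"bad group label {group}")
            if not 1 <= number <= 100:
                raise FixtureIntegrityError(f"protein number {number} out of range")

    def group_members(self, group: int) -> list[int]:
        return [n for n, g, _, _ in self.group_table if g == group]

    @property
    def channel_count(self) -> int:
        return len(self.group_table)


def _read_text(name: str) -> str:
    return resources.files("gluscreen.data").joinpath(name).read_text()


def load_probes() -> ProbeSet:
    """Return the packaged S1/S2 probe segments exactly as published."""
    seqs: dict[str, str] = {}
    label = None
    for line in _read_text("probes.fasta").splitlines():
        if line.startswith(">"):
            label = line[1:].split()[0]
            seqs[label] = ""
        elif label:
            seqs[label] += line.strip()
    try:
        return ProbeSet(seqs["S1"], seqs["S2"])
    except KeyError as exc:  # pragma: no cover - corrupt install
        raise FixtureIntegrityError(f"probe record missing: {exc}") from exc


def load_study_tables() -> StudyTables:
    """Load the transcribed annotation, group and human-receptor tables."""
    annotation = []
    for line in _read_text("table1_annotation.tsv").splitlines()[1:]:
        if not line.strip():
            continue
        category, numbers, count = line.split("\t")
        annotation.append(
            (category, tuple(int(n) for n in numbers.split(",")), int(count))
        )
    groups = []
    for line in _read_text("table2_groups.tsv").splitlines()[1:]:
        if not line.strip():
            continue
        number, group, description, accession = line.split("\t")
        groups.append((int(number), int(group), description, accession))
    human = []
    for line in _read_text("table4_human_iglur.tsv").splitlines()[1:]:
        if not line.strip():
            continue
        subtype, name, accession, length = line.split("\t")
        human.append((subtype, name, accession, int(length)))
    return StudyTables(tuple(annotation), tuple(groups), tuple(human))


#: Aggregation of printed annotation categories into the headline classes
#: ("51 ... ABC-type amino acid transporter or something similar, 13 ...
#: binding proteins, 14 ... hypothetical proteins, 2 ... K channels").
ANNOTATION_CLASSES = {
    "abc_like": (
        "ABC transport system glutamine-binding protein",
        "ABC-type amino acid transport/signal",
    ),
    "binding_protein": (
        "binding protein",
        "extracellular solute-binding protein",
    ),
    "hypothetical": ("hypothetical protein",),
    "k_channel": ("K channel",),
    "iglur": ("iGluR",),
}


def annotation_tallies(tables: StudyTables) -> dict[str, int]:
    """Headline annotation-class counts recomputed from the row lists."""
    by_category = {
        category: len(numbers)
        for category, numbers, _ in tables.annotation_table
    }
    return {
        cls: sum(by_category.get(cat, 0) for cat in cats)
        for cls, cats in ANNOTATION_CLASSES.items()
    }
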