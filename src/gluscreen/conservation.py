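"""Region-wise alignment joining and per-column conservation classes.

Columns are classified with the ClustalX conventions behind the '*', ':' and
'.' consensus marks: *identical* (one residue type, no gaps), *strongly
conserved* (all residues within one strong group), *weakly conserved* (all
within one weak group), otherwise *none*; any gap in a column makes it none.
Region alignments (S1, channel, S2) are aligned separately and then joined,
with recorded column boundaries, so conservation can be compared per region.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRONG_GROUPS = (
    "STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW",
)
WEAK_GROUPS = (
    "CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK", "NDEQHK",
    "NEQHRK", "FVLIM", "HFY",
)
_STRONG = tuple(frozenset(g) for g in STRONG_GROUPS)
_WEAK = tuple(frozenset(g) for g in WEAK_GROUPS)

#: canonical left-to-right order of joined regions along the protein
CANONICAL_REGION_ORDER = ("S1", "channel", "S2")

GAP_CHARACTERS = frozenset("-.")

Rows = Sequence[tuple[str, str]]


@dataclass(frozen=True)
class RegionAlignment:
    """A joined multi-region alignment with per-region column boundaries."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    boundaries: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def region_columns(self, region: str) -> range:
        start, end = self.boundaries[region]
        return range(start, end)


@dataclass(frozen=True)
class ConservationSummary:
    """Per-region counts of each conservation class."""

    regions: Mapping[str, Mapping[str, int]]

    def fraction(self, region: str, klass: str) -> tuple[int, int]:
        r = self.regions[region]
        return r[klass], r["columns_total"]


def _as_rows(alignment) -> Rows:
    if isinstance(alignment, MultipleSeqAlignment):
        return [(rec.id, str(rec.seq)) for rec in alignment]
    return list(alignment)


def join_alignments(per_region: Mapping[str, object]) -> RegionAlignment:
    """Concatenate per-region alignments horizontally.

    All inputs must share the same sequence ids in the same order. Regions
    are joined in the canonical order S1, channel, S2 (others appended
    alphabetically) regardless of mapping order.
    """
    regions = {name: _as_rows(aln) for name, aln in per_region.items()}
    known = [r for r in CANONICAL_REGION_ORDER if r in regions]
    extra = sorted(set(regions) - set(CANONICAL_REGION_ORDER))
    order = known + extra
    if not order:
        raise ValueError("no regions to join")
    reference_ids = [rid for rid, _ in regions[order[0]]]
    for name in order[1:]:
        ids = [rid for rid, _ in regions[name]]
        if ids != reference_ids:
            offenders = sorted(set(ids) ^ set(reference_ids)) or ids
            raise ValueError(
                f"region {name!r} id set/order mismatch: {offenders}"
            )
    boundaries = {}
    cursor = 0
    joined = ["" for _ in reference_ids]
    for name in order:
        width = len(regions[name][0][1])
        boundaries[name] = (cursor, cursor + width)
        cursor += width
        for i, (_, seq) in enumerate(regions[name]):
            joined[i] += seq
    return RegionAlignment(tuple(reference_ids), tuple(joined), boundaries)


def classify_column(column: str) -> str:
    """ClustalX-style conservation class of one alignment column."""
    if not column:
        raise ValueError("empty column")
    if GAP_CHARACTERS & set(column):
        return "none"
    residues = frozenset(column)
    if len(residues) == 1:
        return "identical"
    if any(residues <= group for group in _STRONG):
        return "strong"
    if any(residues <= group for group in _WEAK):
        return "weak"
    return "none"


def summarize(alignment: RegionAlignment) -> ConservationSummary:
    """Count conservation classes per region of a joined alignment."""
    regions = {}
    for region, (start, end) in alignment.boundaries.items():
        counts = {"columns_total": end - start, "identical": 0,
                  "strong": 0, "weak": 0, "none": 0}
        for j in range(start, end):
            counts[classify_column(alignment.column(j))] += 1
        regions[region] = counts
    return ConservationSummary(regions)


def key_residue_check(
    alignment: RegionAlignment,
    s1_anchor: int,
    s2_anchor: int,
    expected: tuple[str, str] = ("R", "D"),
) -> dict[str, bool]:
    """Check total conservation of the key binding residues.

    ``s1_anchor``/``s2_anchor`` are alignment column indices that must fall
    inside the S1 and S2 region boundaries; expected residues default to the
    ligand-contacting Arg (S1) and Asp (S2). A flag is True iff every row
    carries exactly the expected residue in that column.
    """
    if not alignment.rows:
        raise ValueError("empty alignment")
    out = {}
    for region, anchor, residue in (
        ("S1", s1_anchor, expected[0]),
        ("S2", s2_anchor, expected[1]),
    ):
        start, end = alignment.boundaries[region]
        if not start <= anchor < end:
            raise ValueError(
                f"anchor column {anchor} outside {region} columns "
                f"[{start}, {end})"
            )
        out[region] = all(row[anchor] == residue for row in alignment.rows)
    return out


# ---------------------------------------------------------------------------
# plain-text alignment I/O (aligned FASTA and Clustal)
# ---------------------------------------------------------------------------


def read_alignment(path: str | Path, fmt: str = "fasta") -> list[tuple[str, str]]:
    """Read an aligned FASTA or Clustal (.aln) file into (id, row) pairs.

    The Clustal consensus-symbol line is ignored on read (and regenerated by
    :func:`write_alignment`).
    """
    aln = AlignIO.read(str(path), fmt)
    return [(rec.id, str(rec.seq)) for rec in aln]


def write_alignment(
    rows: Rows, path: str | Path, fmt: str = "fasta"
) -> None:
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in rows]
    )
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, fmt)


def write_summary_tsv(
    summaries: Mapping[str, ConservationSummary], path: str | Path
) -> None:
    """Summary TSV shaped like the published conservation table."""
    with open(path, "w") as fh:
        fh.write("group\tregion\tclass\tnumerator\tdenominator\n")
        for group in sorted(summaries):
            summary = summaries[group]
            for region in sorted(summary.regions):
                for klass in ("identical", "strong", "weak"):
                    num, den = summary.fraction(region, klass)
                    fh.write(f"{group}\t{region}\t{klass}\t{num}\t{den}\n")
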