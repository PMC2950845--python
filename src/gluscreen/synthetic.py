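"""Synthetic benchmark data with planted ground truth.

The generator emulates the architectures the screen must distinguish:

* ``channel-g1`` / ``channel-g2`` — optional signal peptide, then a mutated
  copy of the S1 probe, a hydrophobic M1 helix, a re-entrant pore segment
  (Group 1 carries a potassium-type selectivity filter, Group 2 does not),
  an M2 helix, and a mutated copy of the S2 probe, joined by background
  linkers.
* ``soluble-binder`` — S1 + S2 with no membrane segments (periplasmic
  binding-protein mimic).
* ``permease`` — three membrane helices, no binding domain.
* ``random`` — background composition.

Only the S1/S2 probe copies are mutated at ``substitution_rate``; membrane
helices, pores and linkers are drawn fresh per protein. Pore segments are
rejection-sampled so every 9-residue window sits in the sub-threshold
hydropathy band the pore detector expects — the pore is a structural feature
of the architecture, not a mutated template. Key binding residues (the S1 Arg
and S2 Asp) and the Group-1 filter motif are excluded from mutation by
default, mirroring their total conservation in real alignments.

Everything is driven by numpy Generators; identical (spec, seed) pairs give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np

from .fixtures import S1_ARG_ANCHOR, S2_ASP_ANCHOR, load_probes
from .records import (
    AMINO_ACIDS,
    ARCHITECTURES,
    GroundTruth,
    ProteinRecord,
    RegionAnnotation,
)
from .screen import hydropathy_profile

#: Robinson-Robinson background amino-acid frequencies
BACKGROUND_FREQUENCIES = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.090, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.066,
}
_BG_RESIDUES = np.array(list(BACKGROUND_FREQUENCIES))
_BG_P = np.array(list(BACKGROUND_FREQUENCIES.values()))
_BG_P = _BG_P / _BG_P.sum()

TM_RESIDUES = np.array(list("AILFVM"))
K_FILTER_MOTIF = "TVGYG"

#: moderately hydrophobic scaffold used for pore segments
_PORE_RESIDUES = np.array(list("AMCVTS"))
_PORE_P = np.array([0.25, 0.20, 0.25, 0.20, 0.05, 0.05])
#: acceptance band on 9-residue window mean hydropathy of a pore segment:
#: inside the detector's sub-threshold band with a small safety margin
PORE_BAND = (1.08, 1.55)

SIGNAL_CORE_RESIDUES = np.array(list("LIVF"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_channels_group1: int = 5
    n_channels_group2: int = 5
    n_decoys_per_class: int = 5
    substitution_rate: float = 0.05
    tm_length: int = 19
    pore_length: int = 12
    linker_length_range: tuple[int, int] = (5, 30)
    include_signal_peptide: bool = True
    protect_anchors: bool = True
    indel_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.tm_length <= 0 or self.pore_length <= 0:
            raise ValueError("lengths must be positive")
        lo, hi = self.linker_length_range
        if not 0 < lo <= hi:
            raise ValueError("bad linker length range")


def _background(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BG_RESIDUES, size=length, p=_BG_P))


def _linker(rng: np.random.Generator, spec: SyntheticSpec) -> str:
    lo, hi = spec.linker_length_range
    return _background(rng, int(rng.integers(lo, hi + 1)))


def mutate(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    protected: frozenset[int] = frozenset(),
) -> str:
    """Per-site substitution to a uniformly random different residue."""
    out = list(seq)
    for i, aa in enumerate(out):
        if i in protected or rng.random() >= rate:
            continue
        choices = [x for x in AMINO_ACIDS if x != aa]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _tm_helix(rng: np.random.Generator, length: int) -> str:
    # 90% core hydrophobics, 10% background "imperfections"
    out = rng.choice(TM_RESIDUES, size=length)
    other = rng.random(length) < 0.10
    out[other] = rng.choice(_BG_RESIDUES, size=int(other.sum()), p=_BG_P)
    return "".join(out)


def sample_pore(
    rng: np.random.Generator,
    length: int = 12,
    with_filter: bool = False,
    max_tries: int = 5000,
) -> str:
    """Draw a pore segment whose window hydropathy sits in the detector band.

    With ``with_filter`` the canonical selectivity-filter motif is embedded at
    a random interior offset. Without it, the scaffold alphabet contains no
    glycine, so the filter signature cannot arise by chance.
    """
    window = 9
    if length < window:
        raise ValueError(f"pore length must be >= {window}")
    lo, hi = PORE_BAND
    for _ in range(max_tries):
        scaffold = rng.choice(_PORE_RESIDUES, size=length, p=_PORE_P)
        seq = "".join(scaffold)
        if with_filter:
            offset = int(rng.integers(2, length - len(K_FILTER_MOTIF) - 1))
            seq = (
                seq[:offset] + K_FILTER_MOTIF
                + seq[offset + len(K_FILTER_MOTIF):]
            )
        prof = hydropathy_profile(seq, window)
        if lo <= prof.min() and prof.max() <= hi:
            return seq
    raise RuntimeError("pore rejection sampling failed")  # pragma: no cover


def _signal_peptide(rng: np.random.Generator) -> str:
    core = "".join(rng.choice(SIGNAL_CORE_RESIDUES, size=10))
    return "M" + "".join(rng.choice(list("KR"), size=2)) + core + "SGA"


def _membrane_section(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    with_filter: bool,
    max_tries: int = 500,
) -> list[tuple[str, Optional[str]]]:
    """Draw the linker/M1/linker/P/linker/M2/linker section of a channel.

    The section is redrawn until, scanned in isolation, it shows exactly two
    passing helices with the best sub-threshold candidate between them
    covering the planted pore (and, for Group 1, the whole filter motif) —
    i.e. until the planted architecture actually presents the channel
    signature it is meant to carry. Random background linkers occasionally
    blur helix boundaries or lift the pore over the full-helix threshold;
    those draws do not represent the intended architecture and are discarded.
    """
    from .screen import predict_tm_segments  # deferred: avoids import cycle

    for _ in range(max_tries):
        l1 = _linker(rng, spec)
        m1 = _tm_helix(rng, spec.tm_length)
        l2 = _linker(rng, spec)
        pore = sample_pore(rng, spec.pore_length, with_filter=with_filter)
        l3 = _linker(rng, spec)
        m2 = _tm_helix(rng, spec.tm_length)
        l4 = _linker(rng, spec)
        section = l1 + m1 + l2 + pore + l3 + m2 + l4
        pore_start = len(l1 + m1 + l2)
        pore_end = pore_start + len(pore)
        segments = predict_tm_segments(section)
        passing = [s for s in segments if s.passes_test]
        if len(passing) != 2:
            continue
        first, second = passing
        between = [
            s for s in segments
            if not s.passes_test
            and s.start >= first.end and s.end <= second.start
        ]
        if not between:
            continue
        best = max(between, key=lambda s: (s.probability_score, -s.start))
        if with_filter:
            motif_at = pore_start + pore.index(K_FILTER_MOTIF)
            localized = (best.start <= motif_at
                         and best.end >= motif_at + len(K_FILTER_MOTIF))
        else:
            overlap = min(best.end, pore_end) - max(best.start, pore_start)
            localized = overlap >= spec.pore_length // 2
        if not localized:
            continue
        return [
            (l1, None), (m1, "M1"), (l2, None), (pore, "P"),
            (l3, None), (m2, "M2"), (l4, None),
        ]
    raise RuntimeError(
        "membrane-section sampling failed"
    )  # pragma: no cover


def generate_protein(
    spec: SyntheticSpec,
    architecture: str,
    rng: np.random.Generator,
    protein_id: str = "SYN0001",
) -> tuple[ProteinRecord, GroundTruth]:
    """Generate one protein of the requested architecture with ground truth."""
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture label {architecture!r}")
    probes = load_probes()
    protected_s1 = frozenset({S1_ARG_ANCHOR}) if spec.protect_anchors else frozenset()
    protected_s2 = frozenset({S2_ASP_ANCHOR}) if spec.protect_anchors else frozenset()

    parts: list[str] = []
    regions: list[RegionAnnotation] = []
    pos = 0

    def add(fragment: str, region_type: Optional[str] = None) -> None:
        nonlocal pos
        if region_type is not None:
            regions.append(
                RegionAnnotation(region_type, pos, pos + len(fragment))
            )
        parts.append(fragment)
        pos += len(fragment)

    if architecture in ("channel-g1", "channel-g2"):
        if spec.include_signal_peptide:
            add(_signal_peptide(rng), "SIGNAL")
        add(_linker(rng, spec))
        add(mutate(probes.s1_sequence, spec.substitution_rate, rng,
                   protected_s1), "S1")
        for fragment, region_type in _membrane_section(
            rng, spec, with_filter=architecture == "channel-g1"
        ):
            add(fragment, region_type)
        add(mutate(probes.s2_sequence, spec.substitution_rate, rng,
                   protected_s2), "S2")
    elif architecture == "soluble-binder":
        add(_linker(rng, spec))
        add(mutate(probes.s1_sequence, spec.substitution_rate, rng,
                   protected_s1), "S1")
        add(_linker(rng, spec))
        add(mutate(probes.s2_sequence, spec.substitution_rate, rng,
                   protected_s2), "S2")
        add(_linker(rng, spec))
    elif architecture == "permease":
        add(_linker(rng, spec))
        for _ in range(3):
            add(_tm_helix(rng, spec.tm_length), "TM")
            add(_linker(rng, spec))
    else:  # random
        add(_background(rng, int(rng.integers(200, 301))))

    record = ProteinRecord(protein_id, "".join(parts), architecture)
    truth = GroundTruth(protein_id, architecture, tuple(regions))
    return record, truth


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], list[GroundTruth]]:
    """Generate the full benchmark dataset described by ``spec``.

    Composition: n_channels_group1 + n_channels_group2 channels followed by
    n_decoys_per_class of each decoy class, in a fixed order; reproducible
    from ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    plan = (
        [("channel-g1", spec.n_channels_group1),
         ("channel-g2", spec.n_channels_group2)]
        + [(label, spec.n_decoys_per_class)
           for label in ("soluble-binder", "permease", "random")]
    )
    records, truths = [], []
    counter = 0
    for label, n in plan:
        for _ in range(n):
            counter += 1
            rec, gt = generate_protein(spec, label, rng, f"SYN{counter:04d}")
            records.append(rec)
            truths.append(gt)
    return records, truths


def generate_lineage(
    records: Sequence[ProteinRecord], rng_seed: int = 0
) -> dict[str, dict[str, str]]:
    """Assign every record a bacterial lineage (phylum drawn at random)."""
    rng = np.random.default_rng(rng_seed)
    phyla = ["Proteobacteria", "Cyanobacteria", "Firmicutes", "Actinobacteria"]
    return {
        rec.protein_id: {
            "superkingdom": "Bacteria",
            "phylum": phyla[int(rng.integers(len(phyla)))],
        }
        for rec in records
    }


# ---------------------------------------------------------------------------
# species scenarios and sequence evolution for tree-based analyses
# ---------------------------------------------------------------------------


def _random_clade(
    rng: np.random.Generator, labels: list[str]
) -> tuple[str, dict[str, str]]:
    """Random bifurcating newick subtree over ``labels``; returns leaf parents
    encoded implicitly (parent identity = newick of the cherry it sits in)."""
    nodes = [(lab, lab) for lab in labels]  # (newick, id)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (nwk_j, _) = nodes.pop(int(j))
        (nwk_i, _) = nodes.pop(int(i))
        bl_i, bl_j = rng.uniform(0.05, 0.3, size=2)
        merged = f"({nwk_i}:{bl_i:.4f},{nwk_j}:{bl_j:.4f})"
        nodes.append((merged, merged))
    return nodes[0][0], {}


def generate_species_scenario(
    n_clade_a: int,
    n_clade_b: int,
    transfers: int = 0,
    rng_seed: int = 0,
) -> tuple[str, dict[str, str]]:
    """Two-clade species tree with ``transfers`` planted cross-clade events.

    Returns a newick string and a leaf-to-group map. Groups follow vertical
    descent (clade A carries group1, clade B group2), then exactly
    ``transfers`` leaves — alternating donor clades, never two leaves of the
    same cherry — are reassigned to the other group. Each reassigned leaf
    contributes one extra parsimony change, so the inferred minimum number of
    transfers (parsimony changes − 1) equals ``transfers``.
    """
    if n_clade_a < 2 or n_clade_b < 2:
        raise ValueError("each clade needs at least 2 leaves")
    if transfers < 0:
        raise ValueError("transfers must be >= 0")
    rng = np.random.default_rng(rng_seed)
    labels_a = [f"A{i + 1:02d}" for i in range(n_clade_a)]
    labels_b = [f"B{i + 1:02d}" for i in range(n_clade_b)]
    nwk_a, _ = _random_clade(rng, labels_a)
    nwk_b, _ = _random_clade(rng, labels_b)
    newick = f"({nwk_a}:0.1000,{nwk_b}:0.1000);"

    groups = {lab: "group1" for lab in labels_a}
    groups.update({lab: "group2" for lab in labels_b})

    tree = dendropy.Tree.get(data=newick, schema="newick")
    parent_of = {
        leaf.taxon.label: id(leaf.parent_node)
        for leaf in tree.leaf_node_iter()
    }
    # a leaf hanging directly off a clade root must stay put: flipping it
    # merges with the between-clade boundary change and the planted transfer
    # would not be countable by parsimony
    basal = {
        leaf.taxon.label
        for leaf in tree.leaf_node_iter()
        if leaf.parent_node.parent_node is tree.seed_node
    }
    pools = {
        "A": list(labels_a),
        "B": list(labels_b),
    }
    for pool in pools.values():
        rng.shuffle(pool)
    used_parents: set[int] = set()
    flipped: list[str] = []
    side = "A"
    for _ in range(transfers):
        pool = pools[side]
        def eligible(lab):
            return lab not in basal and parent_of[lab] not in used_parents

        choice = next((lab for lab in pool if eligible(lab)), None)
        if choice is None:
            other = pools["B" if side == "A" else "A"]
            choice = next((lab for lab in other if eligible(lab)), None)
        if choice is None:
            raise ValueError(
                f"cannot place {transfers} transfers on this tree: "
                "no reassignable leaves left"
            )
        for pool in pools.values():
            if choice in pool:
                pool.remove(choice)
        used_parents.add(parent_of[choice])
        groups[choice] = "group2" if choice.startswith("A") else "group1"
        flipped.append(choice)
        side = "B" if side == "A" else "A"
    return newick, groups


def simulate_region_alignments(
    tree: "str | dendropy.Tree",
    region_lengths: dict[str, int],
    rng_seed: int = 0,
    scale: float = 1.0,
) -> dict[str, list[tuple[str, str]]]:
    """Evolve one alignment per region along a shared tree.

    Uses an infinite-sites protein model: each edge mutates a disjoint set of
    sites (about edge_length x region_length x scale of them, at least one),
    and a site never mutates twice. Pairwise Hamming distances are then
    exactly additive on the tree, so distance-based reconstruction recovers
    the generating topology deterministically. This is a deliberately
    idealized model for exercising tree machinery, not a realistic
    substitution process.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(rng_seed)
    edges = [
        e for e in tree.preorder_edge_iter()
        if e.head_node is not tree.seed_node
    ]
    out: dict[str, list[tuple[str, str]]] = {}
    for region, length in region_lengths.items():
        requested = [
            max(1, int(round((e.length or 0.1) * length * scale)))
            for e in edges
        ]
        total = sum(requested)
        budget = int(0.9 * length)
        if len(edges) > budget:
            raise ValueError(f"region {region!r} too short for this tree")
        if total > budget:
            shrink = budget / total
            requested = [max(1, int(r * shrink)) for r in requested]
        pool = list(rng.permutation(length))
        root_seq = list(_background(rng, length))
        seqs = {id(tree.seed_node): root_seq}
        for edge, n_mut in zip(edges, requested):
            parent = seqs[id(edge.tail_node)]
            child = list(parent)
            for _ in range(n_mut):
                site = int(pool.pop())
                alternatives = [x for x in AMINO_ACIDS if x != parent[site]]
                child[site] = alternatives[int(rng.integers(len(alternatives)))]
            seqs[id(edge.head_node)] = child
        rows = [
            (leaf.taxon.label, "".join(seqs[id(leaf)]))
            for leaf in tree.leaf_node_iter()
        ]
        rows.sort()
        out[region] = rows
    return out
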