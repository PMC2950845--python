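"""Distance trees, congruence statistics and parsimony-based HGT bounds.

Trees are built by neighbor joining on p-distances — the reproducible
surrogate for the guide-tree/display programs used in legacy pipelines.
Horizontal transfer is bounded from below by small parsimony: with the group
membership of each organism's channel as a character on the 16S (species)
tree, a single vertical divergence explains one state change, so the minimum
number of transfers is the parsimony score minus one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import dendropy
import numpy as np
from dendropy.calculate import treecompare

Rows = Sequence[tuple[str, str]]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray  # symmetric, zero diagonal, >= 0

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.matrix):
                fh.write(label + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def p_distance(rows: Rows) -> DistanceMatrix:
    """Pairwise fraction of differing sites, gap columns excluded pairwise."""
    if len(rows) < 2:
        raise ValueError("need at least two rows")
    labels = tuple(rid for rid, _ in rows)
    seqs = [np.frombuffer(seq.encode(), dtype="S1") for _, seq in rows]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("rows must be aligned (equal length)")
    gaps = [np.isin(s, [b"-", b"."]) for s in seqs]
    n = len(rows)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        ok = ~(gaps[i] | gaps[j])
        comparable = int(ok.sum())
        if comparable == 0:
            raise ValueError(
                f"no comparable columns between {labels[i]} and {labels[j]}"
            )
        mismatches = int((seqs[i][ok] != seqs[j][ok]).sum())
        d[i, j] = d[j, i] = mismatches / comparable
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the lowest (i, j) label-index pair;
    negative branch lengths are clamped to zero with a warning. Returns an
    unrooted dendropy tree (trifurcation at the seed node).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    tns = dendropy.TaxonNamespace()
    nodes = []
    for label in dm.labels:
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label)
        nodes.append(node)
    active = list(range(n))
    d = dm.matrix.astype(float).copy()

    def clamp(value: float) -> float:
        if value < 0:
            warnings.warn(f"negative NJ branch length {value:.4g} clamped to 0")
            return 0.0
        return value

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = d[i, j]
        li = clamp(0.5 * dij + (sums[i] - sums[j]) / (2 * (r - 2)))
        lj = clamp(dij - (0.5 * dij + (sums[i] - sums[j]) / (2 * (r - 2))))
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # reuse slot i for the new node
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    root = dendropy.Node()
    li = clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    lj = clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    lk = clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].edge.length = length
        root.add_child(nodes[idx])
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def tree_from_rows(rows: Rows) -> dendropy.Tree:
    return neighbor_joining(p_distance(rows))


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson–Foulds (symmetric bipartition difference)."""
    leaves1 = {leaf.taxon.label for leaf in t1.leaf_node_iter()}
    leaves2 = {leaf.taxon.label for leaf in t2.leaf_node_iter()}
    if leaves1 != leaves2:
        raise ValueError(
            f"trees have different taxon sets: {sorted(leaves1 ^ leaves2)}"
        )
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.as_string(schema="newick"), schema="newick",
        taxon_namespace=tns,
    )
    b = dendropy.Tree.get(
        data=t2.as_string(schema="newick"), schema="newick",
        taxon_namespace=tns,
    )
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))


def monophyly(
    tree: dendropy.Tree, chars: Mapping[str, str], state: str
) -> bool:
    """True iff some edge bipartition isolates exactly the leaves in ``state``."""
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    unmapped = [l for l in leaves if l not in chars]
    if unmapped:
        raise ValueError(f"unmapped leaves: {unmapped}")
    target = {l for l in leaves if chars[l] == state}
    if not target:
        raise ValueError(f"state {state!r} absent from tree")
    all_leaves = set(leaves)
    if target == all_leaves:
        return True
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if below == target or (all_leaves - below) == target:
            return True
    return False


def fitch_min_changes(
    tree: dendropy.Tree, chars: Mapping[str, str]
) -> int:
    """Small-parsimony minimum number of state changes on the tree.

    Computed by unit-cost dynamic programming over observed states (Sankoff
    recursion), which handles multifurcating nodes exactly and is invariant
    to the (arbitrary) rooting. A single observed state costs 0.
    """
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    unmapped = [l for l in leaves if l not in chars]
    if unmapped:
        raise ValueError(f"unmapped leaves: {unmapped}")
    states = sorted({chars[l] for l in leaves})
    if len(states) < 2:
        return 0
    index = {s: k for k, s in enumerate(states)}
    inf = float("inf")

    def costs(node) -> list[float]:
        if node.is_leaf():
            state = index[chars[node.taxon.label]]
            return [0.0 if k == state else inf for k in range(len(states))]
        child_costs = [costs(child) for child in node.child_nodes()]
        out = []
        for k in range(len(states)):
            total = 0.0
            for cc in child_costs:
                total += min(
                    cc[k2] + (0 if k2 == k else 1)
                    for k2 in range(len(states))
                )
            out.append(total)
        return out

    return int(min(costs(tree.seed_node)))


def minimum_transfers(
    tree: dendropy.Tree, chars: Mapping[str, str]
) -> int:
    """Lower bound on horizontal transfers from tree/character incongruence.

    One state change is expected from the vertical divergence of the groups
    themselves; every additional parsimony change requires a transfer.
    """
    return max(0, fitch_min_changes(tree, chars) - 1)


def region_tree_congruence(
    alignments: Mapping[str, Rows],
) -> dict[tuple[str, str], int]:
    """Pairwise Robinson–Foulds distances between per-region NJ trees."""
    taxa = None
    trees = {}
    for region, rows in alignments.items():
        ids = sorted(rid for rid, _ in rows)
        if taxa is None:
            taxa = ids
        elif ids != taxa:
            raise ValueError(
                f"region {region!r} taxa differ: {sorted(set(ids) ^ set(taxa))}"
            )
        trees[region] = tree_from_rows(rows)
    out = {}
    for r1, r2 in combinations(sorted(trees), 2):
        out[(r1, r2)] = robinson_foulds(trees[r1], trees[r2])
    return out
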