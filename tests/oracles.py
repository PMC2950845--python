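"""Independent brute-force oracles used to validate the implementation.

Each oracle is written against the mathematical definition of the quantity,
deliberately avoiding the code path (and, where possible, the libraries) the
implementation uses.
"""

from itertools import combinations, product

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
BLOSUM62 = {
    (a, b): int(_B62[a, b]) for a in _B62.alphabet for b in _B62.alphabet
}
for aa in _B62.alphabet:
    BLOSUM62[("X", aa)] = 0
    BLOSUM62[(aa, "X")] = 0


def sw_score(query, subject, gap_open=11, gap_extend=1):
    """Plain O(mn) Gotoh local-alignment score, BLAST gap convention
    (a gap of length k costs gap_open + k*gap_extend)."""
    m, n = len(query), len(subject)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    first_gap = gap_open + gap_extend
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - first_gap, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first_gap, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + BLOSUM62[(query[i - 1], subject[j - 1])],
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return int(best)


def edn_edges_brute(compositions):
    """All unordered node pairs with |A symmetric-difference B| == 1."""
    nodes = sorted({c for c in compositions}, key=sorted)
    edges = set()
    for a, b in combinations(nodes, 2):
        if len(a ^ b) == 1:
            edges.add(frozenset((a, b)))
    return edges


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


def components_brute(nodes, edges):
    uf = UnionFind(nodes)
    for a, b in edges:
        uf.union(a, b)
    groups = {}
    for node in nodes:
        groups.setdefault(uf.find(node), set()).add(node)
    return {frozenset(g) for g in groups.values()}


def parsimony_brute(tree, chars):
    """Minimum changes by exhaustive assignment over internal-node states."""
    states = sorted(set(chars.values()))
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaf_state = {
        id(leaf): chars[leaf.taxon.label] for leaf in tree.leaf_node_iter()
    }
    best = None
    for assignment in product(states, repeat=len(internals)):
        state_of = dict(leaf_state)
        for node, s in zip(internals, assignment):
            state_of[id(node)] = s
        changes = 0
        for node in tree.preorder_node_iter():
            for child in node.child_nodes():
                if state_of[id(node)] != state_of[id(child)]:
                    changes += 1
        if best is None or changes < best:
            best = changes
    return best


def monophyly_brute(tree, chars, state):
    """Exhaustive bipartition check on small trees."""
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    target = frozenset(l for l in leaves if chars[l] == state)
    if target == frozenset(leaves):
        return True
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        splits.add(below)
        splits.add(frozenset(leaves) - below)
    return target in splits


def conservation_counts_brute(rows, start, end, strong_groups, weak_groups):
    """Per-column conservation recount by direct looping."""
    counts = {"identical": 0, "strong": 0, "weak": 0, "none": 0}
    for j in range(start, end):
        column = [row[j] for row in rows]
        if "-" in column or "." in column:
            counts["none"] += 1
            continue
        residues = set(column)
        if len(residues) == 1:
            counts["identical"] += 1
        elif any(residues <= set(g) for g in strong_groups):
            counts["strong"] += 1
        elif any(residues <= set(g) for g in weak_groups):
            counts["weak"] += 1
        else:
            counts["none"] += 1
    return counts


def bfs_path(adjacency, source, target):
    """Shortest path by plain breadth-first search; None when unreachable."""
    if source == target:
        return [source]
    seen = {source: None}
    frontier = [source]
    while frontier:
        nxt = []
        for node in frontier:
            for neigh in adjacency.get(node, ()):
                if neigh in seen:
                    continue
                seen[neigh] = node
                if neigh == target:
                    path = [neigh]
                    while seen[path[-1]] is not None:
                        path.append(seen[path[-1]])
                    return path[::-1]
                nxt.append(neigh)
        frontier = nxt
    return None
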