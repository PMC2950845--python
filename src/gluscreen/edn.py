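"""Evolutionary Domain Network (EDN).

Proteins are grouped into nodes by domain composition — the *set* of
functional-domain accessions annotated on them (copy number and coordinates
are ignored; overlapping domains are retained as distinct accessions). Edges
join compositions that differ by the addition or subtraction of exactly one
domain, i.e. |A Δ B| = 1; rows index nodes by composition size. Tie lines
sketch plausible single-step domain recombination, not verified events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx

DEFAULT_DOMAIN_EVALUE = 1e-3


class DomainTableError(ValueError):
    """Malformed domain-annotation TSV row."""


@dataclass(frozen=True)
class DomainComposition:
    protein_id: str
    domains: frozenset[str]

    @property
    def is_empty(self) -> bool:
        return not self.domains


def node_id(domains: frozenset[str]) -> str:
    """Stable printable identifier: sorted accessions joined by '+'."""
    return "+".join(sorted(domains)) if domains else "(none)"


def compose(
    path: str | Path,
    proteins: Optional[Sequence[str]] = None,
    evalue_threshold: float = DEFAULT_DOMAIN_EVALUE,
) -> list[DomainComposition]:
    """Read an InterProScan-style TSV into one composition per protein.

    Expected columns: protein_id, domain_accession, start, end, evalue
    (header optional). Annotations weaker than ``evalue_threshold`` are
    excluded. Intervals are ignored for composition. ``proteins`` — when
    given — defines the full protein universe: ids without surviving
    annotations are kept with an empty composition, and rows referencing
    unknown ids are an error.
    """
    domains: dict[str, set[str]] = {p: set() for p in (proteins or [])}
    order: list[str] = list(proteins or [])
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "protein_id":
                continue
            if len(parts) < 5:
                raise DomainTableError(
                    f"line {lineno}: expected 5 columns, got {len(parts)}"
                )
            pid, accession, start, end, evalue = parts[:5]
            try:
                int(start), int(end)
                evalue_f = float(evalue)
            except ValueError as exc:
                raise DomainTableError(f"line {lineno}: {exc}") from exc
            if proteins is not None and pid not in domains:
                raise DomainTableError(
                    f"line {lineno}: unknown protein {pid!r}"
                )
            if pid not in domains:
                domains[pid] = set()
                order.append(pid)
            if evalue_f <= evalue_threshold:
                domains[pid].add(accession)
    return [DomainComposition(pid, frozenset(domains[pid])) for pid in order]


@dataclass
class EDNGraph:
    """Nodes are distinct domain sets; edges join single-step neighbours."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> list[frozenset[str]]:
        return sorted(self.graph.nodes, key=node_id)

    @property
    def edges(self) -> list[tuple[frozenset[str], frozenset[str]]]:
        out = []
        for a, b in self.graph.edges:
            a, b = sorted((a, b), key=node_id)
            out.append((a, b))
        return sorted(out, key=lambda e: (node_id(e[0]), node_id(e[1])))

    def members(self, node: frozenset[str]) -> list[str]:
        return self.graph.nodes[node]["members"]

    @property
    def rows(self) -> dict[int, list[frozenset[str]]]:
        rows: dict[int, list[frozenset[str]]] = {}
        for node in self.nodes:
            rows.setdefault(len(node), []).append(node)
        return rows


def build_edn(compositions: Sequence[DomainComposition]) -> EDNGraph:
    """Build the network over the distinct compositions.

    Since |A Δ B| = 1 forces one set to be the other plus one domain, edges
    are found by single-domain-removal lookups rather than all-pairs
    comparison (the all-pairs criterion is the test oracle).
    """
    if not compositions:
        raise ValueError("need at least one composition")
    graph = nx.Graph()
    for comp in compositions:
        if comp.domains not in graph:
            graph.add_node(comp.domains, members=[])
        graph.nodes[comp.domains]["members"].append(comp.protein_id)
    for node in list(graph.nodes):
        for domain in node:
            smaller = node - {domain}
            if smaller in graph:
                graph.add_edge(node, smaller)
    for node in graph.nodes:
        graph.nodes[node]["members"].sort()
    return EDNGraph(graph)


def components(edn: EDNGraph) -> list[list[frozenset[str]]]:
    """Connected components, each sorted, ordered by smallest node id."""
    comps = [
        sorted(comp, key=node_id)
        for comp in nx.connected_components(edn.graph)
    ]
    return sorted(comps, key=lambda comp: node_id(comp[0]))


def exchange_path(
    edn: Optional[EDNGraph],
    source: frozenset[str],
    target: frozenset[str],
    allow_virtual: bool = False,
) -> Optional[list[tuple[str, str]]]:
    """Shortest sequence of single-domain steps turning source into target.

    Steps are ("remove", accession) / ("add", accession). With
    ``allow_virtual`` intermediates need not be observed nodes (missing
    intermediates may have vanished or may simply be unsequenced) and the
    path length equals |source Δ target|. Without it, the path must run
    along observed network edges; returns None when no such path exists.
    """
    source, target = frozenset(source), frozenset(target)
    if not source or not target:
        raise ValueError("source and target must be non-empty")
    if allow_virtual:
        steps = [("remove", d) for d in sorted(source - target)]
        steps += [("add", d) for d in sorted(target - source)]
        return steps
    if edn is None:
        raise ValueError("observed-path search requires a graph")
    if source not in edn.graph or target not in edn.graph:
        return None
    try:
        node_path = nx.shortest_path(edn.graph, source, target)
    except nx.NetworkXNoPath:
        return None
    steps = []
    for a, b in zip(node_path, node_path[1:]):
        (diff,) = a.symmetric_difference(b)
        steps.append(("remove", diff) if diff in a else ("add", diff))
    return steps


def write_edge_tsv(edn: EDNGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\n")
        for a, b in edn.edges:
            fh.write(f"{node_id(a)}\t{node_id(b)}\n")


def to_dot(edn: EDNGraph) -> str:
    lines = ["graph EDN {"]
    for node in edn.nodes:
        members = ",".join(edn.members(node))
        lines.append(f'  "{node_id(node)}" [label="{node_id(node)}\\n{members}"];')
    for a, b in edn.edges:
        lines.append(f'  "{node_id(a)}" -- "{node_id(b)}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
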