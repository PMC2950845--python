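"""Reciprocal-best-hit orthology and probe retrieval ratios.

Two sequences are called orthologs when each is the other's best
cross-proteome hit ("reciprocal best hits"): best = lowest E-value, ties
broken by highest raw score, then lexicographic id. Retrieval ratios measure
how much of a reference set (e.g. the human receptor list) a single probe
recovers at a permissive E-value cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import ScoringParams, database_length, estimate_evalue, smith_waterman
from .records import ProteinRecord


@dataclass(frozen=True)
class OrthologPair:
    id_a: str
    id_b: str
    evalue_ab: float
    evalue_ba: float


@dataclass
class OrthologReport:
    pairs: list[OrthologPair] = field(default_factory=list)

    @property
    def pair_ids(self) -> set[tuple[str, str]]:
        return {(p.id_a, p.id_b) for p in self.pairs}


def _best_hits(
    queries: Sequence[ProteinRecord],
    subjects: Sequence[ProteinRecord],
    params: ScoringParams,
) -> dict[str, tuple[str, float]]:
    """Best subject per query (id, E-value), None-filtered by threshold."""
    n = database_length(list(subjects))
    best: dict[str, tuple[str, float]] = {}
    for q in queries:
        ranked = []
        for s in subjects:
            hit = smith_waterman(q.sequence, s.sequence, params)
            evalue = estimate_evalue(hit.raw_score, len(q), n, params)
            if evalue < params.evalue_threshold:
                ranked.append((evalue, -hit.raw_score, s.protein_id))
        if ranked:
            evalue, _, sid = min(ranked)
            best[q.protein_id] = (sid, evalue)
    return best


def reciprocal_best_hits(
    proteome_a: Sequence[ProteinRecord],
    proteome_b: Sequence[ProteinRecord],
    params: Optional[ScoringParams] = None,
) -> OrthologReport:
    """Ortholog pairs between two proteomes by the reciprocal-best-hit rule.

    Swapping the argument order transposes the pairs but changes nothing
    else. Queries without any hit under the E-value threshold are excluded.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    params = params or ScoringParams()
    a_best = _best_hits(proteome_a, proteome_b, params)
    b_best = _best_hits(proteome_b, proteome_a, params)
    pairs = []
    for id_a in sorted(a_best):
        id_b, evalue_ab = a_best[id_a]
        back = b_best.get(id_b)
        if back is not None and back[0] == id_a:
            pairs.append(OrthologPair(id_a, id_b, evalue_ab, back[1]))
    return OrthologReport(pairs)


def retrieval_ratio(
    probe: ProteinRecord,
    reference: Sequence[ProteinRecord],
    params: Optional[ScoringParams] = None,
) -> tuple[int, int]:
    """(hits, reference size): reference entries the probe hits at E < cutoff.

    The search space n is the total residue count of the reference set.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    params = params or ScoringParams()
    n = database_length(list(reference))
    hits = 0
    for ref in reference:
        hit = smith_waterman(probe.sequence, ref.sequence, params)
        if estimate_evalue(hit.raw_score, len(probe), n, params) < params.evalue_threshold:
            hits += 1
    return hits, len(reference)


def write_ortholog_tsv(report: OrthologReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tevalue_ab\tevalue_ba\n")
        for p in report.pairs:
            fh.write(
                f"{p.id_a}\t{p.id_b}\t{p.evalue_ab:.6g}\t{p.evalue_ba:.6g}\n"
            )
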