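"""End-to-end orchestration: screen -> classify -> EDN -> conservation ->
trees -> orthologs, with machine-readable reporting.

Every intermediate result is written as plain text (TSV/FASTA/Newick) and the
run is summarized in a deterministic ``report.json``; identical config and
seed reproduce the report byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

from . import __version__
from .align import ScoringParams
from .conservation import join_alignments, summarize, write_summary_tsv
from .edn import build_edn, components, compose, write_edge_tsv
from .msa import align_star
from .orthology import reciprocal_best_hits, write_ortholog_tsv
from .phylo import region_tree_congruence, tree_from_rows
from .records import read_fasta, read_lineage
from .screen import run_screen, write_hits_tsv
from .topology import (
    K_FILTER_PATTERN,
    classify_screen_survivors,
    write_classification_tsv,
    write_topology_tsv,
)

logger = logging.getLogger("gluscreen")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    input_fasta: str
    lineage_tsv: str
    output_dir: str
    domain_tsv: Optional[str] = None
    reference_fasta: Optional[str] = None
    evalue: float = 10.0
    min_tm: int = 2
    tm_window: int = 19
    tm_threshold: float = 1.6
    k_filter_pattern: str = K_FILTER_PATTERN
    domain_evalue: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("evalue", "min_tm", "tm_window", "tm_threshold",
                     "domain_evalue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written as
    ``report.json`` under the output directory)."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = ScoringParams(evalue_threshold=config.evalue)

    @_stage("load")
    def load():
        db = read_fasta(config.input_fasta)
        if not db:
            raise ValueError(f"input FASTA {config.input_fasta} is empty")
        return db, read_lineage(config.lineage_tsv)

    db, lineage = load()

    @_stage("screen")
    def screen():
        result = run_screen(
            db, lineage, params, min_tm=config.min_tm,
            tm_window=config.tm_window, tm_threshold=config.tm_threshold,
        )
        write_hits_tsv(result, out_dir / "hits.tsv")
        return result

    screen_result = screen()

    @_stage("classify")
    def classify():
        profiles = classify_screen_survivors(
            db, screen_result, config.k_filter_pattern
        )
        write_topology_tsv(profiles, out_dir / "topology.tsv")
        write_classification_tsv(profiles, out_dir / "classification.tsv")
        return profiles

    profiles = classify()
    channels = [p for p in profiles if p.is_channel]
    by_id = {rec.protein_id: rec for rec in db}

    report = {
        "tool": "gluscreen",
        "version": __version__,
        "config": asdict(config),
        "stage_counts": screen_result.stage_counts,
        "channels": {
            "total": len(channels),
            "group1": sorted(
                p.protein_id for p in channels if p.group == 1
            ),
            "group2": sorted(
                p.protein_id for p in channels if p.group == 2
            ),
            "without_signal_peptide": sorted(
                p.protein_id for p in channels if not p.has_signal_peptide
            ),
        },
    }

    if config.domain_tsv:
        @_stage("edn")
        def edn_stage():
            comps = compose(
                config.domain_tsv,
                proteins=sorted(by_id),
                evalue_threshold=config.domain_evalue,
            )
            graph = build_edn(comps)
            write_edge_tsv(graph, out_dir / "edn_edges.tsv")
            return {
                "nodes": len(graph.nodes),
                "edges": len(graph.edges),
                "components": len(components(graph)),
            }

        report["edn"] = edn_stage()

    @_stage("conservation")
    def conservation_stage():
        summaries = {}
        region_rows_by_group = {}
        for group in (1, 2):
            members = [p for p in channels if p.group == group]
            if len(members) < 2:
                continue
            per_region = {}
            for region_name, types in (
                ("S1", ("S1",)), ("channel", ("M1", "P", "M2")),
                ("S2", ("S2",)),
            ):
                rows = []
                for p in members:
                    pieces = []
                    for t in types:
                        r = p.region(t)
                        pieces.append(
                            by_id[p.protein_id].sequence[r.start:r.end]
                        )
                    rows.append((p.protein_id, "".join(pieces)))
                per_region[region_name] = align_star(rows)
            region_rows_by_group[group] = per_region
            joined = join_alignments(per_region)
            summaries[f"group{group}"] = summarize(joined)
        if summaries:
            write_summary_tsv(summaries, out_dir / "conservation.tsv")
        return summaries, region_rows_by_group

    summaries, region_rows_by_group = conservation_stage()
    report["conservation"] = {
        group: dict(summary.regions)
        for group, summary in summaries.items()
    }

    @_stage("phylo")
    def phylo_stage():
        tree_files = []
        congruence = {}
        for group, per_region in region_rows_by_group.items():
            taxa_counts = {len(rows) for rows in per_region.values()}
            if min(taxa_counts) < 3:
                continue
            for region, rows in per_region.items():
                tree = tree_from_rows(rows)
                path = out_dir / f"group{group}_{region}.nwk"
                tree.write(path=str(path), schema="newick")
                tree_files.append(path.name)
            rf = region_tree_congruence(per_region)
            congruence[f"group{group}"] = {
                f"{a}~{b}": v for (a, b), v in rf.items()
            }
        return {"tree_files": sorted(tree_files), "rf_distances": congruence}

    report["phylo"] = phylo_stage()

    if config.reference_fasta:
        @_stage("orthologs")
        def ortholog_stage():
            reference = read_fasta(config.reference_fasta)
            channel_records = [by_id[p.protein_id] for p in channels]
            if not channel_records:
                return {"pairs": 0}
            rbh = reciprocal_best_hits(channel_records, reference, params)
            write_ortholog_tsv(rbh, out_dir / "orthologs.tsv")
            return {"pairs": len(rbh.pairs)}

        report["orthologs"] = ortholog_stage()

    validate_report(report)
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report


def validate_report(report: dict) -> None:
    """Internal consistency checks on a run report."""
    counts = report["stage_counts"]
    for probe in ("s1", "s2"):
        cascade = [counts[f"stage{k}_{probe}"] for k in (1, 2, 3)]
        if not all(a >= b for a, b in zip(cascade, cascade[1:])):
            raise PipelineError("report", f"stage counts not monotone: {cascade}")
    if counts["stage4_both"] > min(counts["stage3_s1"], counts["stage3_s2"]):
        raise PipelineError("report", "stage4 exceeds stage3 intersection bound")
    ch = report["channels"]
    if len(ch["group1"]) + len(ch["group2"]) != ch["total"]:
        raise PipelineError("report", "group1 + group2 != channels")
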