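"""Stages 1-4 of the discovery screen.

Stage 1: probe-based local-alignment search with an E-value cutoff (separately
for the S1 and S2 halves of the glutamate-binding domain). Stage 2: discard
sequences with fewer than ``min_tm`` predicted transmembrane helices — the
minimum compatible with the channel architecture. Stage 3: keep prokaryotes.
Stage 4: keep proteins hit by both probes.

Transmembrane prediction is a documented hydropathy surrogate: sliding-window
mean Kyte–Doolittle hydropathy with a logistic "TM probability" score. A
segment passes the TM test when its probability is >= 0.5, i.e. its mean
hydropathy reaches the window threshold; sub-threshold ("shaded") candidates
between helices are retained for pore-loop detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .align import AlignmentHit, ScoringParams, database_length, smith_waterman
from .fixtures import load_probes
from .records import ProteinRecord

PROKARYOTE_SUPERKINGDOMS = frozenset({"Bacteria", "Archaea"})

#: defaults of the hydropathy TM surrogate
TM_WINDOW = 19
TM_THRESHOLD = 1.6  # mean KD hydropathy at which a window counts as TM-like
PORE_WINDOW = 9  # shorter window used for partial (re-entrant) segments
PASS_PROBABILITY = 0.5  # logistic(0) — mean hydropathy exactly at threshold


class MissingLineageError(KeyError):
    """A surviving protein has no taxonomy lineage entry."""


@dataclass(frozen=True)
class TMSegment:
    """A membrane-like hydrophobic segment (full or partial helix)."""

    interval: tuple[int, int]
    probability_score: float
    passes_test: bool

    @property
    def start(self) -> int:
        return self.interval[0]

    @property
    def end(self) -> int:
        return self.interval[1]


def hydropathy_profile(seq: str, window: int) -> np.ndarray:
    """Sliding-window mean Kyte-Doolittle hydropathy.

    Entry i is the mean over ``seq[i:i+window]``; unknown residues score 0.
    """
    values = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in seq])
    if len(values) < window:
        return np.empty(0)
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


def _logistic(mean_hydropathy: float, threshold: float) -> float:
    return 1.0 / (1.0 + math.exp(-2.0 * (mean_hydropathy - threshold)))


def probability_floor_to_mean(p_lo: float, threshold: float) -> float:
    """Mean hydropathy at which the logistic score equals ``p_lo``."""
    return threshold - 0.5 * math.log(1.0 / p_lo - 1.0)


def _runs(mask: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Maximal True runs over window-start indices, merging gaps < merge_gap."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    runs = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i - prev - 1 < merge_gap:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def predict_tm_segments(
    seq: str,
    window: int = TM_WINDOW,
    threshold: float = TM_THRESHOLD,
    candidate_floor: float = 0.25,
    pore_window: int = PORE_WINDOW,
) -> list[TMSegment]:
    """Predict membrane-like segments by windowed hydropathy.

    Full helices are maximal runs of ``window``-mean hydropathy >= threshold
    (gap < 3 merged); these pass the TM test. Regions outside passing helices
    are rescanned with the shorter ``pore_window`` for sub-threshold partial
    segments whose logistic score falls in [candidate_floor, 0.5); these are
    reported with ``passes_test=False``. A sequence shorter than ``window``
    yields no segments.
    """
    if window < 7 or window % 2 == 0:
        raise ValueError("window must be odd and >= 7")
    profile = hydropathy_profile(seq, window)
    if profile.size == 0:
        return []

    def span(first: int, last: int, w: int) -> tuple[int, int]:
        # center span of the qualifying windows, padded out to the window
        # length when the run is short (a single window localizes a full
        # helix around its center)
        core = (first + w // 2, last + w // 2 + 1)
        short = w - (core[1] - core[0])
        if short > 0:
            left = short // 2
            return (max(0, core[0] - left),
                    min(len(seq), core[1] + (short - left)))
        return core

    segments: list[TMSegment] = []
    covered = np.zeros(len(seq), dtype=bool)
    for first, last in _runs(profile >= threshold, merge_gap=3):
        start, end = span(first, last, window)
        mean = float(profile[first:last + 1].mean())
        segments.append(
            TMSegment((start, end), _logistic(mean, threshold), True)
        )
        covered[start:end] = True

    sub_profile = hydropathy_profile(seq, pore_window)
    if sub_profile.size:
        floor_mean = probability_floor_to_mean(candidate_floor, threshold)
        # a candidate window must lie entirely outside passing helices
        free = np.array([
            not covered[i:i + pore_window].any()
            for i in range(len(sub_profile))
        ])
        for first, last in _runs((sub_profile >= floor_mean) & free, 3):
            mean = float(sub_profile[first:last + 1].mean())
            prob = _logistic(mean, threshold)
            if prob < PASS_PROBABILITY:
                segments.append(
                    TMSegment(span(first, last, pore_window), prob, False)
                )
    segments.sort(key=lambda s: s.interval)
    return segments


def count_passing(segments: Sequence[TMSegment]) -> int:
    return sum(1 for s in segments if s.passes_test)


def screen_probe(
    probe: str,
    db: Sequence[ProteinRecord],
    params: Optional[ScoringParams] = None,
    probe_label: str = "",
) -> list[AlignmentHit]:
    """All database hits of ``probe`` with E-value below the threshold.

    The search space n is the total residue count of the database (BLAST
    convention); output is sorted by ascending E-value, ties by protein_id.
    """
    if not db:
        raise ValueError("database must be non-empty")
    params = params or ScoringParams()
    n = database_length(list(db))
    from .align import estimate_evalue  # local import to avoid cycle noise

    hits = []
    for rec in db:
        hit = smith_waterman(probe, rec.sequence, params, rec.protein_id,
                             probe_label)
        evalue = estimate_evalue(hit.raw_score, len(probe), n, params)
        hit = AlignmentHit(
            rec.protein_id, probe_label, hit.raw_score, evalue,
            hit.subject_interval, hit.query_interval,
        )
        if evalue < params.evalue_threshold:
            hits.append(hit)
    hits.sort(key=lambda h: (h.evalue, h.protein_id))
    return hits


@dataclass
class ScreenResult:
    """Per-stage survivor sets, hits and TM predictions of one screen run."""

    stage1_s1: set[str] = field(default_factory=set)
    stage1_s2: set[str] = field(default_factory=set)
    stage2_s1: set[str] = field(default_factory=set)
    stage2_s2: set[str] = field(default_factory=set)
    stage3_s1: set[str] = field(default_factory=set)
    stage3_s2: set[str] = field(default_factory=set)
    stage4_both: set[str] = field(default_factory=set)
    hits: dict[str, dict[str, AlignmentHit]] = field(default_factory=dict)
    tm_segments: dict[str, list[TMSegment]] = field(default_factory=dict)

    @property
    def stage_counts(self) -> dict[str, int]:
        return {
            "stage1_s1": len(self.stage1_s1),
            "stage1_s2": len(self.stage1_s2),
            "stage2_s1": len(self.stage2_s1),
            "stage2_s2": len(self.stage2_s2),
            "stage3_s1": len(self.stage3_s1),
            "stage3_s2": len(self.stage3_s2),
            "stage4_both": len(self.stage4_both),
        }


def run_screen(
    db: Sequence[ProteinRecord],
    taxonomy: Mapping[str, Mapping[str, str]],
    params: Optional[ScoringParams] = None,
    probes=None,
    min_tm: int = 2,
    tm_window: int = TM_WINDOW,
    tm_threshold: float = TM_THRESHOLD,
) -> ScreenResult:
    """Run stages 1-4 of the discovery cascade over ``db``.

    ``taxonomy`` maps protein_id to a lineage dict with a ``superkingdom``
    key; a survivor without a lineage entry is an error (never silently
    treated as eukaryotic).
    """
    params = params or ScoringParams()
    probes = probes or load_probes()
    result = ScreenResult()

    for label, probe in (("S1", probes.s1_sequence), ("S2", probes.s2_sequence)):
        for hit in screen_probe(probe, db, params, label):
            result.hits.setdefault(hit.protein_id, {})[label] = hit
            getattr(result, "stage1_s1" if label == "S1" else "stage1_s2").add(
                hit.protein_id
            )

    by_id = {rec.protein_id: rec for rec in db}
    for pid in sorted(result.stage1_s1 | result.stage1_s2):
        result.tm_segments[pid] = predict_tm_segments(
            by_id[pid].sequence, tm_window, tm_threshold
        )

    for probe_attr in ("s1", "s2"):
        stage1 = getattr(result, f"stage1_{probe_attr}")
        stage2 = {
            pid for pid in stage1
            if count_passing(result.tm_segments[pid]) >= min_tm
        }
        setattr(result, f"stage2_{probe_attr}", stage2)
        stage3 = set()
        for pid in stage2:
            if pid not in taxonomy:
                raise MissingLineageError(
                    f"no taxonomy lineage for surviving protein {pid!r}"
                )
            if taxonomy[pid]["superkingdom"] in PROKARYOTE_SUPERKINGDOMS:
                stage3.add(pid)
        setattr(result, f"stage3_{probe_attr}", stage3)

    result.stage4_both = result.stage3_s1 & result.stage3_s2
    return result


def write_hits_tsv(result: ScreenResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tprobe\tscore\tevalue\tstart\tend\n")
        for pid in sorted(result.hits):
            for label in ("S1", "S2"):
                hit = result.hits[pid].get(label)
                if hit is None:
                    continue
                s, e = hit.subject_interval
                fh.write(
                    f"{pid}\t{label}\t{hit.raw_score}\t{hit.evalue:.6g}"
                    f"\t{s}\t{e}\n"
                )
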