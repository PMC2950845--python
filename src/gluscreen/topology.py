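"""Stage 5 and validation: channel topology, Group 1/2 typing, signal peptides.

A protein has channel topology when its annotated regions occur in the
canonical order S1 - M1 - P - M2 - S2: the two halves of the glutamate-binding
domain flank two full transmembrane helices, which in turn flank a re-entrant
pore-loop (a partial, sub-threshold membrane segment). Channels whose pore
carries a potassium-type selectivity-filter motif form Group 1; channels
without it form Group 2.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

from .align import AlignmentHit
from .records import ProteinRecord, RegionAnnotation
from .screen import (
    PASS_PROBABILITY,
    ScreenResult,
    TMSegment,
    hydropathy_profile,
)

#: K-channel selectivity filter signature (canonical filter: TVGYG) with a
#: permissive fallback on the invariant GYG core. Published work names the
#: filter but never prints a pattern, so the definition is ours and
#: configurable.
K_FILTER_PATTERN = r"[TS].[GA][YF]G"
K_FILTER_FALLBACK = r"G[YF]G"

GROUP1_ANNOTATION = "putative glutamate-sensitive potassium channel"
GROUP2_ANNOTATION = "putative glutamate-sensitive ion channel"

SIGNAL_SEARCH_SPAN = 25  # N-terminal residues examined for the core
SIGNAL_CORE_WINDOW = 7
SIGNAL_CORE_THRESHOLD = 1.8
SIGNAL_CORE_MAX_START = 10  # h-region must directly follow the n-region
POSITIVE_RESIDUES = frozenset("KR")


@dataclass(frozen=True)
class TopologyProfile:
    """Ordered region annotations plus channel/group classification."""

    protein_id: str
    regions: tuple[RegionAnnotation, ...]
    is_channel: bool
    group: Optional[int] = None  # 1, 2 or None
    has_signal_peptide: bool = False
    suggested_annotation: str = ""

    def __post_init__(self) -> None:
        starts = [r.start for r in self.regions]
        if starts != sorted(starts):
            raise ValueError(f"{self.protein_id}: regions not sorted by start")
        if self.group is not None and not self.is_channel:
            raise ValueError(f"{self.protein_id}: group set on non-channel")

    def region(self, region_type: str) -> Optional[RegionAnnotation]:
        for r in self.regions:
            if r.region_type == region_type:
                return r
        return None


def detect_pore_loop(
    seq: str,
    tm_segments: Sequence[TMSegment],
    p_lo: float = 0.25,
) -> Optional[RegionAnnotation]:
    """Best sub-threshold membrane-like segment between the two flanking TMs.

    ``tm_segments`` must contain at least two passing helices; the candidate
    is searched strictly between the first and last passing helix and must
    score in [p_lo, 0.5) — hydrophobic enough to be pore-like, below the full
    TM test. Returns None when no such segment exists.
    """
    passing = [s for s in tm_segments if s.passes_test]
    if len(passing) < 2:
        raise ValueError("pore-loop detection requires >= 2 passing TM helices")
    left, right = passing[0], passing[-1]
    candidates = [
        s for s in tm_segments
        if not s.passes_test
        and s.start >= left.end
        and s.end <= right.start
        and p_lo <= s.probability_score < PASS_PROBABILITY
    ]
    if not candidates:
        return None
    best = max(candidates, key=lambda s: (s.probability_score, -s.start))
    return RegionAnnotation("P", best.start, best.end, best.probability_score)


def classify_topology(
    protein: ProteinRecord,
    s1: AlignmentHit,
    s2: AlignmentHit,
    tm_segments: Sequence[TMSegment],
    pore: Optional[RegionAnnotation] = None,
    check_signal: bool = True,
) -> TopologyProfile:
    """Decide whether the annotated regions form the channel topology.

    The channel predicate requires end(S1) <= start(M1) < end(M1) <= start(P)
    < end(P) <= start(M2) < end(M2) <= start(S2). With more than two passing
    helices (e.g. an extra C-terminal helix, as in the eukaryotic receptors),
    M1/M2 are chosen as the pair maximizing containment between the S1 end and
    the S2 start, so extra helices do not break classification.
    """
    s1_iv, s2_iv = s1.subject_interval, s2.subject_interval
    if max(s1_iv[0], s2_iv[0]) < min(s1_iv[1], s2_iv[1]):
        raise ValueError(
            f"{protein.protein_id}: overlapping S1/S2 hits {s1_iv} vs {s2_iv}"
        )
    regions = [
        RegionAnnotation("S1", *s1_iv, s1.evalue),
        RegionAnnotation("S2", *s2_iv, s2.evalue),
    ]
    signal = signal_peptide_region(protein.sequence) if check_signal else None
    has_signal = signal is not None
    if signal is not None and signal.end <= min(s1_iv[0], s2_iv[0]):
        regions.append(signal)

    is_channel = False
    if s1_iv[1] <= s2_iv[0]:
        inner = [
            s for s in tm_segments
            if s.passes_test and s.start >= s1_iv[1] and s.end <= s2_iv[0]
        ]
        if len(inner) >= 2:
            m1, m2 = inner[0], inner[-1]  # outermost pair: maximal containment
            if pore is None:
                pore = detect_pore_loop(protein.sequence, [m1, m2] + [
                    s for s in tm_segments if not s.passes_test
                ])
            if (
                pore is not None
                and m1.end <= pore.start
                and pore.end <= m2.start
            ):
                regions.append(RegionAnnotation("M1", *m1.interval,
                                                m1.probability_score))
                regions.append(pore)
                regions.append(RegionAnnotation("M2", *m2.interval,
                                                m2.probability_score))
                is_channel = True
    regions.sort(key=lambda r: (r.start, r.end))
    return TopologyProfile(
        protein.protein_id, tuple(regions), is_channel,
        has_signal_peptide=has_signal,
    )


def detect_k_filter(
    pore_sequence: str, pattern: str = K_FILTER_PATTERN,
    fallback: str = K_FILTER_FALLBACK,
) -> bool:
    """True when the pore region matches the K-channel signature."""
    return bool(
        re.search(pattern, pore_sequence)
        or (fallback and re.search(fallback, pore_sequence))
    )


def detect_signal_peptide(seq: str) -> bool:
    """Heuristic N-terminal signal-peptide test (documented stand-in).

    True iff the first 25 residues contain a hydrophobic core (some 7-residue
    window with mean Kyte-Doolittle hydropathy >= 1.8, starting no later than
    position 10 so the h-region directly follows the charged n-region)
    preceded by at least one positively charged residue within the first five
    positions.
    """
    if len(seq) < 30:
        warnings.warn("sequence shorter than 30 aa: signal test unreliable")
        return False
    if not POSITIVE_RESIDUES & set(seq[:5]):
        return False
    prof = hydropathy_profile(seq[:SIGNAL_SEARCH_SPAN], SIGNAL_CORE_WINDOW)
    prof = prof[:SIGNAL_CORE_MAX_START + 1]
    return bool(prof.size and prof.max() >= SIGNAL_CORE_THRESHOLD)


def signal_peptide_region(seq: str) -> Optional[RegionAnnotation]:
    """Locate the signal peptide, when present, as [0, core end).

    The reported extent runs from the N-terminus to the end of the last
    qualifying hydrophobic-core window, a conventional proxy for the
    pre-cleavage region.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if not detect_signal_peptide(seq):
            return None
    prof = hydropathy_profile(seq[:SIGNAL_SEARCH_SPAN], SIGNAL_CORE_WINDOW)
    qualifying = [
        i for i, mean in enumerate(prof[:SIGNAL_CORE_MAX_START + 1])
        if mean >= SIGNAL_CORE_THRESHOLD
    ]
    end = qualifying[-1] + SIGNAL_CORE_WINDOW
    return RegionAnnotation("SIGNAL", 0, end, float(prof[qualifying[-1]]))


def assign_groups(
    profiles: Sequence[TopologyProfile],
    sequences: Mapping[str, str],
    pattern: str = K_FILTER_PATTERN,
) -> list[TopologyProfile]:
    """Split channel-topology proteins into Group 1 / Group 2.

    Group 1: channel topology and a potassium-type selectivity filter in the
    pore region; Group 2: channel topology without it; everything else stays
    ungrouped. The suggested free-text annotation mirrors the study's wording.
    """
    out = []
    for profile in profiles:
        if not profile.is_channel:
            out.append(replace(profile, group=None, suggested_annotation=""))
            continue
        pore = profile.region("P")
        pore_seq = sequences[profile.protein_id][pore.start:pore.end]
        if detect_k_filter(pore_seq, pattern):
            out.append(replace(
                profile, group=1, suggested_annotation=GROUP1_ANNOTATION
            ))
        else:
            out.append(replace(
                profile, group=2, suggested_annotation=GROUP2_ANNOTATION
            ))
    return out


def classify_screen_survivors(
    db: Sequence[ProteinRecord],
    screen: ScreenResult,
    pattern: str = K_FILTER_PATTERN,
) -> list[TopologyProfile]:
    """Classify every stage-4 survivor of a screen run and assign groups."""
    by_id = {rec.protein_id: rec for rec in db}
    profiles = []
    for pid in sorted(screen.stage4_both):
        profiles.append(classify_topology(
            by_id[pid],
            screen.hits[pid]["S1"],
            screen.hits[pid]["S2"],
            screen.tm_segments[pid],
        ))
    return assign_groups(
        profiles, {rec.protein_id: rec.sequence for rec in db}, pattern
    )


def write_classification_tsv(profiles: Sequence[TopologyProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "protein_id\tis_channel\tgroup\thas_signal_peptide"
            "\tsuggested_annotation\n"
        )
        for p in sorted(profiles, key=lambda p: p.protein_id):
            group = p.group if p.group is not None else "none"
            fh.write(
                f"{p.protein_id}\t{int(p.is_channel)}\t{group}"
                f"\t{int(p.has_signal_peptide)}\t{p.suggested_annotation}\n"
            )


def write_topology_tsv(profiles: Sequence[TopologyProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tregion_type\tstart\tend\tscore\n")
        for p in sorted(profiles, key=lambda p: p.protein_id):
            for r in p.regions:
                score = "" if r.score is None else f"{r.score:.6g}"
                fh.write(
                    f"{p.protein_id}\t{r.region_type}\t{r.start}\t{r.end}"
                    f"\t{score}\n"
                )
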