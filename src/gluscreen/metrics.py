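"""Ground-truth evaluation helpers for synthetic benchmarks."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .records import GroundTruth
from .screen import ScreenResult
from .topology import TopologyProfile

#: expected group label per planted architecture
EXPECTED_GROUP = {
    "channel-g1": 1,
    "channel-g2": 2,
    "soluble-binder": None,
    "permease": None,
    "random": None,
}


def channel_ids(truths: Sequence[GroundTruth]) -> set[str]:
    return {
        gt.protein_id for gt in truths if gt.label.startswith("channel-")
    }


def stage4_recall(
    result: ScreenResult, truths: Sequence[GroundTruth]
) -> float:
    """Fraction of planted channel proteins surviving the full cascade."""
    channels = channel_ids(truths)
    if not channels:
        raise ValueError("no planted channels in ground truth")
    return len(result.stage4_both & channels) / len(channels)


def group_accuracy(
    profiles: Sequence[TopologyProfile],
    truths: Sequence[GroundTruth],
) -> float:
    """Fraction of proteins whose assigned group (1/2/none) is correct.

    Proteins absent from ``profiles`` (eliminated before stage 5) count as
    assigned no group.
    """
    assigned: Mapping[str, Optional[int]] = {
        p.protein_id: p.group for p in profiles
    }
    correct = 0
    for gt in truths:
        if assigned.get(gt.protein_id) == EXPECTED_GROUP[gt.label]:
            correct += 1
    return correct / len(truths)
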