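"""Basic multiple aligner for synthetic tests — non-authoritative.

Center-star construction: every sequence is globally aligned (BLOSUM62,
affine gaps) against the longest input, and the pairwise alignments are
merged on the star center's coordinate system. Adequate for the
low-divergence synthetic data this package tests itself on; real analyses
should consume alignments produced by a dedicated aligner.
"""

from __future__ import annotations

from typing import Sequence

from Bio.Align import PairwiseAligner, substitution_matrices


def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _split_by_center(center_row: str, subject_row: str, n: int):
    """Decompose a pairwise alignment along the ungapped center sequence.

    Returns (before, at): ``before[i]`` holds subject residues inserted
    before center position i, ``at[i]`` the subject character (residue or
    gap) aligned with center residue i.
    """
    before = [""] * (n + 1)
    at = [""] * n
    k = 0
    for c_char, s_char in zip(center_row, subject_row):
        if c_char == "-":
            before[k] += s_char
        else:
            at[k] = s_char
            k += 1
    return before, at


def align_star(rows: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    """Multiple-align (id, sequence) pairs by the center-star method.

    The center is the longest sequence (ties broken by id); input row order
    is preserved in the output.
    """
    if not rows:
        raise ValueError("nothing to align")
    if len(rows) == 1:
        return list(rows)
    center_idx = max(
        range(len(rows)), key=lambda i: (len(rows[i][1]), rows[i][0])
    )
    center_seq = rows[center_idx][1]
    n = len(center_seq)
    aligner = _global_aligner()

    decomposed: dict[int, tuple[list[str], list[str]]] = {}
    insertions = [0] * (n + 1)
    for i, (_, seq) in enumerate(rows):
        if i == center_idx:
            continue
        aln = next(iter(aligner.align(center_seq, seq)))
        before, at = _split_by_center(aln[0], aln[1], n)
        decomposed[i] = (before, at)
        for k, ins in enumerate(before):
            insertions[k] = max(insertions[k], len(ins))

    merged = []
    for i, (rid, _) in enumerate(rows):
        if i == center_idx:
            cols = []
            for k in range(n):
                cols.append("-" * insertions[k])
                cols.append(center_seq[k])
            cols.append("-" * insertions[n])
            merged.append((rid, "".join(cols)))
            continue
        before, at = decomposed[i]
        cols = []
        for k in range(n):
            cols.append(before[k].rjust(insertions[k], "-"))
            cols.append(at[k])
        cols.append(before[n].ljust(insertions[n], "-"))
        merged.append((rid, "".join(cols)))
    widths = {len(row) for _, row in merged}
    assert len(widths) == 1, "star merge produced ragged rows"
    return merged
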