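"""Local alignment with affine gaps and Karlin–Altschul E-values.

This is the package's self-contained stand-in for an iterated profile search:
a single-pass Smith–Waterman (BLOSUM62, BLAST-style gap costs) whose raw
scores are converted to E-values with the standard gapped Karlin–Altschul
calibration E = K·m·n·exp(−λ·S).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from Bio.Align import PairwiseAligner, substitution_matrices

from .records import ProteinRecord


@dataclass(frozen=True)
class ScoringParams:
    """Scoring model for the probe search.

    ``gap_open``/``gap_extend`` follow the BLAST convention: a gap of length k
    costs gap_open + k·gap_extend. ``lam``/``kappa`` default to the standard
    gapped BLOSUM62/11,1 calibration (λ=0.267, K=0.041).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    kappa: float = 0.041
    evalue_threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.kappa <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    """One probe-vs-subject local alignment."""

    protein_id: str
    probe_label: str
    raw_score: int
    evalue: float
    subject_interval: tuple[int, int]
    query_interval: tuple[int, int]

    def __post_init__(self) -> None:
        if self.raw_score < 0:
            raise ValueError("raw_score must be >= 0")


@lru_cache(maxsize=8)
def _matrix(name: str):
    """Substitution matrix with X (unknown residue) scored 0 against all."""
    mat = substitution_matrices.load(name).copy()
    for aa in mat.alphabet:
        mat["X", aa] = 0.0
        mat[aa, "X"] = 0.0
    return mat


@lru_cache(maxsize=32)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _matrix(matrix_name)
    # biopython charges open on the first gap column; BLAST charges open+extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def smith_waterman(
    query: str,
    subject: str,
    params: Optional[ScoringParams] = None,
    protein_id: str = "",
    probe_label: str = "",
) -> AlignmentHit:
    """Optimal local alignment of ``query`` against ``subject``.

    Returns a hit with the optimal raw score and the subject/query span of the
    first optimal traceback; a score of 0 (no positive-scoring cell) yields
    empty intervals. E-value is filled in by the caller via
    :func:`estimate_evalue`; here it is computed with n = len(subject).
    """
    params = params or ScoringParams()
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    score = int(aligner.score(subject, query))
    if score <= 0:
        return AlignmentHit(
            protein_id, probe_label, 0,
            estimate_evalue(0, len(query), len(subject), params),
            (0, 0), (0, 0),
        )
    aln = next(iter(aligner.align(subject, query)))
    t_blocks, q_blocks = aln.aligned
    subject_interval = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    query_interval = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    return AlignmentHit(
        protein_id, probe_label, score,
        estimate_evalue(score, len(query), len(subject), params),
        subject_interval, query_interval,
    )


def estimate_evalue(
    raw_score: int, m: int, n: int, params: Optional[ScoringParams] = None
) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−λ·S).

    ``m`` is the query length, ``n`` the search-space length (by convention
    the total residue count of the database searched).
    """
    params = params or ScoringParams()
    if m <= 0 or n <= 0:
        raise ValueError("m and n must be positive")
    return params.kappa * m * n * math.exp(-params.lam * raw_score)


def database_length(db: list[ProteinRecord]) -> int:
    return sum(len(rec) for rec in db)
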