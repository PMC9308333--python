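"""Pairwise global alignment and identity distances.

Alignment is Needleman-Wunsch with affine gap penalties via Biopython's
PairwiseAligner, defaulting to BLOSUM62 with gap open 10 / extend 1 (positive
magnitudes).  A gap of length k costs open + (k-1)*extend, terminal gaps
included.  Fractional identity is the number of identical aligned columns
divided by the total number of alignment columns (gap columns included), and
distance is 1 - identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices


class AlignmentInputError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise AlignmentInputError("gap penalties must be positive magnitudes")


@lru_cache(maxsize=8)
def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="global")
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float


DEFAULT_PARAMS = AlignmentParams()


def pairwise_global_align(a: str, b: str,
                          params: AlignmentParams = DEFAULT_PARAMS
                          ) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences.

    Among co-optimal alignments the aligner's first enumerated alignment is
    returned (deterministic for fixed inputs); the score is unique.
    """
    if not a or not b:
        raise AlignmentInputError("sequences must be nonempty")
    alignments = _aligner(params).align(a, b)
    best = alignments[0]
    row_a, row_b = str(best[0]), str(best[1])
    n_cols = len(row_a)
    n_ident = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return PairwiseAlignment(row_a, row_b, float(best.score), n_ident / n_cols)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise AlignmentInputError("matrix shape must match id count")
        if not np.allclose(m, m.T, atol=1e-12) or (np.diag(m) != 0).any():
            raise AlignmentInputError("matrix must be symmetric with zero diagonal")
        if (m < 0).any():
            raise AlignmentInputError("distances must be nonnegative")
        self.matrix = m

    def __len__(self) -> int:
        return len(self.ids)


def distance_matrix(seqs: list[tuple[str, str]],
                    params: AlignmentParams = DEFAULT_PARAMS) -> DistanceMatrix:
    """All-pairs distances d = 1 - fractional identity (each pair aligned once)."""
    ids = [name for name, _ in seqs]
    if len(set(ids)) != len(ids):
        raise AlignmentInputError("duplicate sequence ids")
    if len(seqs) < 2:
        raise AlignmentInputError("need at least 2 sequences")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = pairwise_global_align(seqs[i][1], seqs[j][1], params)
            d[i, j] = d[j, i] = 1.0 - aln.identity
    return DistanceMatrix(ids, d)
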