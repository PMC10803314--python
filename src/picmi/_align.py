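"""Shared pairwise-alignment helpers built on Bio.Align.PairwiseAligner."""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@lru_cache(maxsize=None)
def dna_global_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


@lru_cache(maxsize=None)
def protein_global_aligner(
    gap_open: float = -11.0, gap_extend: float = -1.0
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


@lru_cache(maxsize=None)
def protein_local_aligner(
    gap_open: float = -11.0, gap_extend: float = -1.0
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def alignment_identity(alignment) -> float:
    """Identity over alignment columns; gap columns count in the denominator."""
    counts = alignment.counts()
    columns = alignment.length
    if columns == 0:
        return 0.0
    return counts.identities / columns


def global_protein_identity(a: str, b: str) -> float:
    """End-to-end protein identity (BLOSUM62, affine gaps), gaps in denominator."""
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    aln = protein_global_aligner().align(a, b)[0]
    return alignment_identity(aln)
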