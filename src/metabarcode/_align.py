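"""Shared pairwise-alignment helpers.

Wraps :class:`Bio.Align.PairwiseAligner` (a C implementation of
Needleman-Wunsch / Smith-Waterman with affine gaps) behind small functions
so that the search and alignment backends stay pluggable.  Protein
alignments use BLOSUM62 with BLAST-like gap costs (open 11, extend 1);
nucleotide read alignments use match +1, mismatch -2, gap open -5,
gap extend -2.
"""

from __future__ import annotations

import math
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

# Karlin-Altschul parameters for gapped BLOSUM62 (gap 11/1), as used by
# BLASTP to convert raw scores into expectation values.
KA_LAMBDA = 0.267
KA_K = 0.041


@lru_cache(maxsize=1)
def blosum62():
    return substitution_matrices.load("BLOSUM62")


def protein_aligner(mode: str = "local") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = blosum62()
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = mode
    return aligner


def nucleotide_aligner(mode: str = "local") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    aligner.mode = mode
    return aligner


def evalue(raw_score: float, m: int, n: int) -> float:
    """Karlin-Altschul expectation value ``K * m * n * exp(-lambda * S)``."""
    return KA_K * m * n * math.exp(-KA_LAMBDA * raw_score)


def aligned_strings(alignment) -> tuple[str, str]:
    """Gapped query/subject strings of a Bio.Align.Alignment."""
    return str(alignment[0]), str(alignment[1])


def alignment_stats(gapped_a: str, gapped_b: str) -> tuple[int, int, int]:
    """(identities, positives, aligned_length) over non-gap columns.

    ``positives`` counts residue pairs with a positive BLOSUM62 score and
    includes identities, matching the BLAST "Positives" statistic.
    """
    matrix = blosum62()
    identities = positives = aligned = 0
    for a, b in zip(gapped_a, gapped_b):
        if a == "-" or b == "-":
            continue
        aligned += 1
        if a == b:
            identities += 1
        try:
            score = matrix[a, b]
        except (KeyError, IndexError):
            score = -1
        if score > 0:
            positives += 1
    return identities, positives, aligned


def kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}
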