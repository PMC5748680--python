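"""Shared pairwise-alignment plumbing (substitution matrix + aligner setup).

Gap convention: a gap of length L costs gap_open + (L - 1) * gap_extend.
Residues outside the matrix alphabet are mapped to the wildcard 'X' row.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices


@lru_cache(maxsize=None)
def load_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


def sanitize(sequence: str, alphabet: str) -> str:
    """Uppercase and map unknown residues to the wildcard 'X'."""
    seq = sequence.upper()
    return "".join(c if c in alphabet else "X" for c in seq)


def make_aligner(
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.2,
    mode: str = "global",
) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = load_matrix(matrix_name)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.mode = mode
    return aligner
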