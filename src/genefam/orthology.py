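"""Ortholog mapping by optimal local alignment with Karlin-Altschul
E-values and a similarity filter, plus best-hit copy-number summaries.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from genefam._alignment import load_matrix, make_aligner, sanitize
from genefam.io_formats import ProteinRecord

logger = logging.getLogger("genefam.orthology")

# Gapped BLOSUM62 (11/1) Karlin-Altschul constants; configurable.
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


@dataclass(frozen=True)
class LocalAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identities: int
    positives: int

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    @property
    def similarity(self) -> float:
        """BLAST-style positives fraction over alignment length."""
        return self.positives / self.length if self.length else 0.0


@dataclass(frozen=True)
class OrthologPair:
    query_id: str
    reference_id: str
    sw_score: float
    evalue: float
    similarity: float
    transferred_label: str = ""
    is_best: bool = False


def smith_waterman(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.2,
) -> LocalAlignment:
    """Optimal affine-gap local alignment (exact, not heuristic).

    Similarity counts identities plus positive-scoring substitutions over
    the alignment length (gap columns count toward length only).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    matrix = load_matrix(matrix_name)
    sa, sb = sanitize(a, matrix.alphabet), sanitize(b, matrix.alphabet)
    aligner = make_aligner(matrix_name, gap_open, gap_extend, mode="local")
    alignments = aligner.align(sa, sb)
    if len(alignments) == 0 or alignments.score <= 0:
        return LocalAlignment("", "", max(float(alignments.score), 0.0), 0, 0)
    aln = alignments[0]
    aa, ab = str(aln[0]), str(aln[1])
    identities = positives = 0
    for x, y in zip(aa, ab):
        if x == "-" or y == "-":
            continue
        if x == y:
            identities += 1
            positives += 1
        elif matrix[x, y] > 0:
            positives += 1
    return LocalAlignment(aa, ab, float(aln.score), identities, positives)


def local_score(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.2,
) -> float:
    """Score-only Smith-Waterman (no traceback); used to pre-filter."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    matrix = load_matrix(matrix_name)
    aligner = make_aligner(matrix_name, gap_open, gap_extend, mode="local")
    return float(aligner.score(sanitize(a, matrix.alphabet), sanitize(b, matrix.alphabet)))


def evalue(
    score: float,
    query_len: int,
    db_len: int,
    lambda_: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be positive")
    return K * query_len * db_len * math.exp(-lambda_ * score)


def find_orthologs(
    queries: Sequence[ProteinRecord],
    references: Sequence[ProteinRecord],
    evalue_max: float = 1e-40,
    min_similarity: float = 0.70,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.2,
    lambda_: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
    labels: Mapping[str, str] | None = None,
    reciprocal_best: bool = False,
) -> list[OrthologPair]:
    """All query-reference pairs passing both the E-value and similarity
    filters; each query's best hit (max score, ties by smaller E then
    lexicographic reference id) carries the transferred label.

    With ``reciprocal_best`` a best pair is additionally required to be its
    reference's best query.
    """
    labels = labels or {}
    db_len = sum(len(r) for r in references)
    pairs: list[OrthologPair] = []
    best_by_query: dict[str, OrthologPair] = {}
    for q in queries:
        candidates: list[OrthologPair] = []
        for ref in references:
            score = local_score(q.sequence, ref.sequence, matrix_name, gap_open, gap_extend)
            e = evalue(score, len(q), db_len, lambda_, K)
            if e > evalue_max:
                continue
            aln = smith_waterman(q.sequence, ref.sequence, matrix_name, gap_open, gap_extend)
            if aln.similarity < min_similarity:
                continue
            candidates.append(
                OrthologPair(
                    query_id=q.gene_id,
                    reference_id=ref.gene_id,
                    sw_score=aln.score,
                    evalue=e,
                    similarity=aln.similarity,
                )
            )
        if not candidates:
            continue
        best = min(candidates, key=lambda p: (-p.sw_score, p.evalue, p.reference_id))
        for p in candidates:
            is_best = p is best
            pairs.append(
                OrthologPair(
                    query_id=p.query_id,
                    reference_id=p.reference_id,
                    sw_score=p.sw_score,
                    evalue=p.evalue,
                    similarity=p.similarity,
                    transferred_label=labels.get(p.reference_id, "") if is_best else "",
                    is_best=is_best,
                )
            )
            if is_best:
                best_by_query[p.query_id] = p
    if reciprocal_best:
        best_query_for_ref: dict[str, str] = {}
        for qid, p in best_by_query.items():
            cur = best_query_for_ref.get(p.reference_id)
            if cur is None or (
                (-p.sw_score, p.evalue, p.query_id)
                < (-best_by_query[cur].sw_score, best_by_query[cur].evalue, cur)
            ):
                best_query_for_ref[p.reference_id] = qid
        pairs = [
            (
                p
                if not p.is_best
                or best_query_for_ref.get(p.reference_id) == p.query_id
                else OrthologPair(
                    p.query_id, p.reference_id, p.sw_score, p.evalue, p.similarity
                )
            )
            for p in pairs
        ]
    return pairs


def best_hits(pairs: Iterable[OrthologPair]) -> dict[str, OrthologPair]:
    return {p.query_id: p for p in pairs if p.is_best}


def copy_number_summary(pairs: Iterable[OrthologPair]) -> Counter:
    """Best-hit in-degree per reference gene (how many queries retained it)."""
    return Counter(p.reference_id for p in pairs if p.is_best)


def pairs_to_frame(pairs: Sequence[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "gene_id": p.query_id,
                "reference_id": p.reference_id,
                "sw_score": p.sw_score,
                "evalue": p.evalue,
                "similarity": round(p.similarity, 4),
                "best_hit": p.is_best,
                "transferred_label": p.transferred_label,
            }
            for p in pairs
        ],
        columns=[
            "gene_id",
            "reference_id",
            "sw_score",
            "evalue",
            "similarity",
            "best_hit",
            "transferred_label",
        ],
    )
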