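"""Expression profiling: tissue-specificity grouping with Venn counts,
fold-change DEG calling with temporal pattern clustering, and 2^-ddCt qPCR
quantification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from genefam.io_formats import ExpressionTable, round_half_up

logger = logging.getLogger("genefam.expression")

UP = "UP"
DOWN = "DOWN"
NS = "NS"
NOT_EXPRESSED = "NOT_EXPRESSED"

_ROMAN = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
)


def roman(n: int) -> str:
    if n < 1:
        raise ValueError("roman numerals start at 1")
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


# ---------------------------------------------------------------------------
# Matrix transforms
# ---------------------------------------------------------------------------


def log2_matrix(table: ExpressionTable, pseudocount: float = 1.0) -> ExpressionTable:
    """value -> log2(value + pseudocount); shape preserved."""
    if np.any(table.values < 0):
        raise ValueError("negative expression values")
    return ExpressionTable(
        gene_ids=list(table.gene_ids),
        condition_ids=list(table.condition_ids),
        values=np.log2(table.values + pseudocount),
    )


# ---------------------------------------------------------------------------
# Tissue specificity
# ---------------------------------------------------------------------------


@dataclass
class PresenceGroups:
    """Partition of genes by tissue-presence pattern.

    ``patterns`` maps gene id to the tuple of tissues where it exceeds the
    threshold (empty tuple = NOT_EXPRESSED).  ``group_ids`` numbers distinct
    non-empty patterns canonically: descending group size, ties broken by
    pattern bit-string.
    """

    tissues: list[str]
    patterns: dict[str, tuple[str, ...]]
    group_ids: dict[tuple[str, ...], str]
    venn_counts: dict[tuple[str, ...], int]

    @property
    def expressed_genes(self) -> list[str]:
        return [g for g, p in self.patterns.items() if p]

    @property
    def common_count(self) -> int:
        """Genes expressed in every tissue."""
        return self.venn_counts.get(tuple(self.tissues), 0)

    def group_of(self, gene_id: str) -> str:
        pattern = self.patterns[gene_id]
        return self.group_ids.get(pattern, NOT_EXPRESSED)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            [
                {
                    "gene_id": g,
                    "group": self.group_of(g),
                    "pattern": "+".join(p) if p else NOT_EXPRESSED,
                    "n_tissues": len(p),
                }
                for g, p in self.patterns.items()
            ],
            columns=["gene_id", "group", "pattern", "n_tissues"],
        )

    def venn_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            [
                {
                    "group": self.group_ids[p],
                    "pattern": "+".join(p),
                    "n_tissues": len(p),
                    "count": c,
                }
                for p, c in sorted(
                    self.venn_counts.items(),
                    key=lambda item: (-item[1], _pattern_bits(self.tissues, item[0])),
                )
            ],
            columns=["group", "pattern", "n_tissues", "count"],
        )


def _pattern_bits(tissues: Sequence[str], pattern: tuple[str, ...]) -> str:
    members = set(pattern)
    return "".join("1" if t in members else "0" for t in tissues)


def tissue_groups(
    table: ExpressionTable, expressed_threshold: float = 1.0
) -> PresenceGroups:
    """Group genes by the subset of tissues where RPKM exceeds the
    threshold; group ids are Roman numerals in canonical order (descending
    size, ties by pattern bit-string)."""
    tissues = list(table.condition_ids)
    patterns: dict[str, tuple[str, ...]] = {}
    for gi, gene in enumerate(table.gene_ids):
        present = tuple(
            t for ti, t in enumerate(tissues) if table.values[gi, ti] > expressed_threshold
        )
        patterns[gene] = present
    counts: dict[tuple[str, ...], int] = {}
    for p in patterns.values():
        if p:
            counts[p] = counts.get(p, 0) + 1
    ordered = sorted(counts, key=lambda p: (-counts[p], _pattern_bits(tissues, p)))
    group_ids = {p: roman(i) for i, p in enumerate(ordered, start=1)}
    return PresenceGroups(
        tissues=tissues, patterns=patterns, group_ids=group_ids, venn_counts=counts
    )


# ---------------------------------------------------------------------------
# DEG calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DEGCall:
    gene_id: str
    time_point: str
    fold_change: float
    verdict: str


def _verdict(fold: float, fc_up: float, fc_down: float) -> str:
    if fold > fc_up:
        return UP
    if fold < fc_down:
        return DOWN
    return NS


def call_degs(
    stress_table: ExpressionTable,
    control_column: str,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    epsilon: float = 0.01,
) -> list[DEGCall]:
    """One call per gene per stress time point.

    fold_change = (stress + eps) / (control + eps); UP iff fc > fc_up,
    DOWN iff fc < fc_down, else NS.
    """
    if control_column not in stress_table.condition_ids:
        raise ValueError(f"control column {control_column!r} not in table")
    if not (fc_down < 1.0 < fc_up):
        raise ValueError("thresholds must satisfy fc_down < 1 < fc_up")
    ci = stress_table.condition_ids.index(control_column)
    time_points = [c for c in stress_table.condition_ids if c != control_column]
    calls: list[DEGCall] = []
    for gi, gene in enumerate(stress_table.gene_ids):
        control = stress_table.values[gi, ci]
        for tp in time_points:
            ti = stress_table.condition_ids.index(tp)
            fold = (stress_table.values[gi, ti] + epsilon) / (control + epsilon)
            calls.append(
                DEGCall(
                    gene_id=gene,
                    time_point=tp,
                    fold_change=fold,
                    verdict=_verdict(fold, fc_up, fc_down),
                )
            )
    return calls


def calls_to_frame(calls: Sequence[DEGCall]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "gene_id": c.gene_id,
                "time_point": c.time_point,
                "fold_change": round(c.fold_change, 6),
                "verdict": c.verdict,
            }
            for c in calls
        ],
        columns=["gene_id", "time_point", "fold_change", "verdict"],
    )


def deg_gene_set(calls: Iterable[DEGCall]) -> set[str]:
    """Genes with at least one non-NS verdict."""
    return {c.gene_id for c in calls if c.verdict != NS}


@dataclass
class PatternClusters:
    """DEGs grouped by their exact verdict trajectory."""

    time_points: list[str]
    signatures: dict[str, tuple[str, ...]]  # gene -> trajectory (DEGs only)
    cluster_ids: dict[tuple[str, ...], str]

    @property
    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for sig in self.signatures.values():
            cid = self.cluster_ids[sig]
            out[cid] = out.get(cid, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            [
                {
                    "gene_id": g,
                    "cluster": self.cluster_ids[sig],
                    "signature": "/".join(sig),
                }
                for g, sig in self.signatures.items()
            ],
            columns=["gene_id", "cluster", "signature"],
        )


def cluster_patterns(calls: Sequence[DEGCall]) -> PatternClusters:
    """Cluster DEGs by identical verdict trajectories across time points.

    All-NS genes are excluded.  Clusters are numbered I, II, ... in
    descending size, ties broken by signature lexicographic order.
    """
    time_points: list[str] = []
    for c in calls:
        if c.time_point not in time_points:
            time_points.append(c.time_point)
    by_gene: dict[str, dict[str, str]] = {}
    for c in calls:
        by_gene.setdefault(c.gene_id, {})[c.time_point] = c.verdict
    signatures: dict[str, tuple[str, ...]] = {}
    for gene, verdicts in by_gene.items():
        sig = tuple(verdicts.get(tp, NS) for tp in time_points)
        if any(v != NS for v in sig):
            signatures[gene] = sig
    counts: dict[tuple[str, ...], int] = {}
    for sig in signatures.values():
        counts[sig] = counts.get(sig, 0) + 1
    ordered = sorted(counts, key=lambda s: (-counts[s], s))
    cluster_ids = {s: roman(i) for i, s in enumerate(ordered, start=1)}
    return PatternClusters(
        time_points=time_points, signatures=signatures, cluster_ids=cluster_ids
    )


@dataclass(frozen=True)
class VennResult:
    a_only: int
    b_only: int
    both: int
    union: int
    pct_of_family: int  # headline integer (half-up)
    pct_exact: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": ["a_only", "b_only", "both", "union", "pct_of_family"],
                "value": [self.a_only, self.b_only, self.both, self.union, self.pct_of_family],
            }
        )


def compare_stresses(
    deg_set_a: Iterable[str], deg_set_b: Iterable[str], family_total: int
) -> VennResult:
    """Set algebra between two DEG gene sets plus the union's share of the
    whole family (rounded half-up to an integer percentage)."""
    a, b = set(deg_set_a), set(deg_set_b)
    union = a | b
    if family_total < len(union):
        raise ValueError(
            f"family_total {family_total} smaller than DEG union {len(union)}"
        )
    pct_exact = 100.0 * len(union) / family_total if family_total else 0.0
    return VennResult(
        a_only=len(a - b),
        b_only=len(b - a),
        both=len(a & b),
        union=len(union),
        pct_of_family=int(round_half_up(pct_exact)),
        pct_exact=pct_exact,
    )


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def ddct(
    ct_table: pd.DataFrame, target_gene: str, reference_gene: str
) -> tuple[list[float], float]:
    """2^-ddCt relative quantification.

    dCt_cond = Ct_target,cond - Ct_ref,cond per replicate; ddCt =
    dCt_stress - dCt_control; fold = 2^-ddCt.  Replicates are paired by
    replicate id; the summary is the geometric mean across replicates.
    Returns (per-replicate folds, geometric mean).
    """

    def cts(gene: str, condition: str) -> dict:
        sub = ct_table[
            (ct_table["gene_id"] == gene) & (ct_table["condition"] == condition)
        ]
        return dict(zip(sub["replicate"], sub["ct"]))

    ref_stress = cts(reference_gene, "stress")
    ref_control = cts(reference_gene, "control")
    if not ref_stress or not ref_control:
        raise ValueError(f"reference gene {reference_gene!r} missing a condition")
    tgt_stress = cts(target_gene, "stress")
    tgt_control = cts(target_gene, "control")
    reps = sorted(
        set(tgt_stress) & set(tgt_control) & set(ref_stress) & set(ref_control)
    )
    if not reps:
        raise ValueError(f"no complete replicates for target {target_gene!r}")
    folds: list[float] = []
    for rep in reps:
        dct_stress = tgt_stress[rep] - ref_stress[rep]
        dct_control = tgt_control[rep] - ref_control[rep]
        folds.append(2.0 ** -(dct_stress - dct_control))
    gmean = math.exp(sum(math.log(f) for f in folds) / len(folds))
    return folds, gmean


def classify_induction(fold: float, up: float = 2.0, down: float = 0.5) -> str:
    """Same rule as DEG verdicts: fold > up -> UP, fold < down -> DOWN."""
    if fold <= 0:
        raise ValueError("fold change must be positive")
    return _verdict(fold, up, down)


def qpcr_report(
    ct_table: pd.DataFrame,
    reference_gene: str,
    up: float = 2.0,
    down: float = 0.5,
) -> pd.DataFrame:
    """Fold change + verdict for every non-reference gene in a Ct table."""
    genes = sorted(set(ct_table["gene_id"]) - {reference_gene})
    records = []
    for gene in genes:
        folds, gmean = ddct(ct_table, gene, reference_gene)
        records.append(
            {
                "gene_id": gene,
                "fold_change": round(gmean, 4),
                "n_replicates": len(folds),
                "verdict": classify_induction(gmean, up, down),
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["gene_id", "fold_change", "n_replicates", "verdict"]
    )
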