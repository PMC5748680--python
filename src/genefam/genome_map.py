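"""Chromosomal ordering/naming, tandem-array detection, and summaries.

Two family genes belong to one tandem array when they sit on the same
linkage group with at most ``max_intervening`` genes (of any family status)
strictly between them; arrays are the transitive closure of that relation
over consecutive family genes, reported at size >= 2.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from genefam.domain_scan import NOT_FAMILY, SUBFAMILIES, SubfamilyCall
from genefam.io_formats import UNANCHORED, GeneModel, round_half_up

logger = logging.getLogger("genefam.genome_map")

_LG_PATTERN = re.compile(r"^LG0*(\d+)$", re.IGNORECASE)


def is_anchored(linkage_group: str) -> bool:
    """Anchored means placed on a numbered linkage group (LG01..)."""
    return bool(_LG_PATTERN.match(linkage_group))


def _lg_sort_key(linkage_group: str) -> tuple:
    m = _LG_PATTERN.match(linkage_group)
    if m:
        return (0, int(m.group(1)), "")
    if linkage_group == UNANCHORED:
        return (2, 0, "")
    return (1, 0, linkage_group)  # scaffolds, by id


@dataclass(frozen=True)
class TandemArray:
    linkage_group: str
    members: tuple[str, ...]  # gene ids ordered by start

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class LGSummary:
    """Per-linkage-group cross-tabulation plus headline percentages."""

    table: pd.DataFrame  # rows: LGs + Scaffold; columns: subfamilies + Total
    family_total: int
    anchored_total: int
    unanchored_total: int
    tandem_count: int
    anchored_pct: int  # headline, rounded half-up to integer
    tandem_pct: int  # tandem members / anchored members, headline integer
    anchored_pct_exact: float
    tandem_pct_exact: float


def _family_ids(family_calls: Iterable[SubfamilyCall]) -> dict[str, str]:
    return {
        c.gene_id: c.subfamily for c in family_calls if c.subfamily != NOT_FAMILY
    }


def assign_and_name(
    gene_models: Sequence[GeneModel],
    family_calls: Iterable[SubfamilyCall],
    prefix: str = "SIMYB",
) -> dict[str, str]:
    """Name family genes prefix+1..prefix+N following their order on the
    linkage groups, then unanchored sequences (scaffold id, then start)."""
    membership = _family_ids(family_calls)
    models = {gm.gene_id: gm for gm in gene_models}
    missing = sorted(set(membership) - set(models))
    if missing:
        raise ValueError(f"family genes missing from gene models: {missing}")
    family = [models[g] for g in membership]
    by_position: dict[tuple, list[GeneModel]] = {}
    for gm in family:
        by_position.setdefault((_lg_sort_key(gm.linkage_group), gm.start), []).append(gm)
    for key, group in by_position.items():
        if len(group) > 1:
            logger.warning(
                "tie at %s broken lexicographically: %s",
                key,
                sorted(g.gene_id for g in group),
            )
    ordered = sorted(
        family, key=lambda gm: (_lg_sort_key(gm.linkage_group), gm.start, gm.gene_id)
    )
    return {gm.gene_id: f"{prefix}{i}" for i, gm in enumerate(ordered, start=1)}


def detect_tandem_arrays(
    all_genes_ordered: Sequence[GeneModel],
    family_membership: Iterable[str],
    max_intervening: int = 3,
) -> list[TandemArray]:
    """Detect maximal tandem arrays over the full gene complement.

    ``all_genes_ordered`` must contain every gene (family and background).
    Genes are ordered by start within each linkage group; consecutive family
    genes with <= ``max_intervening`` genes strictly between them are
    chained, and connected components of size >= 2 are returned sorted by
    linkage group then first start.
    """
    family = set(family_membership)
    present = {gm.gene_id for gm in all_genes_ordered}
    missing = sorted(family - present)
    if missing:
        raise ValueError(f"family genes absent from the ordered gene list: {missing}")
    by_lg: dict[str, list[GeneModel]] = {}
    for gm in all_genes_ordered:
        by_lg.setdefault(gm.linkage_group, []).append(gm)
    arrays: list[TandemArray] = []
    for lg, genes in by_lg.items():
        genes = sorted(genes, key=lambda gm: (gm.start, gm.gene_id))
        fam_positions = [i for i, gm in enumerate(genes) if gm.gene_id in family]
        current: list[int] = []
        runs: list[list[int]] = []
        for pos in fam_positions:
            if current and (pos - current[-1] - 1) <= max_intervening:
                current.append(pos)
            else:
                if len(current) >= 2:
                    runs.append(current)
                current = [pos]
        if len(current) >= 2:
            runs.append(current)
        for run in runs:
            arrays.append(
                TandemArray(
                    linkage_group=lg,
                    members=tuple(genes[i].gene_id for i in run),
                )
            )
    arrays.sort(
        key=lambda a: (
            _lg_sort_key(a.linkage_group),
            a.members,
        )
    )
    return arrays


def per_lg_summary(
    gene_models: Sequence[GeneModel],
    family_calls: Iterable[SubfamilyCall],
    arrays: Sequence[TandemArray] = (),
) -> LGSummary:
    """Cross-tabulate family genes LG x subfamily and compute the headline
    anchored/tandem percentages (rounded half-up to integers; exact values
    kept alongside)."""
    membership = _family_ids(family_calls)
    models = {gm.gene_id: gm for gm in gene_models}
    rows: dict[str, dict[str, int]] = {}
    anchored_total = 0
    for gene_id, subfamily in membership.items():
        gm = models.get(gene_id)
        if gm is None:
            raise ValueError(f"family gene {gene_id!r} missing from gene models")
        if is_anchored(gm.linkage_group):
            key = gm.linkage_group.upper()
            anchored_total += 1
        else:
            key = "Scaffold"
        rows.setdefault(key, {s: 0 for s in SUBFAMILIES})[subfamily] += 1
    family_total = len(membership)
    unanchored_total = family_total - anchored_total
    lg_names = sorted(
        (k for k in rows if k != "Scaffold"), key=_lg_sort_key
    )
    if "Scaffold" in rows:
        lg_names.append("Scaffold")
    table = pd.DataFrame(
        [[rows[lg][s] for s in SUBFAMILIES] for lg in lg_names],
        index=lg_names,
        columns=list(SUBFAMILIES),
    )
    table["Total"] = table.sum(axis=1)
    tandem_members = {g for a in arrays for g in a.members}
    tandem_count = len(tandem_members & set(membership))
    anchored_pct_exact = 100.0 * anchored_total / family_total if family_total else 0.0
    tandem_pct_exact = 100.0 * tandem_count / anchored_total if anchored_total else 0.0
    return LGSummary(
        table=table,
        family_total=family_total,
        anchored_total=anchored_total,
        unanchored_total=unanchored_total,
        tandem_count=tandem_count,
        anchored_pct=int(round_half_up(anchored_pct_exact)),
        tandem_pct=int(round_half_up(tandem_pct_exact)),
        anchored_pct_exact=anchored_pct_exact,
        tandem_pct_exact=tandem_pct_exact,
    )


def exon_intron_profile(
    gene_models: Sequence[GeneModel],
    family_membership: Iterable[str],
) -> pd.DataFrame:
    """Per-family-gene exon counts with an intronless flag.

    The returned frame carries ``exon_count`` and ``intronless`` per gene;
    family-wide min/max are attached as frame attrs.
    """
    family = set(family_membership)
    records = []
    for gm in gene_models:
        if gm.gene_id not in family:
            continue
        records.append(
            {
                "gene_id": gm.gene_id,
                "exon_count": gm.exon_count,
                "intronless": gm.exon_count == 1,
            }
        )
    frame = pd.DataFrame.from_records(
        records, columns=["gene_id", "exon_count", "intronless"]
    ).sort_values("gene_id", kind="mergesort", ignore_index=True)
    if len(frame):
        frame.attrs["exon_count_min"] = int(frame["exon_count"].min())
        frame.attrs["exon_count_max"] = int(frame["exon_count"].max())
    return frame
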