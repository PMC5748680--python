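"""Synthetic "sesame-like" dataset generator with planted ground truth.

Generates a 16-linkage-group genome carrying family members of every
subfamily with planted tandem arrays, a matching proteome with planted
repeat motifs, a labeled reference proteome with a planted ortholog map,
tissue/stress RPKM tables with planted expression patterns, and qPCR Ct
tables — so every downstream stage is testable without downloads.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from genefam.domain_scan import (
    ATYPICAL,
    ONE_R,
    R1R2R3,
    R2R3,
    SUBFAMILIES,
    RepeatProfile,
    default_repeat_profile,
)
from genefam.expression import DOWN, NS, UP
from genefam.io_formats import AMINO_ACIDS, ExpressionTable, GeneModel, ProteinRecord

logger = logging.getLogger("genefam.synthetic_data")

#: Default subfamily mix mirroring the emulated family's composition.
DEFAULT_SUBFAMILY_MIX = {ONE_R: 0.5122, R2R3: 0.4669, R1R2R3: 0.0174, ATYPICAL: 0.0035}

#: Default tandem plan: (array_size, count); 2*8 + 3*5 + 4*6 = 55 members.
DEFAULT_TANDEM_SPEC = ((2, 8), (3, 5), (4, 6))

#: Repeats per subfamily (ATYPICAL gets >= 4).
REPEATS_PER_SUBFAMILY = {ONE_R: 1, R2R3: 2, R1R2R3: 3, ATYPICAL: 4}

TISSUES = ("root", "stem", "leaf", "seed", "capsule")

WATERLOGGING_TIME_POINTS = ("3h", "9h", "15h")
DROUGHT_TIME_POINTS = ("d1", "d2", "d3")

#: Temporal verdict signatures for the five waterlogging pattern groups.
WATERLOGGING_SIGNATURES: dict[str, tuple[str, str, str]] = {
    "I": (NS, UP, NS),      # strongly induced mid-stress
    "II": (NS, NS, UP),     # induced only under prolonged stress
    "III": (UP, UP, DOWN),  # induced early/mid, repressed late
    "IV": (UP, DOWN, DOWN), # induced at onset, declining after
    "V": (UP, DOWN, UP),    # repressed mid-stress, induced at both ends
}
WATERLOGGING_GROUP_SIZES = {"I": 39, "II": 12, "III": 12, "IV": 22, "V": 29}

#: Temporal verdict signatures for the four drought pattern groups.
DROUGHT_SIGNATURES: dict[str, tuple[str, str, str]] = {
    "I": (UP, UP, UP),        # constitutively induced, strongest late
    "II": (NS, UP, UP),       # induced under severe stress
    "III": (DOWN, DOWN, DOWN),  # constitutively repressed
    "IV": (UP, UP, DOWN),     # induced early, repressed under severe stress
}
DROUGHT_GROUP_SIZES = {"I": 5, "II": 6, "III": 8, "IV": 27}


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic dataset."""

    family_genes: list[str] = field(default_factory=list)
    background_genes: list[str] = field(default_factory=list)
    subfamily: dict[str, str] = field(default_factory=dict)
    tandem_arrays: list[tuple[str, ...]] = field(default_factory=list)
    tissue_pattern: dict[str, tuple[str, ...]] = field(default_factory=dict)
    waterlogging_group: dict[str, str] = field(default_factory=dict)
    drought_group: dict[str, str] = field(default_factory=dict)
    orthologs: dict[str, str] = field(default_factory=dict)
    reference_labels: dict[str, str] = field(default_factory=dict)
    exon_counts: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        known = set(self.family_genes) | set(self.background_genes)
        for name, mapping in (
            ("subfamily", self.subfamily),
            ("tissue_pattern", self.tissue_pattern),
            ("waterlogging_group", self.waterlogging_group),
            ("drought_group", self.drought_group),
            ("orthologs", self.orthologs),
        ):
            stray = set(mapping) - known
            if stray:
                raise ValueError(f"{name} refers to unknown genes: {sorted(stray)}")
        for arr in self.tandem_arrays:
            if not 2 <= len(arr) <= 4:
                raise ValueError(f"tandem array size {len(arr)} outside 2..4")
            stray = set(arr) - known
            if stray:
                raise ValueError(f"tandem array refers to unknown genes: {sorted(stray)}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "family_genes": self.family_genes,
            "background_genes": self.background_genes,
            "subfamily": self.subfamily,
            "tandem_arrays": [list(a) for a in self.tandem_arrays],
            "tissue_pattern": {g: list(p) for g, p in self.tissue_pattern.items()},
            "waterlogging_group": self.waterlogging_group,
            "drought_group": self.drought_group,
            "orthologs": self.orthologs,
            "reference_labels": self.reference_labels,
            "exon_counts": self.exon_counts,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            family_genes=payload["family_genes"],
            background_genes=payload["background_genes"],
            subfamily=payload["subfamily"],
            tandem_arrays=[tuple(a) for a in payload["tandem_arrays"]],
            tissue_pattern={g: tuple(p) for g, p in payload["tissue_pattern"].items()},
            waterlogging_group=payload["waterlogging_group"],
            drought_group=payload["drought_group"],
            orthologs=payload["orthologs"],
            reference_labels=payload["reference_labels"],
            exon_counts={g: int(c) for g, c in payload["exon_counts"].items()},
        )


# ---------------------------------------------------------------------------
# Genome + proteome
# ---------------------------------------------------------------------------


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    # uniform 1/20 background residue frequencies
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _sample_motif(rng: np.random.Generator, consensus: str, noise: float) -> str:
    if noise <= 0:
        return consensus
    out = []
    for aa in consensus:
        if rng.random() < noise:
            alternatives = [c for c in AMINO_ACIDS if c != aa]
            out.append(alternatives[rng.integers(len(alternatives))])
        else:
            out.append(aa)
    return "".join(out)


def _family_protein(
    rng: np.random.Generator, consensus: str, n_repeats: int, motif_noise: float
) -> str:
    parts = [_random_peptide(rng, int(rng.integers(5, 30)))]
    for k in range(n_repeats):
        parts.append(_sample_motif(rng, consensus, motif_noise))
        parts.append(_random_peptide(rng, int(rng.integers(8, 25))))
    return "".join(parts)


def _make_exons(
    rng: np.random.Generator, start: int, n_exons: int
) -> tuple[tuple[tuple[int, int], ...], int]:
    exons = []
    cursor = start
    for i in range(n_exons):
        length = int(rng.integers(50, 300))
        exons.append((cursor, cursor + length - 1))
        cursor += length
        if i < n_exons - 1:
            cursor += int(rng.integers(50, 500))  # intron
    return tuple(exons), exons[-1][1]


def simulate_genome(
    n_family_genes: int = 287,
    n_background_genes: int = 2000,
    n_linkage_groups: int = 16,
    subfamily_mix: Mapping[str, float] | None = None,
    tandem_spec: Sequence[tuple[int, int]] | None = None,
    seed: int = 0,
    motif_noise: float = 0.0,
    n_unanchored_family: int = 0,
    profile: RepeatProfile | None = None,
    max_intervening: int = 3,
) -> tuple[list[GeneModel], list[ProteinRecord], SyntheticTruth]:
    """Generate gene models, proteins, and planted truth.

    Family proteins carry k sampled copies of the repeat consensus (k per
    subfamily) embedded in uniform-random background sequence; background
    proteins carry no planted motif.  Planted tandem arrays are consecutive
    family genes with 0..max_intervening intervening background genes;
    distinct family units are separated by enough background genes that no
    unplanned array can arise.
    """
    mix = dict(subfamily_mix or DEFAULT_SUBFAMILY_MIX)
    if abs(sum(mix.values()) - 1.0) > 1e-6:
        raise ValueError("subfamily_mix proportions must sum to 1")
    if tandem_spec is None:
        scale = n_family_genes / 287.0
        tandem_spec = [
            (size, int(round(count * scale))) for size, count in DEFAULT_TANDEM_SPEC
        ]
    spec = tuple(tandem_spec)
    for size, count in spec:
        if not 2 <= size <= 4:
            raise ValueError(f"tandem array size {size} outside the 2..4 range")
        if count < 0:
            raise ValueError("tandem array count must be >= 0")
    n_tandem_members = sum(size * count for size, count in spec)
    n_anchored_family = n_family_genes - n_unanchored_family
    if n_tandem_members > n_anchored_family:
        raise ValueError(
            f"tandem spec needs {n_tandem_members} family genes but only "
            f"{n_anchored_family} anchored family genes are budgeted"
        )
    rng = np.random.default_rng(seed)
    profile = profile or default_repeat_profile()
    consensus = profile.consensus

    # subfamily labels via a recorded multinomial draw
    order = list(SUBFAMILIES)
    draws = rng.multinomial(n_family_genes, [mix.get(s, 0.0) for s in order])
    labels: list[str] = []
    for subfam, count in zip(order, draws):
        labels.extend([subfam] * count)
    rng.shuffle(labels)

    # family units: planted arrays first, then singletons
    family_indices = list(range(n_family_genes))
    units: list[list[int]] = []
    cursor = 0
    for size, count in spec:
        for _ in range(count):
            units.append(family_indices[cursor : cursor + size])
            cursor += size
    anchored_singletons = family_indices[cursor:n_anchored_family]
    units.extend([[i] for i in anchored_singletons])
    unanchored = family_indices[n_anchored_family:]
    rng.shuffle(units)

    # distribute units over linkage groups
    lg_names = [f"LG{i + 1:02d}" for i in range(n_linkage_groups)]
    unit_lg = [lg_names[int(rng.integers(n_linkage_groups))] for _ in units]

    # background budget: separators between units on each LG
    separator = max_intervening + 2  # guarantees no cross-unit chaining
    per_lg_units: dict[str, list[list[int]]] = {lg: [] for lg in lg_names}
    for unit, lg in zip(units, unit_lg):
        per_lg_units[lg].append(unit)
    required_background = sum(
        separator * max(len(us) - 1, 0) for us in per_lg_units.values()
    )
    # intervening genes inside arrays come out of the same budget
    intra = [
        [int(rng.integers(0, max_intervening + 1)) for _ in range(len(u) - 1)]
        for u in units
    ]
    required_background += sum(sum(gaps) for gaps in intra)
    if n_background_genes < required_background:
        raise ValueError(
            f"n_background_genes={n_background_genes} too small; layout needs "
            f"at least {required_background}"
        )
    spare = n_background_genes - required_background
    intra_by_unit = {id(u): gaps for u, gaps in zip(units, intra)}

    # lay out slots per LG: each slot is ('family', idx) or ('background',)
    slots_per_lg: dict[str, list[tuple]] = {}
    spare_weights = rng.dirichlet(np.ones(n_linkage_groups))
    spare_per_lg = rng.multinomial(spare, spare_weights)
    for lg, n_spare in zip(lg_names, spare_per_lg):
        slots: list[tuple] = []
        lg_units = per_lg_units[lg]
        # spread spare background between/around units (never inside arrays)
        gap_slots = len(lg_units) + 1
        spare_split = (
            rng.multinomial(n_spare, np.ones(gap_slots) / gap_slots)
            if gap_slots
            else []
        )
        for ui, unit in enumerate(lg_units):
            slots.extend([("background",)] * int(spare_split[ui]))
            if ui > 0:
                slots.extend([("background",)] * separator)
            gaps = intra_by_unit[id(unit)]
            for mi, member in enumerate(unit):
                if mi > 0:
                    slots.extend([("background",)] * gaps[mi - 1])
                slots.append(("family", member))
        if lg_units:
            slots.extend([("background",)] * int(spare_split[len(lg_units)]))
        else:
            slots.extend([("background",)] * n_spare)
        slots_per_lg[lg] = slots

    # emit genes with coordinates; sequential ids in layout order
    gene_models: list[GeneModel] = []
    proteins: list[ProteinRecord] = []
    truth = SyntheticTruth()
    family_gene_ids: dict[int, str] = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"g{counter:05d}"

    def emit(lg: str, cursor: int, slot: tuple) -> int:
        gid = next_id()
        n_exons = int(min(1 + rng.poisson(2.5), 31))
        start = cursor + int(rng.integers(200, 2000))
        exons, end = _make_exons(rng, start, n_exons)
        strand = "+" if rng.random() < 0.5 else "-"
        gene_models.append(
            GeneModel(
                gene_id=gid, linkage_group=lg, start=start, end=end,
                strand=strand, exons=exons,
            )
        )
        truth.exon_counts[gid] = n_exons
        if slot[0] == "family":
            idx = slot[1]
            family_gene_ids[idx] = gid
            subfam = labels[idx]
            n_rep = REPEATS_PER_SUBFAMILY[subfam]
            if subfam == ATYPICAL:
                n_rep += int(rng.integers(0, 2))
            proteins.append(
                ProteinRecord(gid, _family_protein(rng, consensus, n_rep, motif_noise))
            )
            truth.family_genes.append(gid)
            truth.subfamily[gid] = subfam
        else:
            proteins.append(
                ProteinRecord(gid, _random_peptide(rng, int(rng.integers(120, 400))))
            )
            truth.background_genes.append(gid)
        return end

    for lg in lg_names:
        cursor = 0
        for slot in slots_per_lg[lg]:
            cursor = emit(lg, cursor, slot)
    # unanchored family genes: one per scaffold, no arrays possible
    for si, idx in enumerate(unanchored, start=1):
        cursor = emit(f"scaffold_{si:04d}", 0, ("family", idx))

    truth.tandem_arrays = [
        tuple(family_gene_ids[i] for i in unit) for unit in units if len(unit) >= 2
    ]
    truth.validate()
    logger.info(
        "simulated %d family + %d background genes on %d LGs (%d planted arrays)",
        len(truth.family_genes),
        len(truth.background_genes),
        n_linkage_groups,
        len(truth.tandem_arrays),
    )
    return gene_models, proteins, truth


# ---------------------------------------------------------------------------
# Reference proteome / planted orthologs
# ---------------------------------------------------------------------------


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    out = []
    for aa in sequence:
        if rng.random() < rate:
            alternatives = [c for c in AMINO_ACIDS if c != aa]
            out.append(alternatives[rng.integers(len(alternatives))])
        else:
            out.append(aa)
    return "".join(out)


def simulate_reference_proteome(
    proteins: Sequence[ProteinRecord],
    truth: SyntheticTruth,
    n_refs: int = 30,
    copy_numbers: Sequence[int] | None = None,
    mutation_rate: float = 0.03,
    seed: int = 0,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Create a labeled reference proteome with a planted ortholog map.

    Each reference is a lightly mutated copy of one family protein; for a
    planted copy number k > 1, k - 1 additional family genes have their
    sequences replaced by independent mutated copies of the same template
    (their truth labels follow the template's subfamily).  Returns the
    (possibly updated) protein list and the reference records; the ortholog
    map and reference labels land in ``truth``.
    """
    rng = np.random.default_rng(seed)
    copy_numbers = list(copy_numbers) if copy_numbers is not None else [1] * n_refs
    if len(copy_numbers) != n_refs:
        raise ValueError("copy_numbers must have one entry per reference")
    if sum(copy_numbers) > len(truth.family_genes):
        raise ValueError("planted copy numbers exceed the family gene budget")
    by_id = {p.gene_id: p for p in proteins}
    pool = list(truth.family_genes)
    rng.shuffle(pool)
    pool_iter = iter(pool)
    functions = (
        "stress_response", "development", "pigment_biosynthesis",
        "root_formation", "circadian_regulation", "cell_differentiation",
    )
    references: list[ProteinRecord] = []
    for ri, k in enumerate(copy_numbers, start=1):
        ref_id = f"REF{ri:03d}"
        template_gene = next(pool_iter)
        template = by_id[template_gene]
        references.append(
            ProteinRecord(ref_id, _mutate(rng, template.sequence, mutation_rate))
        )
        truth.reference_labels[ref_id] = functions[(ri - 1) % len(functions)]
        truth.orthologs[template_gene] = ref_id
        for _ in range(k - 1):
            extra_gene = next(pool_iter)
            by_id[extra_gene] = ProteinRecord(
                extra_gene, _mutate(rng, template.sequence, mutation_rate)
            )
            truth.subfamily[extra_gene] = truth.subfamily[template_gene]
            truth.orthologs[extra_gene] = ref_id
    updated = [by_id[p.gene_id] for p in proteins]
    return updated, references


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def _noisy(rng: np.random.Generator, value: float, noise_sd: float) -> float:
    # multiplicative log-normal noise: RPKM is ratio-scale
    return float(value * np.exp(rng.normal(0.0, noise_sd)))


def default_tissue_spec(n_genes: int) -> list[tuple[tuple[str, ...] | str, int]]:
    """Scaled mirror of the emulated tissue-specificity structure: ~60%
    ubiquitous, a small silent fraction, a few tissue-specific genes, the
    rest random proper subsets."""
    n_all = int(round(n_genes * 173 / 287))
    n_none = int(round(n_genes * 19 / 287))
    spec: list[tuple[tuple[str, ...] | str, int]] = [("ALL", n_all), ("NONE", n_none)]
    n_specific = min(7, max(n_genes - n_all - n_none, 0))
    for i in range(n_specific):
        spec.append(((TISSUES[i % len(TISSUES)],), 1))
    remainder = n_genes - n_all - n_none - n_specific
    spec.append(("RANDOM", remainder))
    return spec


def default_stress_spec(n_genes: int) -> dict[str, dict[str, int]]:
    """Paper-scale stress group sizes, scaled proportionally to the family
    size (287 -> the printed 39/12/12/22/29 and 5/6/8/27)."""
    scale = n_genes / 287.0
    return {
        "waterlogging": {
            g: max(int(round(s * scale)), 1) for g, s in WATERLOGGING_GROUP_SIZES.items()
        },
        "drought": {
            g: max(int(round(s * scale)), 1) for g, s in DROUGHT_GROUP_SIZES.items()
        },
    }


def simulate_expression(
    truth: SyntheticTruth,
    tissue_spec: Sequence[tuple[tuple[str, ...] | str, int]] | None = None,
    stress_spec: Mapping[str, Mapping[str, int]] | None = None,
    noise_sd: float = 0.2,
    seed: int = 0,
    overlap: int | None = None,
) -> tuple[ExpressionTable, ExpressionTable, ExpressionTable]:
    """Generate tissue, waterlogging, and drought RPKM tables.

    Tissue patterns: expressed tissues get RPKM in [4, 100], silent ones in
    [0.01, 0.3] (margins that survive the noise), then multiplicative
    log-normal noise.  Stress genes follow their planted group's verdict
    trajectory with fold changes >= 4 (up) and <= 0.25 (down).  Planted
    assignments are recorded in ``truth``.
    """
    genes = list(truth.family_genes)
    n = len(genes)
    rng = np.random.default_rng(seed)

    # --- tissue patterns -------------------------------------------------
    spec = list(tissue_spec if tissue_spec is not None else default_tissue_spec(n))
    total = sum(count for _, count in spec)
    if total != n:
        raise ValueError(f"tissue_spec covers {total} genes, need {n}")
    shuffled = list(genes)
    rng.shuffle(shuffled)
    it = iter(shuffled)
    for pattern, count in spec:
        for _ in range(count):
            gene = next(it)
            if pattern == "ALL":
                chosen: tuple[str, ...] = tuple(TISSUES)
            elif pattern == "NONE":
                chosen = ()
            elif pattern == "RANDOM":
                size = int(rng.integers(1, len(TISSUES)))  # proper non-empty subset
                pick = set(rng.choice(list(TISSUES), size=size, replace=False))
                chosen = tuple(t for t in TISSUES if t in pick)
            elif isinstance(pattern, tuple):
                unknown = set(pattern) - set(TISSUES)
                if unknown:
                    raise ValueError(f"unknown tissues in pattern: {sorted(unknown)}")
                chosen = tuple(t for t in TISSUES if t in pattern)
            else:
                raise ValueError(f"unknown pattern label {pattern!r}")
            truth.tissue_pattern[gene] = chosen

    values = np.zeros((n, len(TISSUES)))
    for gi, gene in enumerate(genes):
        present = set(truth.tissue_pattern[gene])
        for ti, tissue in enumerate(TISSUES):
            base = rng.uniform(4.0, 100.0) if tissue in present else rng.uniform(0.01, 0.3)
            values[gi, ti] = _noisy(rng, base, noise_sd)
    tissues_table = ExpressionTable(
        gene_ids=genes, condition_ids=list(TISSUES), values=values
    )

    # --- stress groups ---------------------------------------------------
    defaults = default_stress_spec(n)
    spec_w = dict((stress_spec or {}).get("waterlogging", defaults["waterlogging"]))
    spec_d = dict((stress_spec or {}).get("drought", defaults["drought"]))
    unknown = (set(spec_w) - set(WATERLOGGING_SIGNATURES)) | (
        set(spec_d) - set(DROUGHT_SIGNATURES)
    )
    if unknown:
        raise ValueError(f"unknown stress pattern group labels: {sorted(unknown)}")
    n_w = sum(spec_w.values())
    n_d = sum(spec_d.values())
    if overlap is None:
        overlap = min(28, n_w, n_d)
    if overlap > min(n_w, n_d):
        raise ValueError("overlap exceeds a stress DEG set size")
    if n_w > n or n_d > n or n_w + n_d - overlap > n:
        raise ValueError("stress group sizes exceed the family gene count")
    pool = list(genes)
    rng.shuffle(pool)
    w_genes = pool[:n_w]
    d_genes = w_genes[:overlap] + pool[n_w : n_w + (n_d - overlap)]
    it_w = iter(w_genes)
    for group in sorted(spec_w):
        for _ in range(spec_w[group]):
            truth.waterlogging_group[next(it_w)] = group
    it_d = iter(d_genes)
    for group in sorted(spec_d):
        for _ in range(spec_d[group]):
            truth.drought_group[next(it_d)] = group

    def stress_table(
        group_of: Mapping[str, str],
        signatures: Mapping[str, tuple[str, ...]],
        time_points: Sequence[str],
    ) -> ExpressionTable:
        cols = ["control", *time_points]
        vals = np.zeros((n, len(cols)))
        for gi, gene in enumerate(genes):
            control = rng.uniform(5.0, 50.0)
            vals[gi, 0] = _noisy(rng, control, noise_sd)
            sig = signatures.get(group_of.get(gene, ""), (NS,) * len(time_points))
            for ti, verdict in enumerate(sig, start=1):
                if verdict == UP:
                    fold = rng.uniform(5.0, 40.0)
                elif verdict == DOWN:
                    fold = rng.uniform(0.03, 0.2)
                else:
                    fold = 1.0
                vals[gi, ti] = _noisy(rng, control * fold, noise_sd)
        return ExpressionTable(gene_ids=genes, condition_ids=cols, values=vals)

    waterlogging = stress_table(
        truth.waterlogging_group, WATERLOGGING_SIGNATURES, WATERLOGGING_TIME_POINTS
    )
    drought = stress_table(
        truth.drought_group, DROUGHT_SIGNATURES, DROUGHT_TIME_POINTS
    )
    return tissues_table, waterlogging, drought


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def simulate_qpcr(
    genes: Sequence[str],
    fold_changes: Sequence[float],
    reference_gene: str = "ACTIN",
    seed: int = 0,
    n_replicates: int = 3,
    base_ct: float = 30.0,
    ct_noise_sd: float = 0.15,
) -> pd.DataFrame:
    """Generate a tidy Ct table (gene_id, condition, replicate, ct).

    Ct = base - log2(expression) + Normal(0, ct_noise_sd); control
    expression is 1, stress expression equals the planted fold change.  The
    reference gene has fold change 1 by construction.
    """
    if len(genes) != len(fold_changes):
        raise ValueError("genes and fold_changes must have equal length")
    for fold in fold_changes:
        if fold <= 0:
            raise ValueError(f"fold change must be positive, got {fold}")
    rng = np.random.default_rng(seed)
    rows = []

    def add(gene: str, condition: str, expression: float) -> None:
        for rep in range(1, n_replicates + 1):
            ct = base_ct - np.log2(expression) + rng.normal(0.0, ct_noise_sd)
            rows.append(
                {"gene_id": gene, "condition": condition, "replicate": rep, "ct": float(ct)}
            )

    add(reference_gene, "control", 1.0)
    add(reference_gene, "stress", 1.0)
    for gene, fold in zip(genes, fold_changes):
        add(gene, "control", 1.0)
        add(gene, "stress", float(fold))
    return pd.DataFrame(rows, columns=["gene_id", "condition", "replicate", "ct"])
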