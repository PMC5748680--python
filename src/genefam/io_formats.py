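"""Readers/writers for the external formats the pipeline touches.

All coordinates are 1-based inclusive (GFF3 dialect) throughout; no
half-open conversions are exposed.  Reports are TSV (UTF-8, '.' decimal).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("genefam")

#: Sentinel linkage-group value for genes not anchored to any LG.  Genes on
#: named scaffolds keep their scaffold id; this value marks a gene with no
#: placement information at all.
UNANCHORED = "UNANCHORED"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene with linkage-group placement and exon structure."""

    gene_id: str
    linkage_group: str
    start: int
    end: int
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        if not exons:
            # genes lacking exon features are treated as single-exon
            exons = ((self.start, self.end),)
        exons = tuple(sorted(exons))
        prev_end = None
        for s, e in exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon {s}-{e} inverted")
            if s < self.start or e > self.end:
                raise ValueError(
                    f"{self.gene_id}: exon {s}-{e} outside gene span "
                    f"{self.start}-{self.end}"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons at {s}-{e}")
            prev_end = e
        object.__setattr__(self, "exons", exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def anchored(self) -> bool:
        return self.linkage_group != UNANCHORED


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence keyed by its gene id.

    Sequences are uppercased on construction.  ``X`` is permitted but is
    excluded from all numeric computations downstream.
    """

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ExpressionTable:
    """A genes x conditions matrix of non-negative RPKM values."""

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValueError(
                f"value matrix {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_ids)} conditions"
            )
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise ValueError("condition ids are not unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids are not unique")
        if np.any(self.values < 0):
            raise ValueError("negative expression values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.condition_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionTable":
        return cls(
            gene_ids=[str(i) for i in frame.index],
            condition_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with printed-cutoff defaults."""

    profile_score_frac: float = 0.60  # threshold as fraction of consensus self-score
    rpkm_expressed: float = 1.0
    fc_up: float = 2.0
    fc_down: float = 0.5
    fc_epsilon: float = 0.01
    evalue_max: float = 1e-40
    min_similarity: float = 0.70
    max_intervening: int = 3
    gap_open: float = 10.0
    gap_extend: float = 0.2
    bootstrap_reps: int = 100
    subgroup_distance_ceiling: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "profile_score_frac",
            "rpkm_expressed",
            "fc_up",
            "fc_down",
            "fc_epsilon",
            "evalue_max",
            "min_similarity",
            "gap_open",
            "gap_extend",
            "subgroup_distance_ceiling",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.max_intervening < 0 or self.bootstrap_reps < 1:
            raise ValueError("max_intervening >= 0 and bootstrap_reps >= 1 required")
        if not (self.fc_down < 1.0 < self.fc_up):
            raise ValueError("thresholds must satisfy fc_down < 1 < fc_up")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA; headers are split at the first whitespace.

    Raises :class:`FormatError` listing offenders on duplicate ids, and on
    empty sequences.
    """
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        seen[rec.id] = seen.get(rec.id, 0) + 1
        records.append(ProteinRecord(gene_id=rec.id, sequence=seq))
    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise FormatError(f"{path}: duplicate record ids: {dups}")
    logger.info("read %d FASTA records from %s", len(records), path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().rstrip(";").split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"bad attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene and exon features from a GFF3 file.

    Coordinates are kept 1-based inclusive.  Exons are attached to their
    ``Parent`` gene and sorted; a gene with no exon lines becomes
    single-exon spanning the gene.  An exon outside its parent's span is an
    error naming the gene; a malformed line is an error naming the line
    number.
    """
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
            try:
                start, end = int(start_s), int(end_s)
                attrs = _parse_attributes(attrs_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene feature without ID")
                if gid in genes:
                    raise FormatError(f"{path}:{lineno}: duplicate gene id {gid!r}")
                genes[gid] = {
                    "linkage_group": seqid,
                    "start": start,
                    "end": end,
                    "strand": strand if strand in "+-" else "+",
                }
                order.append(gid)
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError(f"{path}:{lineno}: exon without Parent")
                exons.setdefault(parent, []).append((start, end))
    missing = sorted(set(exons) - set(genes))
    if missing:
        raise FormatError(f"{path}: exon Parent ids with no gene feature: {missing}")
    models: list[GeneModel] = []
    for gid in order:
        info = genes[gid]
        gene_exons = sorted(exons.get(gid, []))
        for s, e in gene_exons:
            if s < info["start"] or e > info["end"]:
                raise FormatError(
                    f"{path}: exon {s}-{e} of gene {gid!r} lies outside the "
                    f"gene span {info['start']}-{info['end']}"
                )
        models.append(
            GeneModel(
                gene_id=gid,
                linkage_group=info["linkage_group"],
                start=info["start"],
                end=info["end"],
                strand=info["strand"],
                exons=tuple(gene_exons),
            )
        )
    logger.info("read %d gene models from %s", len(models), path)
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models (genes + exon children) as GFF3."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            fh.write(
                "\t".join(
                    [
                        gm.linkage_group,
                        "genefam",
                        "gene",
                        str(gm.start),
                        str(gm.end),
                        ".",
                        gm.strand,
                        ".",
                        f"ID={gm.gene_id}",
                    ]
                )
                + "\n"
            )
            for s, e in gm.exons:
                fh.write(
                    "\t".join(
                        [
                            gm.linkage_group,
                            "genefam",
                            "exon",
                            str(s),
                            str(e),
                            ".",
                            gm.strand,
                            ".",
                            f"Parent={gm.gene_id}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def read_expression_tsv(path: str | Path) -> ExpressionTable:
    """Read a genes x conditions RPKM table.

    First column holds gene ids, header row holds condition ids.  Ragged
    rows, non-numeric cells (reported with coordinates), negative values
    and duplicate gene ids are errors.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty expression table")
    header = lines[0].split("\t")
    condition_ids = header[1:]
    ncols = len(header)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cols = line.split("\t")
        if len(cols) != ncols:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(cols)} columns, expected {ncols})"
            )
        gene_ids.append(cols[0])
        row: list[float] = []
        for j, cell in enumerate(cols[1:], start=1):
            try:
                value = float(cell)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric value {cell!r} in column "
                    f"{header[j]!r}"
                ) from exc
            if value < 0:
                raise FormatError(
                    f"{path}:{lineno}: negative value {value} in column {header[j]!r}"
                )
            row.append(value)
        rows.append(row)
    dups = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
    if dups:
        raise FormatError(f"{path}: duplicated gene ids: {dups}")
    table = ExpressionTable(
        gene_ids=gene_ids,
        condition_ids=condition_ids,
        values=np.array(rows, dtype=float) if rows else np.empty((0, len(condition_ids))),
    )
    logger.info("read %d x %d expression table from %s", len(gene_ids), len(condition_ids), path)
    return table


def write_expression_tsv(table: ExpressionTable, path: str | Path) -> None:
    frame = table.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.6g")


def read_ct_tsv(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table with columns gene_id, condition, replicate, ct."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "condition": str})
    required = {"gene_id", "condition", "replicate", "ct"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if (frame["ct"] <= 0).any():
        raise FormatError(f"{path}: Ct values must be > 0")
    bad = set(frame["condition"]) - {"stress", "control"}
    if bad:
        raise FormatError(f"{path}: unknown conditions {sorted(bad)}")
    return frame


# ---------------------------------------------------------------------------
# Plain-text PWM
# ---------------------------------------------------------------------------


def read_pwm(path: str | Path) -> tuple[str, np.ndarray]:
    """Read a plain-text PWM: header of amino-acid letters, one row per
    position with 20 columns.  Returns (alphabet, L x 20 matrix)."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty PWM file")
    alphabet = "".join(lines[0].split())
    if sorted(alphabet) != sorted(AMINO_ACIDS):
        raise FormatError(f"{path}: header must list the 20 amino acids once each")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split()
        if len(cells) != 20:
            raise FormatError(f"{path}: row {lineno} has {len(cells)} columns, expected 20")
        rows.append([float(c) for c in cells])
    matrix = np.array(rows, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise FormatError(f"{path}: non-finite PWM entries")
    return alphabet, matrix


def write_pwm(alphabet: str, matrix: np.ndarray, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(" ".join(alphabet) + "\n")
        for row in np.asarray(matrix):
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

REPORT_TABLES = (
    "family_summary",
    "tandem_arrays",
    "ortholog_pairs",
    "tissue_groups",
    "deg_calls",
    "venn_counts",
)


def write_report(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write the report TSV set; deterministic row order (sorted by gene_id
    where the table has one).  Unknown table names are written too, so
    callers can add ad-hoc outputs."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise FormatError(f"cannot write to {out}: {exc}") from exc
    written: list[Path] = []
    for name in sorted(tables):
        frame = tables[name].copy()
        if "gene_id" in frame.columns:
            frame = frame.sort_values(
                ["gene_id"] + [c for c in frame.columns if c != "gene_id"],
                kind="mergesort",
            )
        path = out / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)
    return written


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero, matching the headline-percentage style."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
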