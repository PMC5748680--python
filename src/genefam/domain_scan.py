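"""Repeat-domain detection, subfamily classification, and pI/Mw.

Detection is log-odds PWM scanning with greedy non-overlap resolution; the
repeat count per protein determines the subfamily verdict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from genefam.io_formats import AMINO_ACIDS, ProteinRecord, read_pwm

logger = logging.getLogger("genefam.domain_scan")

NOT_FAMILY = "NOT_FAMILY"
ONE_R = "1R"
R2R3 = "R2R3"
R1R2R3 = "R1R2R3"
ATYPICAL = "ATYPICAL"

#: Subfamilies in report order.
SUBFAMILIES = (ONE_R, R2R3, R1R2R3, ATYPICAL)

# Bjellqvist pKa values (ExPASy-style); pluggable via compute_pI arguments.
PKA_NTERM = 7.5
PKA_CTERM = 3.55
PKA_POSITIVE = {"K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}

# Average residue masses (Da); protein Mw = sum + one water.
WATER_MW = 18.01524
RESIDUE_MW = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}


@dataclass(frozen=True)
class RepeatProfile:
    """A position weight matrix of per-position log-odds scores."""

    alphabet: str
    weights: np.ndarray  # L x 20 log-odds
    score_threshold: float

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        if weights.ndim != 2 or weights.shape[1] != len(self.alphabet):
            raise ValueError("weights must be L x |alphabet|")
        if not np.all(np.isfinite(weights)):
            raise ValueError("non-finite profile weights")
        if not np.isfinite(self.score_threshold):
            raise ValueError("non-finite score threshold")
        object.__setattr__(self, "weights", weights)

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @property
    def consensus_self_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(self.alphabet[j] for j in self.weights.argmax(axis=1))

    @classmethod
    def from_probabilities(
        cls,
        alphabet: str,
        probabilities: np.ndarray,
        threshold_frac: float = 0.60,
        background: float | np.ndarray = 1.0 / 20,
        floor: float = 1e-4,
    ) -> "RepeatProfile":
        """Build log-odds weights log2(p/q) from per-position residue
        probabilities; the threshold defaults to ``threshold_frac`` of the
        consensus self-score."""
        probs = np.asarray(probabilities, dtype=float)
        probs = np.clip(probs, floor, None)
        probs = probs / probs.sum(axis=1, keepdims=True)
        weights = np.log2(probs / background)
        self_score = float(weights.max(axis=1).sum())
        return cls(
            alphabet=alphabet,
            weights=weights,
            score_threshold=threshold_frac * self_score,
        )

    @classmethod
    def from_pwm_file(
        cls, path: str | Path, threshold_frac: float = 0.60
    ) -> "RepeatProfile":
        alphabet, matrix = read_pwm(path)
        return cls.from_probabilities(alphabet, matrix, threshold_frac=threshold_frac)

    def probabilities(self) -> np.ndarray:
        """Invert the log-odds back to per-position residue probabilities."""
        probs = (2.0**self.weights) / 20.0
        return probs / probs.sum(axis=1, keepdims=True)


def default_repeat_profile(threshold_frac: float = 0.60) -> RepeatProfile:
    """The packaged 52-residue repeat profile fixture."""
    ref = resources.files("genefam.data").joinpath("repeat_pwm.txt")
    with resources.as_file(ref) as path:
        return RepeatProfile.from_pwm_file(path, threshold_frac=threshold_frac)


@dataclass(frozen=True)
class DomainHit:
    """One repeat occurrence; 1-based inclusive residue coordinates."""

    gene_id: str
    start: int
    end: int
    score: float


@dataclass(frozen=True)
class SubfamilyCall:
    gene_id: str
    n_repeats: int
    subfamily: str


def _index_sequence(sequence: str, profile: RepeatProfile) -> np.ndarray:
    """Map residues to alphabet indices; -1 marks X, -2 other non-standard."""
    lookup = np.full(128, -2, dtype=np.int64)
    for j, aa in enumerate(profile.alphabet):
        lookup[ord(aa)] = j
    lookup[ord("X")] = -1
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return lookup[codes]


def scan_repeats(protein: ProteinRecord, profile: RepeatProfile) -> list[DomainHit]:
    """Find repeat occurrences scoring >= the profile threshold.

    Among all windows at or above threshold, a maximal non-overlapping set
    is chosen greedily by descending score, ties broken by smaller start.
    X scores 0 at every position; any other non-standard residue scores the
    worst value of its column (with a warning, not an error).
    """
    seq = protein.sequence
    L = profile.length
    n = len(seq)
    if n < L:
        return []
    idx = _index_sequence(seq, profile)
    if np.any(idx == -2):
        bad = sorted({seq[i] for i in np.nonzero(idx == -2)[0]})
        logger.warning(
            "%s: non-standard residues %s scored as worst column value",
            protein.gene_id,
            bad,
        )
    # per-position score vectors for each residue of the sequence
    col_min = profile.weights.min(axis=1)
    n_windows = n - L + 1
    scores = np.zeros(n_windows, dtype=float)
    for offset in range(L):
        codes = idx[offset : offset + n_windows]
        row = profile.weights[offset]
        contrib = np.where(
            codes >= 0,
            row[np.clip(codes, 0, None)],
            np.where(codes == -1, 0.0, col_min[offset]),
        )
        scores += contrib
    passing = np.nonzero(scores >= profile.score_threshold)[0]
    # greedy: descending score, then smaller start
    order = sorted(passing, key=lambda i: (-scores[i], i))
    chosen: list[int] = []
    for i in order:
        if all(abs(i - j) >= L for j in chosen):
            chosen.append(i)
    chosen.sort()
    return [
        DomainHit(
            gene_id=protein.gene_id,
            start=i + 1,
            end=i + L,
            score=float(scores[i]),
        )
        for i in chosen
    ]


def classify_subfamily(hits: Sequence[DomainHit], gene_id: str | None = None) -> SubfamilyCall:
    """Map a protein's repeat count to its subfamily verdict.

    0 -> NOT_FAMILY, 1 -> 1R, 2 -> R2R3, 3 -> R1R2R3, >=4 -> ATYPICAL.
    """
    n = len(hits)
    if gene_id is None:
        if not hits:
            raise ValueError("gene_id required when the hit list is empty")
        gene_id = hits[0].gene_id
    if n == 0:
        subfamily = NOT_FAMILY
    elif n == 1:
        subfamily = ONE_R
    elif n == 2:
        subfamily = R2R3
    elif n == 3:
        subfamily = R1R2R3
    else:
        subfamily = ATYPICAL
    return SubfamilyCall(gene_id=gene_id, n_repeats=n, subfamily=subfamily)


# ---------------------------------------------------------------------------
# Protein physics
# ---------------------------------------------------------------------------


def _net_charge(
    pH: float,
    counts: Mapping[str, int],
    pka_positive: Mapping[str, float],
    pka_negative: Mapping[str, float],
    pka_nterm: float,
    pka_cterm: float,
) -> float:
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka_nterm))
    charge -= 1.0 / (1.0 + 10.0 ** (pka_cterm - pH))
    for aa, pka in pka_positive.items():
        charge += counts.get(aa, 0) / (1.0 + 10.0 ** (pH - pka))
    for aa, pka in pka_negative.items():
        charge -= counts.get(aa, 0) / (1.0 + 10.0 ** (pka - pH))
    return charge


def compute_pI(
    sequence: str,
    *,
    pka_positive: Mapping[str, float] = PKA_POSITIVE,
    pka_negative: Mapping[str, float] = PKA_NEGATIVE,
    pka_nterm: float = PKA_NTERM,
    pka_cterm: float = PKA_CTERM,
    tolerance: float = 1e-4,
) -> float:
    """Isoelectric point by bisection on the net-charge curve.

    The charge model sums Henderson-Hasselbalch terms over the termini and
    the ionizable side chains (K, R, H, D, E, C, Y); X residues are ignored.
    Returns the pH in (0, 14) where |charge| < ``tolerance``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper().replace("X", "")
    counts = {aa: seq.count(aa) for aa in set(pka_positive) | set(pka_negative)}

    def charge(pH: float) -> float:
        return _net_charge(pH, counts, pka_positive, pka_negative, pka_nterm, pka_cterm)

    lo, hi = 0.0, 14.0
    # charge is monotonically decreasing in pH; iterate until the root is
    # pinned tightly in pH (charge then satisfies |charge| < tolerance too)
    mid = 7.0
    while hi - lo > 1e-8:
        mid = 0.5 * (lo + hi)
        if charge(mid) > 0:
            lo = mid
        else:
            hi = mid
    if abs(charge(mid)) >= tolerance:  # pragma: no cover - defensive
        raise ArithmeticError("pI bisection failed to reach charge tolerance")
    return mid


def compute_mw(sequence: str) -> float:
    """Average molecular weight in daltons: residue masses plus one water.

    X residues are excluded from the sum; any other unknown residue is an
    error.
    """
    if not sequence:
        raise ValueError("empty sequence")
    total = WATER_MW
    for aa in sequence.upper():
        if aa == "X":
            continue
        try:
            total += RESIDUE_MW[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None
    return total


# ---------------------------------------------------------------------------
# Family summary (Table-1 analog)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilySummary:
    counts: dict[str, int]
    percentages: dict[str, float]  # rounded to 2 decimals
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subfamily": list(SUBFAMILIES),
                "count": [self.counts.get(s, 0) for s in SUBFAMILIES],
                "percentage": [self.percentages.get(s, 0.0) for s in SUBFAMILIES],
            }
        )


def summarize_family(calls: Iterable[SubfamilyCall]) -> FamilySummary:
    """Count family members per subfamily; percentage = 100 x count/total
    rounded to 2 decimals.  NOT_FAMILY calls are excluded from the family."""
    counts = {s: 0 for s in SUBFAMILIES}
    for call in calls:
        if call.subfamily == NOT_FAMILY:
            continue
        counts[call.subfamily] += 1
    total = sum(counts.values())
    if total == 0:
        return FamilySummary(counts=counts, percentages={s: 0.0 for s in SUBFAMILIES}, total=0)
    percentages = {s: round(100.0 * c / total, 2) for s, c in counts.items()}
    return FamilySummary(counts=counts, percentages=percentages, total=total)


def scan_proteome(
    proteins: Sequence[ProteinRecord], profile: RepeatProfile
) -> tuple[dict[str, list[DomainHit]], list[SubfamilyCall]]:
    """Scan every protein and classify; convenience for the CLI and tests."""
    hits: dict[str, list[DomainHit]] = {}
    calls: list[SubfamilyCall] = []
    for rec in proteins:
        h = scan_repeats(rec, profile)
        hits[rec.gene_id] = h
        calls.append(classify_subfamily(h, gene_id=rec.gene_id))
    return hits, calls
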