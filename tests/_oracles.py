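"""Independent brute-force oracles used to cross-check the implementations.

Each oracle deliberately takes the most literal route (exhaustive
enumeration, dense grids, union-find) and shares no code with the package
paths it checks.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


# --- window scanning -------------------------------------------------------


def brute_scan(sequence: str, alphabet: str, weights: np.ndarray, threshold: float):
    """Score every window explicitly, then greedily pick non-overlapping
    hits by descending score (ties by smaller start).  Returns a list of
    (start_1based, end_1based, score)."""
    L = weights.shape[0]
    col_min = weights.min(axis=1)
    scores = []
    for i in range(len(sequence) - L + 1):
        s = 0.0
        for k in range(L):
            aa = sequence[i + k]
            if aa == "X":
                continue
            elif aa in alphabet:
                s += weights[k, alphabet.index(aa)]
            else:
                s += col_min[k]
        scores.append(s)
    passing = [i for i, s in enumerate(scores) if s >= threshold]
    passing.sort(key=lambda i: (-scores[i], i))
    chosen = []
    for i in passing:
        if all(abs(i - j) >= L for j in chosen):
            chosen.append(i)
    return [(i + 1, i + L, scores[i]) for i in sorted(chosen)]


# --- isoelectric point -----------------------------------------------------


def grid_pI(
    sequence: str,
    pka_positive: dict,
    pka_negative: dict,
    pka_nterm: float,
    pka_cterm: float,
    step: float = 1e-4,
) -> float:
    """Dense pH grid scan: the grid point with net charge closest to zero."""
    seq = sequence.upper().replace("X", "")
    grid = np.arange(0.0, 14.0 + step, step)
    charge = 1.0 / (1.0 + 10.0 ** (grid - pka_nterm))
    charge -= 1.0 / (1.0 + 10.0 ** (pka_cterm - grid))
    for aa, pka in pka_positive.items():
        charge += seq.count(aa) / (1.0 + 10.0 ** (grid - pka))
    for aa, pka in pka_negative.items():
        charge -= seq.count(aa) / (1.0 + 10.0 ** (pka - grid))
    return float(grid[np.argmin(np.abs(charge))])


# --- tandem arrays ---------------------------------------------------------


def tandem_oracle(genes_by_lg: dict, family: set, max_intervening: int = 3):
    """All-pairs chaining + union-find connected components.

    ``genes_by_lg`` maps linkage group to the ordered list of gene ids.
    Returns the set of frozensets of member ids (components of size >= 2).
    """
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    for lg, ordered in genes_by_lg.items():
        fam_positions = [(i, g) for i, g in enumerate(ordered) if g in family]
        for g in ordered:
            if g in family:
                parent.setdefault(g, g)
        for ai in range(len(fam_positions)):
            for bi in range(ai + 1, len(fam_positions)):
                (pa, ga), (pb, gb) = fam_positions[ai], fam_positions[bi]
                if pb - pa - 1 <= max_intervening:
                    union(ga, gb)
    comps: dict = {}
    for g in parent:
        comps.setdefault(find(g), set()).add(g)
    return {frozenset(c) for c in comps.values() if len(c) >= 2}


# --- alignment -------------------------------------------------------------


def nw_affine_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Optimal global affine-gap score by memoized recursion over
    (i, j, previous move); a gap of length L costs open + (L-1)*extend."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(float(matrix[a[i], b[j]]) + best(i + 1, j + 1, "M"))
        if i < len(a):  # gap in b
            cost = gap_extend if prev == "X" else gap_open
            options.append(-cost + best(i + 1, j, "X"))
        if j < len(b):  # gap in a
            cost = gap_extend if prev == "Y" else gap_open
            options.append(-cost + best(i, j + 1, "Y"))
        return max(options)

    return best(0, 0, "S")


def enumerate_global_score(
    a: str, b: str, matrix, gap_open: float, gap_extend: float
) -> float:
    """Enumeration over move strings, tracking consumed positions."""
    best = [-np.inf]

    def rec(i, j, prev, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + float(matrix[a[i], b[j]]))
        if i < len(a):
            rec(i + 1, j, "X", score - (gap_extend if prev == "X" else gap_open))
        if j < len(b):
            rec(i, j + 1, "Y", score - (gap_extend if prev == "Y" else gap_open))

    rec(0, 0, "S", 0.0)
    return best[0]


def sw_oracle(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Exhaustive local alignment: the best global affine score over every
    substring pair (the empty alignment scores 0)."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(
                        best,
                        nw_affine_score(a[i1:i2], b[j1:j2], matrix, gap_open, gap_extend),
                    )
    return best


# --- random additive trees -------------------------------------------------


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random binary tree with positive branch lengths.

    Returns (taxa, distance matrix, bipartitions) where bipartitions is the
    set of canonical non-trivial splits (side not containing taxon 0's
    name).
    """
    taxa = [f"t{i:02d}" for i in range(n_taxa)]
    active = list(range(n_taxa))
    all_d = np.zeros((n_taxa, n_taxa))
    index = {t: i for i, t in enumerate(taxa)}
    splits = set()
    next_id = n_taxa
    clusters = {i: {taxa[i]} for i in range(n_taxa)}
    depths = {i: {taxa[i]: 0.0} for i in range(n_taxa)}
    while len(active) > 1:
        ia, ib = rng.choice(len(active), size=2, replace=False)
        a, b = active[ia], active[ib]
        la = float(rng.uniform(0.05, 1.0))
        lb = float(rng.uniform(0.05, 1.0))
        for ta in clusters[a]:
            for tb in clusters[b]:
                d = depths[a][ta] + la + depths[b][tb] + lb
                all_d[index[ta], index[tb]] = d
                all_d[index[tb], index[ta]] = d
        merged = clusters[a] | clusters[b]
        if 2 <= len(merged) <= n_taxa - 2:
            side = frozenset(merged)
            if taxa[0] in side:
                side = frozenset(set(taxa) - merged)
            splits.add(side)
        new_depths = {}
        for ta in clusters[a]:
            new_depths[ta] = depths[a][ta] + la
        for tb in clusters[b]:
            new_depths[tb] = depths[b][tb] + lb
        clusters[next_id] = merged
        depths[next_id] = new_depths
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return taxa, all_d, splits
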