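"""Distance-based phylogeny: global alignment p-distances, Neighbor-Joining,
column-resampling bootstrap over a star alignment, and reference-anchored
subgroup assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from genefam._alignment import load_matrix, make_aligner, sanitize
from genefam.io_formats import ProteinRecord

logger = logging.getLogger("genefam.phylogeny")

UNASSIGNED = "UNASSIGNED"


# ---------------------------------------------------------------------------
# Pairwise global alignment
# ---------------------------------------------------------------------------


def global_align(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.2,
) -> tuple[str, str, float]:
    """Needleman-Wunsch with affine gaps; returns (aligned_a, aligned_b, score).

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  Residues
    absent from the substitution matrix are scored via its wildcard row.
    The traceback is deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    matrix = load_matrix(matrix_name)
    sa, sb = sanitize(a, matrix.alphabet), sanitize(b, matrix.alphabet)
    aligner = make_aligner(matrix_name, gap_open, gap_extend, mode="global")
    aln = aligner.align(sa, sb)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if np.any(self.d < 0):
            raise ValueError("negative distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("non-zero diagonal")


def p_distance(aligned_a: str, aligned_b: str) -> float:
    """Mismatch fraction over aligned columns, excluding gap-gap columns.

    A residue opposite a gap counts as a mismatch.
    """
    cols = [(x, y) for x, y in zip(aligned_a, aligned_b) if not (x == "-" and y == "-")]
    if not cols:
        raise ValueError("alignment has no informative columns")
    mism = sum(1 for x, y in cols if x != y)
    return mism / len(cols)


def distance_matrix(
    records: Sequence[ProteinRecord],
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.2,
) -> DistanceMatrix:
    """All-pairs global-alignment p-distances."""
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aa, ab, _ = global_align(
                records[i].sequence, records[j].sequence, matrix_name, gap_open, gap_extend
            )
            d[i, j] = d[j, i] = p_distance(aa, ab)
    return DistanceMatrix(taxa=[r.gene_id for r in records], d=d)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to parent; ignored at the root
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, with_support: bool = True) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._newick(with_support) for c in self.children)
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6f}"


@dataclass
class PhyloTree:
    """Unrooted tree, stored rooted at the final join (a trifurcation for
    n >= 3, a bifurcation for n = 2)."""

    root: TreeNode
    taxa: list[str]

    def newick(self, with_support: bool = True) -> str:
        inner = ",".join(c._newick(with_support) for c in self.root.children)
        return f"({inner});"

    def _edges(self):
        """Yield (parent, child) over the rooted representation."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child in node.children:
                yield node, child
                stack.append(child)

    def edge_count(self) -> int:
        return sum(1 for _ in self._edges())

    def path_length_matrix(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path lengths along the tree."""
        adjacency: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}
        index: dict[int, int] = {}

        def walk(node: TreeNode) -> None:
            nid = id(node)
            adjacency.setdefault(nid, [])
            if node.is_leaf:
                names[nid] = node.name  # type: ignore[assignment]
            for child in node.children:
                cid = id(child)
                adjacency[nid].append((cid, child.length))
                adjacency.setdefault(cid, []).append((nid, child.length))
                walk(child)

        walk(self.root)
        leaf_ids = [nid for nid in names]
        order = {t: i for i, t in enumerate(self.taxa)}
        leaf_ids.sort(key=lambda nid: order[names[nid]])
        n = len(leaf_ids)
        dist = np.zeros((n, n))
        for i, src in enumerate(leaf_ids):
            seen = {src: 0.0}
            stack = [src]
            while stack:
                cur = stack.pop()
                for nxt, w in adjacency[cur]:
                    if nxt not in seen:
                        seen[nxt] = seen[cur] + w
                        stack.append(nxt)
            for j, dst in enumerate(leaf_ids):
                dist[i, j] = seen[dst]
        return [names[nid] for nid in leaf_ids], dist

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Non-trivial splits keyed canonically (the side not containing the
        lexicographically smallest taxon), mapped to the child node whose
        subtree realizes the split."""
        all_taxa = frozenset(self.taxa)
        anchor = min(all_taxa)
        out: dict[frozenset, TreeNode] = {}
        for parent, child in self._edges():
            below = frozenset(leaf.name for leaf in child.leaves())
            if len(below) < 2 or len(all_taxa - below) < 2:
                continue
            key = below if anchor not in below else all_taxa - below
            out[key] = child
        return out


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    """Clamp negative NJ branch estimates to 0, moving the deficit to the
    sibling branch (standard practice)."""
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Classical Saitou-Nei Neighbor-Joining.

    Ties in the Q criterion are broken by the lexicographically smallest
    (cluster label) pair, where a cluster is labeled by its smallest leaf
    name.  For an additive input matrix the output path metric reproduces
    the input exactly (up to floating error).
    """
    n = len(D.taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in D.taxa]
    labels: list[str] = list(D.taxa)
    d = D.d.astype(float).copy()

    if n == 2:
        nodes[0].length = D.d[0, 1] / 2.0
        nodes[1].length = D.d[0, 1] / 2.0
        root = TreeNode(children=[nodes[0], nodes[1]])
        return PhyloTree(root=root, taxa=list(D.taxa))

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        # floating addition order can leave q asymmetric at ~1e-16; work on
        # the upper triangle only so every pair is considered exactly once
        q[np.tril_indices(m)] = np.inf
        qmin = q.min()
        candidates = [
            (min(labels[active[i]], labels[active[j]]),
             max(labels[active[i]], labels[active[j]]), i, j)
            for i, j in zip(*np.nonzero(q == qmin))
        ]
        _, _, bi, bj = min(candidates)
        i_glob, j_glob = active[bi], active[bj]
        dij = d[i_glob, j_glob]
        li = dij / 2.0 + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        nodes[i_glob].length = li
        nodes[j_glob].length = lj
        new_node = TreeNode(children=[nodes[i_glob], nodes[j_glob]])
        new_label = min(labels[i_glob], labels[j_glob])
        new_index = len(nodes)
        nodes.append(new_node)
        labels.append(new_label)
        new_row = np.zeros(len(nodes))
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i_glob, j_glob):
                continue
            dist = 0.5 * (d[i_glob, k] + d[j_glob, k] - dij)
            d[new_index, k] = d[k, new_index] = max(dist, 0.0)
        active = [k for k in active if k not in (i_glob, j_glob)] + [new_index]

    # resolve the final three clusters around a central node
    a, b, c = sorted(active, key=lambda k: labels[k])
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    nodes[a].length = max(la, 0.0)
    nodes[b].length = max(lb, 0.0)
    nodes[c].length = max(lc, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root=root, taxa=list(D.taxa))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def star_alignment(
    records: Sequence[ProteinRecord],
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.2,
) -> tuple[list[str], np.ndarray]:
    """Pseudo-reference alignment: every sequence is globally aligned to the
    longest one (ties by smallest id); columns are the center's positions,
    insertions relative to the center are dropped.

    Returns (ids sorted by id, n x L character matrix).
    """
    recs = sorted(records, key=lambda r: r.gene_id)
    center = max(recs, key=lambda r: (len(r.sequence), r.gene_id))
    L = len(center.sequence)
    rows = []
    for rec in recs:
        if rec.gene_id == center.gene_id:
            rows.append(list(center.sequence))
            continue
        ac, ar, _ = global_align(
            center.sequence, rec.sequence, matrix_name, gap_open, gap_extend
        )
        row = [ar[k] for k in range(len(ac)) if ac[k] != "-"]
        rows.append(row)
    matrix = np.array(rows, dtype="<U1")
    assert matrix.shape == (len(recs), L)
    return [r.gene_id for r in recs], matrix


def _column_p_distances(ids: list[str], columns: np.ndarray) -> DistanceMatrix:
    n = len(ids)
    d = np.zeros((n, n))
    gaps = columns == "-"
    for i in range(n):
        for j in range(i + 1, n):
            informative = ~(gaps[i] & gaps[j])
            total = informative.sum()
            if total == 0:
                dist = 1.0
            else:
                dist = float((columns[i] != columns[j])[informative].sum() / total)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa=ids, d=d)


def bootstrap_support(
    records: Sequence[ProteinRecord],
    n_reps: int,
    seed: int,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.2,
    tree: PhyloTree | None = None,
) -> dict[frozenset, float]:
    """Column-resampling bootstrap over the star alignment.

    Returns support per internal edge of the reference tree (built from the
    full pairwise distance matrix unless ``tree`` is given), as
    100 x replicate frequency of each bipartition.  Supports are also
    annotated onto the tree's nodes.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ids, columns = star_alignment(records, matrix_name, gap_open, gap_extend)
    if tree is None:
        tree = neighbor_joining(
            distance_matrix(
                sorted(records, key=lambda r: r.gene_id),
                matrix_name,
                gap_open,
                gap_extend,
            )
        )
    splits = tree.bipartitions()
    counts = {split: 0 for split in splits}
    rng = np.random.default_rng(seed)
    L = columns.shape[1]
    for _ in range(n_reps):
        draw = rng.integers(0, L, size=L)
        rep_d = _column_p_distances(ids, columns[:, draw])
        rep_tree = neighbor_joining(rep_d)
        rep_splits = rep_tree.bipartitions()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    supports = {split: 100.0 * c / n_reps for split, c in counts.items()}
    for split, node in splits.items():
        node.support = supports[split]
    return supports


# ---------------------------------------------------------------------------
# Subgroup assignment
# ---------------------------------------------------------------------------


def assign_subgroups(
    query_records: Sequence[ProteinRecord],
    reference_records: Sequence[ProteinRecord],
    reference_labels: Mapping[str, str],
    distance_ceiling: float = 0.8,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.2,
) -> dict[str, str]:
    """Assign each query the subgroup label of its nearest labeled reference
    by path length on a joint NJ tree; queries farther than
    ``distance_ceiling`` from every reference are UNASSIGNED."""
    if not reference_records:
        return {q.gene_id: UNASSIGNED for q in query_records}
    missing = sorted(
        r.gene_id for r in reference_records if r.gene_id not in reference_labels
    )
    if missing:
        raise ValueError(f"references without labels: {missing}")
    joint = list(query_records) + list(reference_records)
    if len(joint) < 2:
        return {q.gene_id: UNASSIGNED for q in query_records}
    tree = neighbor_joining(
        distance_matrix(joint, matrix_name, gap_open, gap_extend)
    )
    names, paths = tree.path_length_matrix()
    pos = {name: i for i, name in enumerate(names)}
    ref_ids = sorted(r.gene_id for r in reference_records)
    out: dict[str, str] = {}
    for q in query_records:
        qi = pos[q.gene_id]
        best = min(ref_ids, key=lambda r: (paths[qi, pos[r]], r))
        if paths[qi, pos[best]] > distance_ceiling:
            out[q.gene_id] = UNASSIGNED
        else:
            out[q.gene_id] = reference_labels[best]
    return out
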