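"""Distance phylogenetics: masking, LogDet distances, NJ, bootstrap.

The LogDet (paralinear) distance is computed from the 4x4 joint base-
frequency matrix F of a sequence pair (pairwise gap deletion; pseudocount
``c`` added to every cell before normalization to guard zero cells on short
V4-length alignments):

    d = -(1/4) [ ln det F - (1/2) sum_a ( ln f_a^(i) + ln f_a^(j) ) ]

where f^(i), f^(j) are the row/column marginals of F. LogDet is robust to
compositional bias across lineages, which is why it complements likelihood
methods on divergent environmental lineages. Trees are built by neighbour
joining (Saitou-Nei Q criterion with Studier-Keppler distance updates);
bootstrap support resamples alignment columns with replacement and maps the
bipartition frequencies onto the full-data tree.

The pseudocount biases distances upward by O(c / usable sites); it vanishes
for realistic alignment lengths but is visible on toy-sized inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultipleAlignment",
    "DistanceMatrix",
    "TreeNode",
    "SupportedTree",
    "mask_columns",
    "logdet_distance",
    "logdet_matrix",
    "nj_tree",
    "bootstrap_support",
    "leaf_distances",
    "bipartitions",
    "SATURATION_DISTANCE",
    "DEFAULT_PSEUDOCOUNT",
]

DEFAULT_PSEUDOCOUNT = 0.1
#: cap/sentinel for saturated pairs (non-positive determinant after
#: pseudocounting, or a distance beyond any phylogenetically usable range)
SATURATION_DISTANCE = 50.0

_ALPHABET = "ACGT-"
_ENCODE = {c: i for i, c in enumerate("ACGT")}
_ENCODE["-"] = -1


@dataclass
class MultipleAlignment:
    """Equal-length rows over {A,C,G,T,-}."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have the same length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        for rid, row in zip(self.ids, self.rows):
            bad = set(row) - set(_ALPHABET)
            if bad:
                raise ValueError(f"row {rid!r}: invalid symbols {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def encoded(self) -> np.ndarray:
        """Rows as an int matrix: A..T -> 0..3, gap -> -1."""
        return np.array(
            [[_ENCODE[c] for c in row] for row in self.rows], dtype=np.int8)

    @classmethod
    def from_fasta(cls, path) -> "MultipleAlignment":
        from .iolib import read_fasta
        records = read_fasta(path)
        # read_fasta uppercases and maps U->T; gaps pass through
        return cls(ids=[r[0] for r in records], rows=[r[1] for r in records])


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")
        self.matrix = m


def mask_columns(alignment: MultipleAlignment,
                 max_gap_fraction: float = 0.5) -> MultipleAlignment:
    """Drop alignment columns whose gap fraction exceeds the threshold.

    Column order is preserved; the kept-column count is len(result.rows[0]).
    """
    n = len(alignment.rows)
    keep = [
        j for j in range(alignment.n_columns)
        if sum(1 for row in alignment.rows if row[j] == "-") / n
        <= max_gap_fraction
    ]
    if not keep:
        raise ValueError(
            f"masking at gap fraction {max_gap_fraction} removed every column")
    return MultipleAlignment(
        ids=list(alignment.ids),
        rows=["".join(row[j] for j in keep) for row in alignment.rows],
    )


def _logdet_from_counts(counts: np.ndarray, pseudocount: float) -> float:
    F = (counts + pseudocount)
    F = F / F.sum()
    det = np.linalg.det(F)
    if det <= 0:
        return SATURATION_DISTANCE
    fi = F.sum(axis=1)
    fj = F.sum(axis=0)
    d = -0.25 * (np.log(det) - 0.5 * (np.log(fi).sum() + np.log(fj).sum()))
    if abs(d) < 1e-12:
        d = max(d, 0.0)
    # distances beyond the sentinel are as uninformative as a failed
    # determinant; capping keeps the sentinel maximal
    return float(min(d, SATURATION_DISTANCE))


def _pair_logdet(xi: np.ndarray, xj: np.ndarray, pseudocount: float,
                 label_i: str, label_j: str) -> float:
    usable = (xi >= 0) & (xj >= 0)
    if not usable.any():
        raise ValueError(
            f"no usable (gap-free) sites between {label_i!r} and {label_j!r}")
    a, b = xi[usable].astype(int), xj[usable].astype(int)
    # canonical orientation: exact symmetry even when the determinant is
    # numerically at the edge of the saturation guard
    if a.tobytes() > b.tobytes():
        a, b = b, a
    joint = np.bincount(a * 4 + b, minlength=16).reshape(4, 4).astype(float)
    return _logdet_from_counts(joint, pseudocount)


def logdet_distance(row_i: str, row_j: str,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Pairwise LogDet distance; sites with a gap in either row are skipped."""
    if len(row_i) != len(row_j):
        raise ValueError("rows must come from a common alignment")
    xi = np.array([_ENCODE[c] for c in row_i], dtype=np.int8)
    xj = np.array([_ENCODE[c] for c in row_j], dtype=np.int8)
    return _pair_logdet(xi, xj, pseudocount, "row_i", "row_j")


def logdet_matrix(alignment: MultipleAlignment,
                  pseudocount: float = DEFAULT_PSEUDOCOUNT) -> DistanceMatrix:
    """All-pairs LogDet distances of an alignment."""
    enc = alignment.encoded()
    n = len(alignment.ids)
    m = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            d = _pair_logdet(enc[i], enc[j], pseudocount,
                             alignment.ids[i], alignment.ids[j])
            if d == SATURATION_DISTANCE:
                saturated.append((alignment.ids[i], alignment.ids[j]))
            m[i, j] = m[j, i] = d
    return DistanceMatrix(list(alignment.ids), m, saturated)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an unrooted tree rendered as rooted at a trifurcation.

    ``length`` is the branch to the parent; ``support`` (internal nodes
    only) is bootstrap support in percent."""

    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0
    support: float | None = None
    node_id: int = -1  # creation order; NJ tie-breaking

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def to_newick(self, with_support: bool = False) -> str:
        def fmt(node: TreeNode, top: bool) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, False) for c in node.children)
                label = ""
                if with_support and node.support is not None:
                    label = f"{node.support:g}"
                body = f"({inner}){label}"
            return body if top else f"{body}:{node.length:.6f}"
        return fmt(self, True) + ";"


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions (one internal edge each), each
    normalized to the side NOT containing the reference (lexicographically
    smallest) leaf."""
    all_leaves = tree.leaf_names()
    ref = min(all_leaves)
    parts: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> None:
        for child in node.children:
            if not child.is_leaf:
                below = child.leaf_names()
                side = all_leaves - below if ref in below else below
                if 2 <= len(side) <= len(all_leaves) - 2:
                    parts.add(side)
                walk(child)
    walk(tree)
    return parts


def leaf_distances(tree: TreeNode) -> dict[tuple[str, str], float]:
    """Path lengths between all leaf pairs (sorted name tuples as keys)."""
    dists: dict[tuple[str, str], float] = {}

    def walk(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        merged: dict[str, float] = {}
        for child in node.children:
            sub = {k: v + child.length for k, v in walk(child).items()}
            for a, da in merged.items():
                for b, db in sub.items():
                    dists[tuple(sorted((a, b)))] = da + db
            merged.update(sub)
        return merged

    walk(tree)
    return dists


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbour joining with deterministic tie-breaking.

    Pairs minimizing the Q criterion are broken by the lowest (id, id) pair
    in creation order (input taxa first, in input order). A negative branch
    length produced by a join is clamped to zero and its deficit moved to
    the sister edge, preserving the joined pair's distance.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("NJ requires at least 3 taxa")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=dm.ids[i], node_id=i) for i in range(n)}
    D: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = float(dm.matrix[i, j])

    def dist(a: int, b: int) -> float:
        return 0.0 if a == b else D[(min(a, b), max(a, b))]

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                key = (min(i, j), max(i, j))
                if q < best_q - 1e-12 or (
                        abs(q - best_q) <= 1e-12 and (best is None or key < best)):
                    best_q = q
                    best = key
        i, j = best
        dij = dist(i, j)
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        node_i, node_j = nodes[i], nodes[j]
        node_i.length, node_j.length = li, lj
        parent = TreeNode(children=[node_i, node_j], node_id=next_id)
        nodes[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            duk = (dist(i, k) + dist(j, k) - dij) / 2
            D[(min(next_id, k), max(next_id, k))] = duk
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    la = (dist(a, b) + dist(a, c) - dist(b, c)) / 2
    lb = dist(a, b) - la
    lc = dist(a, c) - la
    la, lb, lc = (max(v, 0.0) for v in (la, lb, lc))
    for k, l in zip((a, b, c), (la, lb, lc)):
        nodes[k].length = l
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]], node_id=next_id)


@dataclass
class SupportedTree:
    tree: TreeNode
    n_replicates: int

    def to_newick(self) -> str:
        return self.tree.to_newick(with_support=True)


def bootstrap_support(
    alignment: MultipleAlignment,
    n_reps: int,
    seed: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> SupportedTree:
    """NJ/LogDet tree of the full alignment with column-resampling bootstrap
    support mapped onto its internal edges."""
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if alignment.n_columns < 1:
        raise ValueError("alignment has no columns to resample")
    if len(alignment.ids) < 3:
        raise ValueError("tree building requires at least 3 rows")

    full_tree = nj_tree(logdet_matrix(alignment, pseudocount))
    target = bipartitions(full_tree)
    counts = {bp: 0 for bp in target}

    rng = np.random.default_rng(seed)
    enc = alignment.encoded()
    n_cols = alignment.n_columns
    decode = np.array(list("ACGT-"))
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_rows = ["".join(decode[enc[i, cols] % 5]) for i in range(len(enc))]
        rep_aln = MultipleAlignment(list(alignment.ids), rep_rows)
        try:
            rep_tree = nj_tree(logdet_matrix(rep_aln, pseudocount))
        except ValueError:
            continue  # replicate unusable (e.g. a pair with no usable sites)
        rep_parts = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_parts:
                counts[bp] += 1

    def annotate(node: TreeNode) -> None:
        all_leaves = full_tree.leaf_names()
        ref = min(all_leaves)
        for child in node.children:
            if not child.is_leaf:
                below = child.leaf_names()
                side = all_leaves - below if ref in below else below
                if side in counts:
                    child.support = 100.0 * counts[side] / n_reps
                annotate(child)

    annotate(full_tree)
    return SupportedTree(tree=full_tree, n_replicates=n_reps)
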