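"""V-REGION distances, neighbor-joining trees and bootstrap support.

Distances come from aligned nucleotide sets under the p-distance or the
Jukes-Cantor (JC69) correction with pairwise gap deletion. Trees are built
with the Saitou-Nei neighbor-joining agglomeration using the standard
Q-criterion; ties break on the lowest taxon-index pair and negative branch
length estimates are clamped to zero (and flagged), so the construction is
fully deterministic. Support values are the percentage of bootstrap
replicates (column resampling with replacement) containing each internal
bipartition of the full-data tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import TRKitError

_VALID = set("ACGT")


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise TRKitError("distance matrix shape does not match label count")
        if not np.allclose(m, m.T, atol=1e-9):
            raise TRKitError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-9):
            raise TRKitError("distance matrix diagonal must be zero")
        if (m < -1e-12).any():
            raise TRKitError("distances must be nonnegative")
        self.matrix = m


def v_region_distances(records: list[tuple[str, str]], model: str = "p") -> DistanceMatrix:
    """Pairwise distances over an aligned nucleotide set.

    Sites where either sequence has a gap or ambiguity are deleted pairwise.
    ``p`` is the raw mismatch proportion; ``JC69`` applies
    -(3/4) ln(1 - 4p/3) and rejects saturated pairs (p >= 0.75).
    """
    if model not in ("p", "JC69"):
        raise TRKitError(f"unknown distance model {model!r}")
    labels = [name for name, _ in records]
    seqs = [s.upper() for _, s in records]
    if len(set(len(s) for s in seqs)) > 1:
        raise TRKitError("aligned sequences must have equal length")
    n = len(seqs)
    arr = np.array([[c for c in s] for s in seqs])
    valid = np.isin(arr, list(_VALID))
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            sites = int(both.sum())
            if sites == 0:
                raise TRKitError(f"no comparable sites between {labels[i]!r} and {labels[j]!r}")
            p = float((arr[i][both] != arr[j][both]).sum()) / sites
            if model == "JC69":
                if p >= 0.75:
                    raise TRKitError(
                        f"JC69 undefined for {labels[i]!r} vs {labels[j]!r}: p = {p:.3f} >= 0.75"
                    )
                d = -0.75 * np.log(1 - 4 * p / 3)
            else:
                d = p
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class Node:
    name: str | None = None          # taxon name for leaves
    children: list = field(default_factory=list)  # (Node, branch_length)
    support: float | None = None     # bootstrap %, internal nodes only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    root: Node                       # trifurcating root of the unrooted tree
    taxa: list[str]
    clamped: int = 0                 # number of negative branch estimates set to 0

    def to_newick(self) -> str:
        def fmt(node: Node, length: float | None) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, ln) for c, ln in node.children)
                label = "" if node.support is None else f"{node.support:g}"
                body = f"({inner}){label}"
            return body if length is None else f"{body}:{length:.6f}"

        return fmt(self.root, None) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, canonicalized to the side not containing the
        lexicographically smallest taxon."""
        ref = min(self.taxa)
        full = set(self.taxa)
        out = set()

        def walk(node: Node) -> None:
            for child, _ in node.children:
                if not child.is_leaf:
                    side = set(child.leaves())
                    if ref in side:
                        side = full - side
                    if 1 < len(side) < len(full) - 1:
                        out.add(frozenset(side))
                    walk(child)

        walk(self.root)
        return out

    def _internal_nodes_with_splits(self) -> list[tuple[Node, frozenset]]:
        ref = min(self.taxa)
        full = set(self.taxa)
        out = []

        def walk(node: Node) -> None:
            for child, _ in node.children:
                if not child.is_leaf:
                    side = set(child.leaves())
                    if ref in side:
                        side = full - side
                    if 1 < len(side) < len(full) - 1:
                        out.append((child, frozenset(side)))
                    walk(child)

        walk(self.root)
        return out


def nj(dist: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; deterministic given the tie rule
    (lowest (i, j) index pair among minimal Q entries)."""
    n = len(dist.labels)
    if n < 3:
        raise TRKitError("neighbor joining requires at least 3 taxa")
    d = dist.matrix.copy()
    nodes = [Node(name=label) for label in dist.labels]
    active = list(range(n))
    clamped = 0

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest flat index among minimal entries -> lowest (i, j) pair
        flat = int(np.flatnonzero(np.isclose(q, q.min()))[0])
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, clamped = 0.0, clamped + 1
        if lj < 0:
            lj, clamped = 0.0, clamped + 1
        new = Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to every other active node
        dk = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = dk
        d[:-1, -1] = dk
        d[-1, -1] = 0.0
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    lengths = []
    for val in (la, lb, lc):
        if val < 0:
            clamped += 1
            val = 0.0
        lengths.append(val)
    root = Node(children=[(nodes[a], lengths[0]), (nodes[b], lengths[1]), (nodes[c], lengths[2])])
    return PhyloTree(root=root, taxa=list(dist.labels), clamped=clamped)


def bootstrap_support(
    records: list[tuple[str, str]],
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "p",
) -> PhyloTree:
    """NJ tree of the full alignment with bootstrap support on internal edges.

    Columns are resampled with replacement ``n_reps`` times; each internal
    bipartition's support is the percentage of replicate trees containing
    it. Deterministic per seed.
    """
    if n_reps < 1:
        raise TRKitError("n_reps must be >= 1")
    tree = nj(v_region_distances(records, model))
    names = [name for name, _ in records]
    arr = np.array([[c for c in s.upper()] for _, s in records])
    ncols = arr.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, ncols)
        sample = ["".join(row) for row in arr[:, cols]]
        try:
            rep = nj(v_region_distances(list(zip(names, sample)), model))
        except TRKitError:
            continue  # e.g. a saturated JC69 pair in this replicate
        for split in rep.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    for node, split in tree._internal_nodes_with_splits():
        node.support = 100.0 * counts.get(split, 0) / n_reps
    return tree


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
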