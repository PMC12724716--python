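"""Hierarchical clustering and two-dendrogram comparison.

The question asked here: do haplotypes with similar mitochondrial sequences
show similar trait profiles?  Both sides are clustered hierarchically --
haplotype-level trait matrices with euclidean distance on z-scored columns,
founder sequences with p-distances from the alignment -- and the two trees
are compared by (i) the entanglement score of their leaf orders after
rotation-based untangling, 0 meaning perfectly concordant orders, and (ii)
the cophenetic correlation coefficient (CPCC), the Pearson correlation of
the two trees' cophenetic distance vectors.

The agglomeration is written with an explicit deterministic tie-break
(equal-distance merges pick the pair whose clusters contain the
lexicographically smallest item labels) so that repeated runs and platform
changes give identical trees; it is validated against
``scipy.cluster.hierarchy`` in the test-suite.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats


class DendroError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Sequence distances


GAP_CHARS = {"-", "."}


def sequence_distance(sequences: Mapping[str, str]) -> pd.DataFrame:
    """Pairwise p-distance matrix from aligned sequences.

    p-distance = mismatches / compared sites, where any position carrying a
    gap character in either sequence is excluded from both numerator and
    denominator.  All sequences must have equal (aligned) length.
    """
    labels = list(sequences)
    if len(labels) < 2:
        raise DendroError("need at least two sequences")
    arrs = {k: np.frombuffer(str(v).upper().encode(), dtype="S1") for k, v in sequences.items()}
    lengths = {len(a) for a in arrs.values()}
    if len(lengths) != 1:
        raise DendroError(f"unequal sequence lengths: {sorted(lengths)}")
    gap = {k: np.isin(a, [b"-", b"."]) for k, a in arrs.items()}
    D = np.zeros((len(labels), len(labels)))
    for i, j in itertools.combinations(range(len(labels)), 2):
        a, b = arrs[labels[i]], arrs[labels[j]]
        mask = ~(gap[labels[i]] | gap[labels[j]])
        comp = int(mask.sum())
        if comp == 0:
            raise DendroError(
                f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
            )
        d = float(np.sum((a != b) & mask)) / comp
        D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Agglomerative clustering


@dataclass
class Dendrogram:
    """Binary merge tree in scipy linkage format plus leaf labels."""

    labels: list[str]
    Z: np.ndarray  # (n-1, 4): child a, child b, height, cluster size

    def __post_init__(self):
        n = len(self.labels)
        if self.Z.shape != (n - 1, 4):
            raise DendroError(f"linkage shape {self.Z.shape} does not match {n} leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf labels as drawn."""
        n = self.n_leaves
        order: list[str] = []

        def walk(node: int):
            if node < n:
                order.append(self.labels[node])
            else:
                a, b = int(self.Z[node - n, 0]), int(self.Z[node - n, 1])
                walk(a)
                walk(b)

        walk(2 * n - 2)
        return order

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Entry (i, j) = height of the lowest merge containing both leaves."""
        n = self.n_leaves
        C = np.zeros((n, n))
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for t in range(n - 1):
            a, b, h = int(self.Z[t, 0]), int(self.Z[t, 1]), self.Z[t, 2]
            A, B = members.pop(a), members.pop(b)
            for i in A:
                C[i, B] = h
            for j in B:
                C[j, A] = h
            members[n + t] = A + B
        return pd.DataFrame(C, index=self.labels, columns=self.labels)

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences."""
        n = self.n_leaves

        def node_str(node: int, parent_h: float) -> str:
            if node < n:
                return f"{self.labels[node]}:{parent_h:.10g}"
            a, b, h = int(self.Z[node - n, 0]), int(self.Z[node - n, 1]), self.Z[node - n, 2]
            return f"({node_str(a, h)},{node_str(b, h)}):{parent_h - h:.10g}"

        root = 2 * n - 2
        h = self.Z[-1, 2]
        a, b = int(self.Z[-1, 0]), int(self.Z[-1, 1])
        return f"({node_str(a, h)},{node_str(b, h)});"


_LINKAGES = ("average", "complete", "ward")


def hcluster(
    data,
    metric: str = "euclidean",
    method: str = "average",
    labels: Sequence[str] | None = None,
) -> Dendrogram:
    """Agglomerative clustering with deterministic tie-breaking.

    ``data`` is either an items x features matrix (``metric='euclidean'``)
    or a precomputed square distance matrix (``metric='precomputed'``).
    Linkage is one of average (UPGMA), complete, or ward (Lance-Williams on
    squared euclidean distances).  Equal-distance merges pick the pair of
    clusters containing the lexicographically smallest item labels, so the
    tree is invariant to item input order.
    """
    if method not in _LINKAGES:
        raise DendroError(f"unknown linkage {method!r}; choose from {_LINKAGES}")
    if isinstance(data, pd.DataFrame):
        if labels is None:
            labels = list(data.index)
        data = data.to_numpy(dtype=float)
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = [f"item{i}" for i in range(data.shape[0])]
    labels = list(labels)
    if np.isnan(data).any():
        raise DendroError("missing values in input; impute before clustering")
    if metric == "precomputed":
        D = np.asarray(data, dtype=float)
        if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
            raise DendroError("precomputed distance matrix must be square symmetric")
    elif metric == "euclidean":
        D = squareform(pdist(data, metric="euclidean"))
    else:
        raise DendroError(f"unknown metric {metric!r}")
    n = D.shape[0]
    if n < 2:
        raise DendroError("need at least two items")
    if len(labels) != n:
        raise DendroError("labels length does not match data")

    # sort items by label so the tie-break is on label order, then map back
    order = sorted(range(n), key=lambda i: labels[i])
    inv = {o: i for i, o in enumerate(order)}

    sq = method == "ward"
    total = 2 * n - 1
    M = np.full((total, total), np.inf)
    Dw = D[np.ix_(order, order)].astype(float)
    M[:n, :n] = Dw**2 if sq else Dw
    np.fill_diagonal(M, np.inf)
    size = np.ones(total)
    minlab = [labels[o] for o in order] + [""] * (n - 1)
    active = list(range(n))
    Z = np.zeros((n - 1, 4))
    for t in range(n - 1):
        best = None
        for ia in range(len(active)):
            for ib in range(ia + 1, len(active)):
                a, b = active[ia], active[ib]
                d = M[a, b]
                key = (d, *sorted((minlab[a], minlab[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        d = M[a, b]
        new = n + t
        h = float(np.sqrt(d)) if sq else float(d)
        Z[t] = [min(a, b), max(a, b), h, size[a] + size[b]]
        sa, sb = size[a], size[b]
        for c in active:
            if c in (a, b):
                continue
            if method == "average":
                M[new, c] = M[c, new] = (sa * M[a, c] + sb * M[b, c]) / (sa + sb)
            elif method == "complete":
                M[new, c] = M[c, new] = max(M[a, c], M[b, c])
            else:  # ward, in squared space
                sc = size[c]
                M[new, c] = M[c, new] = (
                    (sc + sa) * M[a, c] + (sc + sb) * M[b, c] - sc * d
                ) / (sa + sb + sc)
        size[new] = sa + sb
        minlab[new] = min(minlab[a], minlab[b])
        active.remove(a)
        active.remove(b)
        active.append(new)

    return Dendrogram(labels=[labels[o] for o in order], Z=Z)


# ---------------------------------------------------------------------------
# Tree comparison


def cpcc(d1: Dendrogram, d2: Dendrogram) -> float:
    """Pearson correlation between two trees' cophenetic distance vectors.

    Tree-vs-tree CPCC: both trees must share the same leaf label set; the
    lower-triangle vectors are paired in identical label order.  Returns
    NaN (with a warning) when either vector has zero variance.
    """
    if set(d1.labels) != set(d2.labels):
        raise DendroError("cpcc: leaf label sets differ")
    if d1.n_leaves < 3:
        raise DendroError("cpcc: need at least 3 leaves")
    labs = sorted(d1.labels)
    C1 = d1.cophenetic_matrix().loc[labs, labs].to_numpy()
    C2 = d2.cophenetic_matrix().loc[labs, labs].to_numpy()
    iu = np.triu_indices(len(labs), k=1)
    v1, v2 = C1[iu], C2[iu]
    if np.std(v1) == 0 or np.std(v2) == 0:
        warnings.warn("cpcc: zero variance in cophenetic distances; undefined")
        return float("nan")
    return float(stats.pearsonr(v1, v2)[0])


def cpcc_data(d: Dendrogram, distances: pd.DataFrame) -> float:
    """Classical CPCC: correlation of tree cophenetic vs original distances."""
    labs = sorted(d.labels)
    C = d.cophenetic_matrix().loc[labs, labs].to_numpy()
    D = distances.loc[labs, labs].to_numpy()
    iu = np.triu_indices(len(labs), k=1)
    if np.std(C[iu]) == 0 or np.std(D[iu]) == 0:
        warnings.warn("cpcc_data: zero variance; undefined")
        return float("nan")
    return float(stats.pearsonr(C[iu], D[iu])[0])


def entanglement(
    order1: Sequence[str], order2: Sequence[str], L: float = 1.5
) -> float:
    """Normalised leaf-order discordance between two dendrograms.

    With u_i, v_i the ranks of label i in the two orders, the score is
    sum |u_i - v_i|^L divided by the worst case (identity vs full
    reversal): 0 for identical orders, 1 for exact reversal.
    """
    if set(order1) != set(order2):
        raise DendroError("entanglement: label sets differ")
    if len(set(order1)) != len(order1):
        raise DendroError("entanglement: duplicate labels")
    n = len(order1)
    if n <= 1:
        return 0.0
    r2 = {lab: i + 1 for i, lab in enumerate(order2)}
    u = np.arange(1, n + 1, dtype=float)
    v = np.array([r2[lab] for lab in order1], dtype=float)
    num = np.sum(np.abs(u - v) ** L)
    r = np.arange(1, n + 1, dtype=float)
    denom = np.sum(np.abs(r - (n + 1 - r)) ** L)
    if denom == 0:
        return 0.0
    return float(num / denom)


class _Node:
    __slots__ = ("left", "right", "label", "height")

    def __init__(self, label=None, left=None, right=None, height=0.0):
        self.label = label
        self.left = left
        self.right = right
        self.height = height

    @property
    def is_leaf(self):
        return self.label is not None


def _to_tree(d: Dendrogram) -> _Node:
    n = d.n_leaves
    nodes = {i: _Node(label=d.labels[i]) for i in range(n)}
    for t in range(n - 1):
        a, b, h = int(d.Z[t, 0]), int(d.Z[t, 1]), float(d.Z[t, 2])
        nodes[n + t] = _Node(left=nodes[a], right=nodes[b], height=h)
    return nodes[2 * n - 2]


def _tree_order(node: _Node, out: list[str]) -> list[str]:
    if node.is_leaf:
        out.append(node.label)
    else:
        _tree_order(node.left, out)
        _tree_order(node.right, out)
    return out


def _all_orders(node: _Node) -> list[list[str]]:
    if node.is_leaf:
        return [[node.label]]
    lefts = _all_orders(node.left)
    rights = _all_orders(node.right)
    out = []
    for l in lefts:
        for r in rights:
            out.append(l + r)
            out.append(r + l)
    return out


def _subtree_size(node: _Node) -> int:
    return 1 if node.is_leaf else _subtree_size(node.left) + _subtree_size(node.right)


def _order_against(root: _Node, target_ranks: dict, L: float) -> float:
    """Rotate ``root``'s internal nodes to minimise sum |pos - target|^L.

    Exact one-sided optimum by dynamic programming: a subtree placed at a
    given start position chooses the cheaper of its two child orders;
    ties keep the current orientation so the procedure is deterministic.
    Mutates the tree in place and returns the optimal cost.
    """
    memo: dict[tuple[int, int], tuple[float, bool]] = {}

    def cost(node: _Node, start: int) -> float:
        if node.is_leaf:
            return abs((start + 1) - target_ranks[node.label]) ** L
        key = (id(node), start)
        if key in memo:
            return memo[key][0]
        nl = _subtree_size(node.left)
        nr = _subtree_size(node.right)
        keep = cost(node.left, start) + cost(node.right, start + nl)
        flip = cost(node.right, start) + cost(node.left, start + nr)
        best = (keep, False) if keep <= flip else (flip, True)
        memo[key] = best
        return best[0]

    def apply(node: _Node, start: int) -> None:
        if node.is_leaf:
            return
        if memo[(id(node), start)][1]:
            node.left, node.right = node.right, node.left
        nl = _subtree_size(node.left)
        apply(node.left, start)
        apply(node.right, start + nl)

    total = cost(root, 0)
    apply(root, 0)
    return total


@dataclass
class TanglegramStats:
    """Result of a two-dendrogram comparison."""

    entanglement: float
    cpcc: float
    order1: tuple[str, ...]
    order2: tuple[str, ...]
    exhaustive_entanglement: float | None = None
    metadata: dict = field(default_factory=dict)


EXHAUSTIVE_MAX_LEAVES = 8


def untangle(
    d1: Dendrogram, d2: Dendrogram, L: float = 1.5
) -> TanglegramStats:
    """Rotate subtrees to minimise entanglement, then report stats.

    Greedy alternating search: sweep the internal nodes of each tree (top
    down), flipping a node's children whenever that strictly lowers the
    entanglement, until a full sweep changes nothing.  For trees with at
    most 8 leaves an exhaustive search over all rotation combinations is
    run as well and reported in ``exhaustive_entanglement``.  The sweep is
    deterministic: no randomness is involved.
    """
    if set(d1.labels) != set(d2.labels):
        raise DendroError("untangle: leaf label sets differ")
    t1, t2 = _to_tree(d1), _to_tree(d2)

    def current() -> float:
        return entanglement(_tree_order(t1, []), _tree_order(t2, []), L)

    e = current()
    improved = True
    sweeps = 0
    while improved and sweeps < 50:
        improved = False
        sweeps += 1
        for tree, other in ((t2, t1), (t1, t2)):
            target = {lab: i + 1 for i, lab in enumerate(_tree_order(other, []))}
            _order_against(tree, target, L)
            e_new = current()
            if e_new < e - 1e-15:
                e = e_new
                improved = True

    order1 = tuple(_tree_order(t1, []))
    order2 = tuple(_tree_order(t2, []))
    exhaustive = None
    n = d1.n_leaves
    if n <= EXHAUSTIVE_MAX_LEAVES:
        labs = sorted(d1.labels)
        pos = {lab: i for i, lab in enumerate(labs)}
        orders1 = _all_orders(_to_tree(d1))
        orders2 = _all_orders(_to_tree(d2))
        O1 = np.array([[pos[l] for l in o] for o in orders1])
        O2 = np.array([[pos[l] for l in o] for o in orders2])
        # rank of each label within each order
        R1 = np.empty_like(O1)
        R2 = np.empty_like(O2)
        ar = np.arange(1, n + 1)
        rows1 = np.arange(O1.shape[0])[:, None]
        rows2 = np.arange(O2.shape[0])[:, None]
        R1[rows1, O1] = ar
        R2[rows2, O2] = ar
        r = np.arange(1, n + 1, dtype=float)
        denom = np.sum(np.abs(r - (n + 1 - r)) ** L)
        diffs = np.abs(R1[:, None, :] - R2[None, :, :]).astype(float) ** L
        ent = diffs.sum(axis=2) / denom if denom else np.zeros(diffs.shape[:2])
        exhaustive = float(ent.min())
        if exhaustive < e - 1e-15:
            # small trees get the exact optimum (first-index tie-break)
            i, j = np.unravel_index(int(ent.argmin()), ent.shape)
            e = exhaustive
            order1 = tuple(orders1[i])
            order2 = tuple(orders2[j])

    return TanglegramStats(
        entanglement=e,
        cpcc=cpcc(d1, d2) if d1.n_leaves >= 3 else float("nan"),
        order1=order1,
        order2=order2,
        exhaustive_entanglement=exhaustive,
        metadata={"L": L, "alternating_rounds": sweeps},
    )


def compare_trait_sequence_trees(
    trait_matrix: pd.DataFrame,
    sequence_distances: pd.DataFrame,
    method: str = "average",
    L: float = 1.5,
) -> TanglegramStats:
    """Cluster a haplotype x trait matrix and a founder distance matrix,
    untangle the two trees, and report entanglement and CPCC.

    Trait columns are z-scored (sample SD) before euclidean distances;
    constant columns are dropped with a warning.  Labels shared by both
    inputs (>= 3 required) are used.
    """
    shared = [l for l in trait_matrix.index if l in sequence_distances.index]
    if len(shared) < 3:
        raise DendroError(f"only {len(shared)} shared labels; need >= 3")
    tm = trait_matrix.loc[shared]
    sd = tm.std(ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping constant traits: {list(tm.columns[~keep])}")
    if not keep.any():
        raise DendroError("all traits constant across haplotypes")
    z = (tm.loc[:, keep] - tm.loc[:, keep].mean()) / sd[keep]
    d_traits = hcluster(z, metric="euclidean", method=method)
    d_seq = hcluster(
        sequence_distances.loc[shared, shared], metric="precomputed", method=method
    )
    out = untangle(d_traits, d_seq, L=L)
    out.metadata.update({"linkage": method, "trait_metric": "euclidean"})
    return out
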