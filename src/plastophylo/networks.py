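"""Distance-based split networks and supernetworks.

``neighbor_net`` implements the canonical agglomerative Neighbour-Net
construction: neighbour-joining-style cluster selection with endpoint
refinement produces a circular ordering of the taxa; every interval of that
ordering is a candidate split, whose weights are estimated by nonnegative
least squares against the observed distances; near-zero splits are dropped
and an optional dimension filter bounds the mutual incompatibility of the
retained splits.  On a tree metric the output is exactly the tree's split
system.

``zclosure_supernetwork`` summarizes trees on partially overlapping taxon
sets: every branch contributes a partial split, pairs of partial splits are
repeatedly extended by the Z-closure rule over several randomized
processing orders, and the completed full splits form the supernetwork.
Conflicting signal shows up as incompatible splits (boxes).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.optimize import nnls

from plastophylo.io import Alignment, UNAMBIGUOUS
from plastophylo.splits import Split, SplitSystem, splits_compatible, splits_from_tree

__all__ = [
    "DistanceMatrix",
    "FitReport",
    "p_distance_matrix",
    "neighbor_net",
    "fit_statistics",
    "zclosure_supernetwork",
]

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    taxa: tuple
    d: np.ndarray

    def __post_init__(self):
        self.taxa = tuple(self.taxa)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(self.d < 0):
            raise ValueError("negative distances")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")


@dataclass
class FitReport:
    """Percent agreement between observed and split-induced distances.

    fit   = 100 * (1 - sum|d_ij - p_ij| / sum d_ij)        (L1 form)
    LSfit = 100 * (1 - sum (d_ij - p_ij)^2 / sum d_ij^2)   (squared form)

    with p_ij the sum of weights of splits separating i and j, both sums
    over unordered pairs.  Undefined (None) for an all-zero matrix.
    """

    fit: float | None
    lsfit: float | None
    induced: np.ndarray
    defined: bool = True


def p_distance_matrix(aln: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Uncorrected p-distances between all row pairs.

    Pairwise deletion compares, for each pair, only the columns where both
    rows carry unambiguous residues; complete deletion restricts every pair
    to the columns unambiguous in all rows.
    """
    m = np.array([list(r) for r in aln.rows], dtype="U1")
    ok = np.isin(m, list(UNAMBIGUOUS))
    if deletion == "complete":
        keep = ok.all(axis=0)
        m, ok = m[:, keep], ok[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion rule {deletion!r}")
    n = len(aln)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        both = ok[i] & ok[j]
        compared = int(both.sum())
        if compared == 0:
            raise ValueError(
                f"no comparable sites between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
            )
        d[i, j] = d[j, i] = (m[i, both] != m[j, both]).sum() / compared
    return DistanceMatrix(tuple(aln.taxa), d)


# ---------------------------------------------------------------------------
# Neighbour-Net


def _reduce_nodes(d: np.ndarray, x: int, y: int, z: int) -> None:
    """Replace the 3-node path x-y-z by two nodes stored at x and z."""
    u = (2.0 * d[x] + d[y]) / 3.0
    v = (2.0 * d[z] + d[y]) / 3.0
    uv = (d[x, y] + d[x, z] + d[y, z]) / 3.0
    d[x, :] = u
    d[:, x] = u
    d[z, :] = v
    d[:, z] = v
    d[y, :] = 0.0
    d[:, y] = 0.0
    d[x, z] = d[z, x] = uv
    d[x, x] = d[z, z] = 0.0


def _cluster_mean(d, a, b) -> float:
    return float(d[np.ix_(a, b)].mean())


def neighbor_net_ordering(dm: DistanceMatrix) -> tuple:
    """Circular taxon ordering by Neighbour-Net agglomeration.

    Clusters are paths of taxa; only the two endpoint nodes of each path
    stay active.  Cluster pairs are chosen by the neighbour-joining
    criterion on cluster-averaged distances, the joined endpoints by the
    same criterion over the candidate endpoint nodes, and each 3-node path
    produced by a join is reduced to 2 nodes with the standard (2/3, 1/3)
    reduction.  Ties break towards the smallest index.
    """
    n = len(dm.taxa)
    d = dm.d.copy()
    CL = [[i] for i in range(n)]     # active endpoint nodes per cluster
    order = [[i] for i in range(n)]  # full taxon path per cluster
    DM = d.copy()                    # cluster-level averaged distances
    new_ord = list(range(n))
    while len(CL) > 1:
        l = len(DM)
        if l > 2:
            r = DM.sum(axis=1) / (l - 2)
            Q = DM - r[:, None] - r[None, :]
            np.fill_diagonal(Q, np.inf)
            e1, e2 = np.unravel_index(int(np.argmin(Q)), Q.shape)
            if e1 > e2:
                e1, e2 = e2, e1
        else:
            e1, e2 = 0, 1
        n1, n2 = len(CL[e1]), len(CL[e2])
        if n1 == 1 and n2 == 1:
            new_cl = CL[e1] + CL[e2]
            new_ord = order[e1] + order[e2]
        else:
            nodes = CL[e1] + CL[e2]
            others = [CL[i] for i in range(len(CL)) if i not in (e1, e2)]
            ltmp = len(nodes) + len(others)
            rt = np.zeros(len(nodes))
            for a, xi in enumerate(nodes):
                s = sum(d[xi, xj] for b, xj in enumerate(nodes) if b != a)
                s += sum(float(d[xi, c].mean()) for c in others)
                rt[a] = s
            if ltmp > 2:
                rt = rt / (ltmp - 2)
            sub = d[np.ix_(nodes, nodes)] - (rt[:, None] + rt[None, :])
            tmp2 = sub[:n1, n1:]
            blub = int(np.argmin(tmp2.flatten(order="F")))
            row, col = blub % n1, blub // n1
            o1, o2 = order[e1], order[e2]
            if n1 == 2 and n2 == 1:
                x1, x2 = CL[e1]
                (y,) = CL[e2]
                if row == 1:  # join x2-y
                    new_cl, new_ord = [x1, y], o1 + o2
                    _reduce_nodes(d, x1, x2, y)
                else:         # join x1-y
                    new_cl, new_ord = [y, x2], o2 + o1
                    _reduce_nodes(d, y, x1, x2)
            elif n1 == 1 and n2 == 2:
                (x,) = CL[e1]
                y1, y2 = CL[e2]
                if col == 0:  # join x-y1
                    new_cl, new_ord = [x, y2], o1 + o2
                    _reduce_nodes(d, x, y1, y2)
                else:         # join x-y2
                    new_cl, new_ord = [y1, x], o2 + o1
                    _reduce_nodes(d, y1, y2, x)
            else:
                x1, x2 = CL[e1]
                y1, y2 = CL[e2]
                if row == 0 and col == 0:    # x1-y1
                    new_cl, new_ord = [x2, y2], o1[::-1] + o2
                    _reduce_nodes(d, x2, x1, y1)
                    _reduce_nodes(d, x2, y1, y2)
                elif row == 1 and col == 0:  # x2-y1
                    new_cl, new_ord = [x1, y2], o1 + o2
                    _reduce_nodes(d, x1, x2, y1)
                    _reduce_nodes(d, x1, y1, y2)
                elif row == 0 and col == 1:  # x1-y2
                    new_cl, new_ord = [x2, y1], o1[::-1] + o2[::-1]
                    _reduce_nodes(d, x2, x1, y2)
                    _reduce_nodes(d, x2, y2, y1)
                else:                        # x2-y2
                    new_cl, new_ord = [x1, y1], o1 + o2[::-1]
                    _reduce_nodes(d, x1, x2, y2)
                    _reduce_nodes(d, x1, y2, y1)
        order[e1] = new_ord
        CL[e1] = new_cl
        for i in range(len(CL)):
            DM[i, e1] = DM[e1, i] = _cluster_mean(d, CL[i], CL[e1])
        DM[e1, e1] = 0.0
        DM = np.delete(np.delete(DM, e2, axis=0), e2, axis=1)
        del CL[e2], order[e2]
    return tuple(dm.taxa[i] for i in new_ord)


def circular_candidate_splits(order: tuple) -> list:
    """All n(n-1)/2 splits whose sides are intervals of the ordering."""
    n = len(order)
    out = []
    for i in range(1, n):
        for j in range(i, n):
            out.append(frozenset(order[i : j + 1]))
    return out


def estimate_split_weights(dm: DistanceMatrix, sides: list) -> np.ndarray:
    """Nonnegative least-squares split weights on the pair-separation
    design matrix (active-set NNLS)."""
    idx = {t: i for i, t in enumerate(dm.taxa)}
    pairs = list(combinations(range(len(dm.taxa)), 2))
    A = np.zeros((len(pairs), len(sides)))
    for s_col, side in enumerate(sides):
        members = {idx[t] for t in side}
        for p_row, (i, j) in enumerate(pairs):
            if (i in members) != (j in members):
                A[p_row, s_col] = 1.0
    b = np.array([dm.d[i, j] for i, j in pairs])
    w, _ = nnls(A, b)
    return w


def filter_dimension(system: SplitSystem, max_dim: int = 4) -> SplitSystem:
    """Greedy dimension filter: remove lowest-weight splits until no
    (max_dim+1) splits are mutually incompatible."""
    splits = list(system.splits)
    while True:
        nontrivial = [s for s in splits if not s.is_trivial(len(system.taxa))]
        G = nx.Graph()
        G.add_nodes_from(range(len(nontrivial)))
        for a, b in combinations(range(len(nontrivial)), 2):
            if not splits_compatible(nontrivial[a].side, nontrivial[b].side,
                                     system.taxa):
                G.add_edge(a, b)
        offending = set()
        for clique in nx.find_cliques(G):
            if len(clique) > max_dim:
                offending.update(clique)
        if not offending:
            break
        worst = min(offending, key=lambda i: nontrivial[i].weight)
        splits.remove(nontrivial[worst])
    return SplitSystem(system.taxa, splits, circular_order=system.circular_order)


def neighbor_net(dm: DistanceMatrix, weight_tol: float = 1e-6,
                 max_dim: int | None = 4) -> SplitSystem:
    """Neighbour-Net circular split system with least-squares weights.

    Splits with weight <= ``weight_tol`` times the mean estimated weight
    are dropped; ``max_dim`` bounds mutual incompatibility (None disables
    the filter).
    """
    if len(dm.taxa) < 4:
        raise ValueError("Neighbour-Net needs at least 4 taxa")
    order = neighbor_net_ordering(dm)
    sides = circular_candidate_splits(order)
    w = estimate_split_weights(dm, sides)
    eps = weight_tol * float(w.mean()) if w.mean() > 0 else 0.0
    splits = [Split(side, float(wt)) for side, wt in zip(sides, w) if wt > eps]
    system = SplitSystem(tuple(dm.taxa), splits, circular_order=order)
    if max_dim is not None:
        system = filter_dimension(system, max_dim)
    return system


def fit_statistics(dm: DistanceMatrix, system: SplitSystem) -> FitReport:
    """L1 (fit) and squared (LSfit) percent agreement between the observed
    distances and the distances induced by the split system."""
    if tuple(system.taxa) != tuple(dm.taxa):
        # allow same taxon set in different order
        if set(system.taxa) != set(dm.taxa):
            raise ValueError("taxon sets differ")
        perm = [system.taxa.index(t) for t in dm.taxa]
        induced_full = system.induced_distances()
        induced = induced_full[np.ix_(perm, perm)]
    else:
        induced = system.induced_distances()
    iu = np.triu_indices(len(dm.taxa), k=1)
    dvec, pvec = dm.d[iu], induced[iu]
    sd, sd2 = float(np.abs(dvec).sum()), float((dvec ** 2).sum())
    if sd == 0:
        log.warning("all-zero distance matrix: fit statistics undefined")
        return FitReport(None, None, induced, defined=False)
    fit = 100.0 * (1.0 - float(np.abs(dvec - pvec).sum()) / sd)
    lsfit = 100.0 * (1.0 - float(((dvec - pvec) ** 2).sum()) / sd2)
    return FitReport(fit, lsfit, induced)


# ---------------------------------------------------------------------------
# Z-closure supernetwork


def _apply_z_rule(s1: list, s2: list) -> bool:
    """Try the Z-closure extension on an ordered pair of partial splits.

    With S1 = A1|B1 and S2 = A2|B2: if A1 meets A2, B1 meets B2 and A1 is
    disjoint from B2, replace S1 by A1|B1∪B2 and S2 by A1∪A2|B2.  Returns
    True when either split grew.  Full splits are fixed points.
    """
    changed = False
    for a2_i, b2_i in ((0, 1), (1, 0)):
        A1, B1 = s1
        A2, B2 = s2[a2_i], s2[b2_i]
        if (A1 & A2) and (B1 & B2) and not (A1 & B2):
            if not B2 <= B1:
                B1 |= B2
                changed = True
            if not A1 <= A2:
                A2 |= A1
                changed = True
    return changed


def zclosure_supernetwork(trees: list, orderings: int = 10,
                          seed: int | None = None) -> SplitSystem:
    """Z-closure supernetwork from trees on overlapping taxon subsets.

    Every branch of every input tree contributes a partial split on that
    tree's taxa with the branch length as weight (1 when absent).  The
    Z-closure rule is applied to pairs of partial splits until no rule
    fires, independently for ``orderings`` random pair-processing orders;
    completed full splits are pooled.  A closed partial split with a
    singleton side is completed by assigning the missing taxa to its large
    side.  The weight of a full split is the mean length of the input
    branches that produced it.
    """
    if not trees:
        raise ValueError("need at least one input tree")
    inputs = []  # (sideA, sideB, source_key, weight)
    taxa = set()
    for k, tree in enumerate(trees):
        tree_splits = splits_from_tree(tree)
        leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
        taxa |= leaves
        for side, length in tree_splits.items():
            inputs.append((side, leaves - side, (k, side), length))
    taxa_f = frozenset(taxa)
    # warn when the trees do not connect all taxa through shared leaves
    overlap = nx.Graph()
    overlap.add_nodes_from(range(len(trees)))
    leafsets = [frozenset(lf.taxon.label for lf in t.leaf_node_iter())
                for t in trees]
    for a, b in combinations(range(len(trees)), 2):
        if leafsets[a] & leafsets[b]:
            overlap.add_edge(a, b)
    if len(trees) > 1 and not nx.is_connected(overlap):
        log.warning("input trees do not overlap into one connected set; "
                    "unconnected taxa will carry trivial splits only")
    rng = random.Random(seed)
    pooled = {}  # canonical full side -> {source_key: weight}
    for _ in range(max(1, orderings)):
        splits = [[set(a), set(b)] for a, b, _, _ in inputs]
        pair_order = [(i, j) for i in range(len(splits))
                      for j in range(len(splits)) if i != j]
        changed = True
        while changed:
            changed = False
            rng.shuffle(pair_order)
            for i, j in pair_order:
                if _apply_z_rule(splits[i], splits[j]):
                    changed = True
        for (a, b), (_, _, key, weight) in zip(splits, inputs):
            a, b = frozenset(a), frozenset(b)
            if a | b != taxa_f:
                missing = taxa_f - a - b
                if len(a) == 1:
                    b |= missing
                elif len(b) == 1:
                    a |= missing
                else:
                    continue
            canon = min(a, b, key=lambda s: (len(s), tuple(sorted(s))))
            pooled.setdefault(canon, {})[key] = weight
    out = []
    for side, sources in pooled.items():
        out.append(Split(side, float(np.mean(list(sources.values())))))
    taxa_sorted = tuple(sorted(taxa))
    has_trivial = set()
    for s in out:
        if len(s.side) == 1:
            has_trivial |= s.side
        elif len(s.side) == len(taxa_sorted) - 1:
            has_trivial |= taxa_f - s.side
    for t in taxa_sorted:  # unconnected taxa still get their trivial split
        if t not in has_trivial:
            out.append(Split(frozenset([t]), 1.0))
    return SplitSystem(taxa_sorted, out)
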