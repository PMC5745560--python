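"""Total-evidence maximum parsimony over mixed character matrices.

Characters may be DNA (optionally with the gap as a fifth state), binary,
unordered multistate, or continuous.  Continuous characters are
range-standardized so that the span between the two most dissimilar
observed states costs exactly one step, and are optimized by the Farris
interval method; discrete characters are scored by unit-cost dynamic
programming (equivalent to Fitch optimization on binary trees, exact on
multifurcations too).  Exact searches use branch and bound with a greedy
upper bound; clade support comes from bootstrap or jackknife resampling of
characters; synapomorphies are mapped by computing, per character, the set
of states every node takes across *all* most-parsimonious reconstructions —
a change is non-ambiguous iff both endpoint state sets are singletons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np

__all__ = [
    "CharacterPartition",
    "MixedMatrix",
    "ParsimonyResult",
    "SynapomorphyMap",
    "assemble_mixed_matrix",
    "tree_length",
    "exact_search",
    "resample_support",
    "map_synapomorphies",
    "strict_consensus_splits",
]

log = logging.getLogger(__name__)

_BIG = 1.0e9
_TOL = 1e-9

_DNA_STATES = ("A", "C", "G", "T")
_MISSING = {None, "?", ""}


@dataclass
class CharacterPartition:
    name: str
    ctype: str                  # dna | binary | unordered | continuous
    columns: int
    gap_as_state: bool = True   # dna only
    ranges: list | None = None  # continuous only: per-character (min, max)


@dataclass
class _Column:
    ctype: str
    name: str
    values: list          # per taxon; str|None (discrete) or float|None
    states: tuple = ()    # discrete state vocabulary


class MixedMatrix:
    """Partitioned mixed character matrix over a fixed taxon list."""

    def __init__(self, taxa, partitions, columns):
        self.taxa = list(taxa)
        self.partitions = list(partitions)
        self.columns = list(columns)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if sum(p.columns for p in self.partitions) != len(self.columns):
            raise ValueError("partition widths do not sum to column count")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.columns)

    def subset_columns(self, indices) -> "MixedMatrix":
        cols = [self.columns[i] for i in indices]
        part = CharacterPartition("resampled", "mixed", len(cols))
        return MixedMatrix(self.taxa, [part], cols)

    def subset_taxa(self, keep) -> "MixedMatrix":
        keep_idx = [self.taxa.index(t) for t in keep]
        cols = [
            _Column(c.ctype, c.name, [c.values[i] for i in keep_idx], c.states)
            for c in self.columns
        ]
        return MixedMatrix(list(keep), self.partitions, cols)

    # -- compiled numeric form -------------------------------------------

    def compile(self) -> dict:
        """Numeric arrays for fast scoring.

        Discrete characters become leaf cost tables (n_taxa, n_disc, S):
        zero for allowed states, a large constant otherwise; missing data
        allows every state.  Continuous characters become per-taxon value
        arrays with NaN for missing.
        """
        disc = [c for c in self.columns if c.ctype != "continuous"]
        cont = [c for c in self.columns if c.ctype == "continuous"]
        n = self.n_taxa
        smax = max((len(c.states) for c in disc), default=1)
        leaf = np.full((n, len(disc), smax), _BIG)
        nstates = np.zeros(len(disc), dtype=int)
        for k, c in enumerate(disc):
            nstates[k] = len(c.states)
            lookup = {s: i for i, s in enumerate(c.states)}
            for t in range(n):
                v = c.values[t]
                if v in _MISSING:
                    leaf[t, k, : len(c.states)] = 0.0
                else:
                    leaf[t, k, lookup[v]] = 0.0
        vals = np.full((n, len(cont)), np.nan)
        for k, c in enumerate(cont):
            for t in range(n):
                if c.values[t] is not None:
                    vals[t, k] = c.values[t]
        lo = np.where(np.isnan(vals), -np.inf, vals)
        hi = np.where(np.isnan(vals), np.inf, vals)
        return {
            "leaf_disc": leaf,
            "n_states": nstates,
            "disc_cols": disc,
            "cont_cols": cont,
            "cont_lo": lo,
            "cont_hi": hi,
        }

    # -- per-character step bounds ---------------------------------------

    def char_bounds(self):
        """(min steps, max steps) per character on any tree.

        Discrete: min = observed states - 1; max = steps on a star tree
        = non-missing count minus the modal state count.  Continuous: min =
        observed range; max = sum of absolute deviations from the median.
        """
        mins, maxs = [], []
        for c in self.columns:
            if c.ctype == "continuous":
                obs = [v for v in c.values if v is not None]
                if len(obs) < 2:
                    mins.append(0.0)
                    maxs.append(0.0)
                else:
                    mins.append(max(obs) - min(obs))
                    med = float(np.median(obs))
                    maxs.append(float(sum(abs(v - med) for v in obs)))
            else:
                obs = [v for v in c.values if v not in _MISSING]
                if not obs:
                    mins.append(0.0)
                    maxs.append(0.0)
                else:
                    counts = {}
                    for v in obs:
                        counts[v] = counts.get(v, 0) + 1
                    mins.append(float(len(counts) - 1))
                    maxs.append(float(len(obs) - max(counts.values())))
        return np.array(mins), np.array(maxs)


@dataclass
class ParsimonyResult:
    trees: list            # dendropy Trees, all most parsimonious
    score: float
    ci: float | None       # consistency index; None when score == 0
    ri: float | None       # retention index; None when max == min steps
    n_trees_examined: int = 0

    @property
    def mp_tree(self):
        return self.trees[0]


@dataclass
class SynapomorphyMap:
    """Per-branch character state changes over all MP reconstructions.

    Branches are keyed by the leaf set of the clade below them.  Entries
    are (character name, from_state, to_state, ambiguous); non-ambiguous
    entries occur with the same states in every most-parsimonious
    reconstruction of that character.
    """

    entries: list = field(default_factory=list)  # (clade, char, frm, to, ambiguous)

    def unambiguous(self) -> list:
        return [e for e in self.entries if not e[4]]

    def by_branch(self) -> dict:
        out = {}
        for clade, char, frm, to, amb in self.entries:
            out.setdefault(clade, []).append((char, frm, to, amb))
        return out


# ---------------------------------------------------------------------------
# matrix assembly


def assemble_mixed_matrix(parts, dummy_outgroup: bool = True,
                          outgroup_name: str = "outgroup",
                          outgroup_coding: str = "missing") -> MixedMatrix:
    """Build a rectangular mixed matrix from heterogeneous partitions.

    ``parts`` is a list of (name, ctype, values) where values maps taxon ->
    aligned sequence (dna), state string/list (binary/unordered), or float
    list (continuous); dna may be given as (name, "dna", values,
    gap_as_state).  Continuous characters are rescaled so their observed
    range equals one step; zero-range characters are excluded with a
    warning.  Taxa become the union; missing taxon x partition blocks are
    '?'.  A dummy outgroup row is appended for polarization, coded all-'?'
    (default) or all-primitive ('0' / minimum value).
    """
    taxa: list = []
    for p in parts:
        for t in p[2]:
            if t not in taxa:
                taxa.append(t)
    if dummy_outgroup:
        if outgroup_name in taxa:
            raise ValueError(f"taxon {outgroup_name!r} already present")
        taxa.append(outgroup_name)
    partitions, columns = [], []
    for p in parts:
        name, ctype, values = p[0], p[1], p[2]
        gap_as_state = p[3] if len(p) > 3 else True
        if ctype == "dna":
            width = len(next(iter(values.values())))
            if any(len(s) != width for s in values.values()):
                raise ValueError(f"partition {name!r}: unequal sequence lengths")
            states = _DNA_STATES + ("-",) if gap_as_state else _DNA_STATES
            for j in range(width):
                col = []
                for t in taxa:
                    s = values.get(t)
                    ch = s[j].upper() if s is not None else "?"
                    col.append(ch if ch in states else None)
                columns.append(_Column("dna", f"{name}[{j}]", col, states))
            partitions.append(CharacterPartition(name, "dna", width, gap_as_state))
        elif ctype in ("binary", "unordered"):
            width = len(next(iter(values.values())))
            for j in range(width):
                col = []
                for t in taxa:
                    s = values.get(t)
                    v = s[j] if s is not None else None
                    col.append(None if v in _MISSING else str(v))
                observed = sorted({v for v in col if v is not None})
                if ctype == "binary" and not set(observed) <= {"0", "1"}:
                    raise ValueError(
                        f"partition {name!r}: binary states must be 0/1, "
                        f"got {observed}"
                    )
                states = ("0", "1") if ctype == "binary" else tuple(observed) or ("0",)
                columns.append(_Column(ctype, f"{name}[{j}]", col, states))
            partitions.append(CharacterPartition(name, ctype, width))
        elif ctype == "continuous":
            width = len(next(iter(values.values())))
            ranges = []
            kept = 0
            for j in range(width):
                col = []
                for t in taxa:
                    s = values.get(t)
                    v = s[j] if s is not None else None
                    col.append(None if v is None else float(v))
                obs = [v for v in col if v is not None]
                lo, hi = (min(obs), max(obs)) if obs else (0.0, 0.0)
                if hi - lo <= 0:
                    log.warning("continuous character %s[%d] has zero range; "
                                "excluded", name, j)
                    continue
                scaled = [None if v is None else (v - lo) / (hi - lo) for v in col]
                columns.append(_Column("continuous", f"{name}[{j}]", scaled))
                ranges.append((lo, hi))
                kept += 1
            partitions.append(
                CharacterPartition(name, "continuous", kept, ranges=ranges))
        else:
            raise ValueError(f"unknown character type {ctype!r}")
    if dummy_outgroup and outgroup_coding == "primitive":
        og = taxa.index(outgroup_name)
        for c in columns:
            if c.ctype == "continuous":
                c.values[og] = 0.0
            else:
                c.values[og] = "0" if "0" in c.states else c.states[0]
    return MixedMatrix(taxa, partitions, columns)


# ---------------------------------------------------------------------------
# tree scoring


def _adjacency_from_tree(tree: dendropy.Tree, taxa: list):
    """Unrooted adjacency {node -> set(node)} with leaves 0..n-1 indexing
    ``taxa``; internal nodes numbered from n."""
    idx = {t: i for i, t in enumerate(taxa)}
    adj: dict = {}
    nid = [len(taxa)]
    mapping = {}

    def node_id(nd):
        if nd not in mapping:
            if nd.is_leaf():
                label = nd.taxon.label
                if label not in idx:
                    raise ValueError(f"leaf {label!r} has no matrix row")
                mapping[nd] = idx[label]
            else:
                mapping[nd] = nid[0]
                nid[0] += 1
            adj.setdefault(mapping[nd], set())
        return mapping[nd]

    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        a, b = node_id(edge.tail_node), node_id(edge.head_node)
        adj[a].add(b)
        adj[b].add(a)
    # suppress a degree-2 root
    for v in [v for v in adj if len(adj[v]) == 2 and v >= len(taxa)]:
        a, b = adj[v]
        adj[a].discard(v)
        adj[b].discard(v)
        adj[a].add(b)
        adj[b].add(a)
        del adj[v]
    return adj


def _postorder(adj: dict, root: int):
    """List of (node, children tuple) in postorder, rooted at ``root``."""
    order = []
    stack = [(root, None, False)]
    children = {}
    while stack:
        node, parent, done = stack.pop()
        kids = tuple(x for x in adj[node] if x != parent)
        if done:
            order.append((node, children[node]))
            continue
        children[node] = kids
        stack.append((node, parent, True))
        for k in kids:
            stack.append((k, node, False))
    return order


def _score_discrete(post, leaf_disc, per_char=False):
    n_taxa = leaf_disc.shape[0]
    cost = {}
    for node, kids in post:
        if not kids:
            cost[node] = leaf_disc[node]
            continue
        # a leaf used as root still contributes its own state constraint
        acc = leaf_disc[node].copy() if node < n_taxa else None
        for k in kids:
            ck = cost[k]
            trans = np.minimum(ck, ck.min(axis=1, keepdims=True) + 1.0)
            acc = trans if acc is None else acc + trans
            del cost[k]
        cost[node] = acc
    root, kids = post[-1][0], post[-1][1]
    per = cost[root].min(axis=1)
    per = np.minimum(per, _BIG / 2)  # characters with no valid state
    return per if per_char else float(per.sum())


def _score_continuous_intervals(post, lo0, hi0, per_char=False):
    """Farris interval optimization; exact on binary trees."""
    lo, hi, steps = {}, {}, {}
    n_taxa, n_cont = lo0.shape
    for node, kids in post:
        if not kids:
            lo[node], hi[node] = lo0[node].copy(), hi0[node].copy()
            steps[node] = np.zeros(n_cont)
            continue
        if node < n_taxa:  # leaf used as root
            clo, chi = lo0[node].copy(), hi0[node].copy()
            cst = np.zeros(n_cont)
            rest = kids
        else:
            clo, chi, cst = lo[kids[0]], hi[kids[0]], steps[kids[0]]
            rest = kids[1:]
        for k in rest:
            a = np.maximum(clo, lo[k])
            b = np.minimum(chi, hi[k])
            gap = a - b
            gap = np.where(np.isfinite(gap), np.maximum(gap, 0.0), 0.0)
            cst = cst + steps[k] + gap
            clo, chi = np.minimum(a, b), np.maximum(a, b)
        lo[node], hi[node], steps[node] = clo, chi, cst
    root = post[-1][0]
    return steps[root] if per_char else float(steps[root].sum())


def _is_binary(post) -> bool:
    return all(len(kids) in (0, 2) for node, kids in post[:-1]) and \
        len(post[-1][1]) in (1, 2, 3)


def _score_continuous_grid(post, values, per_char=False):
    """Exact continuous parsimony by dynamic programming on the grid of
    observed values; handles multifurcations (oracle-grade, slower)."""
    n_cont = values.shape[1]
    out = np.zeros(n_cont)
    for j in range(n_cont):
        obs = sorted({v for v in values[:, j] if np.isfinite(v)})
        if len(obs) < 2:
            continue
        g = np.array(obs)
        diff = np.abs(g[:, None] - g[None, :])
        f = {}
        for node, kids in post:
            if not kids:
                v = values[node, j]
                f[node] = np.zeros(len(g)) if not np.isfinite(v) else np.abs(g - v)
                continue
            acc = np.zeros(len(g))
            if node < values.shape[0]:  # leaf used as root
                v = values[node, j]
                if np.isfinite(v):
                    acc += np.abs(g - v)
            for k in kids:
                acc += (f[k][None, :] + diff).min(axis=1)
            f[node] = acc
        out[j] = f[post[-1][0]].min()
    return out if per_char else float(out.sum())


def _score(post, comp, per_char=False, exact_multifurcation=True):
    disc = (_score_discrete(post, comp["leaf_disc"], per_char)
            if len(comp["disc_cols"]) else (np.zeros(0) if per_char else 0.0))
    if len(comp["cont_cols"]):
        if _is_binary(post) or not exact_multifurcation:
            cont = _score_continuous_intervals(
                post, comp["cont_lo"], comp["cont_hi"], per_char)
        else:
            vals = np.where(np.isinf(comp["cont_lo"]), np.nan, comp["cont_lo"])
            cont = _score_continuous_grid(post, vals, per_char)
    else:
        cont = np.zeros(0) if per_char else 0.0
    if per_char:
        return disc, cont
    return disc + cont


def tree_length(tree, matrix: MixedMatrix, per_character: bool = False):
    """Parsimony length of a tree under the mixed-character model.

    ``tree`` may be a dendropy Tree, a newick string, or an adjacency dict.
    Missing data never forces steps.  With ``per_character`` the
    (discrete, continuous) per-character step arrays are returned.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick",
                                 preserve_underscores=True)
    if isinstance(tree, dendropy.Tree):
        adj = _adjacency_from_tree(tree, matrix.taxa)
    else:
        adj = tree
    comp = matrix.compile()
    leaves = [v for v in adj if v < matrix.n_taxa]
    root = min(leaves)
    post = _postorder(adj, root)
    return _score(post, comp, per_char=per_character)


# ---------------------------------------------------------------------------
# exact search (branch and bound)


def _addition_order(matrix: MixedMatrix) -> list:
    """Max-min distance taxon addition order, ties broken lexicographically."""
    n = matrix.n_taxa
    d = np.zeros((n, n))
    for c in matrix.columns:
        for i, j in combinations(range(n), 2):
            a, b = c.values[i], c.values[j]
            if a is None or b is None:
                continue
            if c.ctype == "continuous":
                d[i, j] += abs(a - b)
            elif a != b:
                d[i, j] += 1.0
    d = d + d.T
    labels = matrix.taxa
    start = min(
        ((i, j) for i, j in combinations(range(n), 2)),
        key=lambda ij: (-d[ij], labels[ij[0]], labels[ij[1]]),
    )
    chosen = list(start)
    while len(chosen) < n:
        rest = [i for i in range(n) if i not in chosen]
        nxt = min(rest, key=lambda i: (-min(d[i, c] for c in chosen), labels[i]))
        chosen.append(nxt)
    return chosen


def _splits_of_adj(adj: dict, n_taxa: int) -> frozenset:
    """Canonical nontrivial splits (leaf index frozensets) of an unrooted
    tree given as adjacency."""
    leaves = frozenset(v for v in adj if v < n_taxa)
    splits = set()
    for u in adj:
        for v in adj[u]:
            if u > v:
                continue
            side = set()
            stack, seen = [v], {u, v}
            while stack:
                x = stack.pop()
                if x < n_taxa:
                    side.add(x)
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            if v < n_taxa:
                side.add(v)
            side = frozenset(side)
            if 1 < len(side) < len(leaves) - 1:
                splits.add(min(side, leaves - side,
                               key=lambda s: (len(s), tuple(sorted(s)))))
    return frozenset(splits)


def _adj_to_newick(adj: dict, taxa: list) -> str:
    leaves = sorted(v for v in adj if v < len(taxa))
    if len(adj) == 1:
        return f"{taxa[leaves[0]]};"
    root = next(iter(adj[leaves[0]]))

    def rec(node, parent):
        kids = [x for x in adj[node] if x != parent]
        if not kids:
            return taxa[node]
        return "(" + ",".join(rec(k, node) for k in kids) + ")"

    return rec(root, None) + ";"


def exact_search(matrix: MixedMatrix, max_taxa: int = 14) -> ParsimonyResult:
    """All most-parsimonious unrooted trees by branch and bound.

    Taxa are added in max-min distance order; the upper bound starts from a
    greedy stepwise-addition tree; a partial tree is pruned as soon as its
    score exceeds the current bound (parsimony length is monotone under
    taxon addition).  Refuses more than ``max_taxa`` taxa — heuristic
    searches are out of scope.
    """
    n = matrix.n_taxa
    if n > max_taxa:
        raise ValueError(
            f"{n} taxa exceeds the exact-search bound of {max_taxa}; "
            "reduce the taxon set or use an external heuristic search"
        )
    if n < 3:
        raise ValueError("need at least 3 taxa")
    comp = matrix.compile()
    order = _addition_order(matrix)
    root_leaf = order[0]

    def score_adj(adj):
        return _score(_postorder(adj, root_leaf), comp)

    def base_adj():
        c = n  # first internal node id
        return {order[0]: {c}, order[1]: {c}, order[2]: {c},
                c: {order[0], order[1], order[2]}}

    def edges_of(adj):
        return [(u, v) for u in adj for v in adj[u] if u < v]

    def insert(adj, u, v, leaf, w):
        adj[u].discard(v)
        adj[v].discard(u)
        adj[u].add(w)
        adj[v].add(w)
        adj[w] = {u, v, leaf}
        adj[leaf] = {w}

    def remove(adj, u, v, leaf, w):
        del adj[w], adj[leaf]
        adj[u].discard(w)
        adj[v].discard(w)
        adj[u].add(v)
        adj[v].add(u)

    # greedy upper bound
    adj = base_adj()
    w = n + 1
    for k in range(3, n):
        leaf = order[k]
        best_edge, best_s = None, np.inf
        for u, v in edges_of(adj):
            insert(adj, u, v, leaf, w)
            s = score_adj(adj)
            remove(adj, u, v, leaf, w)
            if s < best_s - _TOL:
                best_s, best_edge = s, (u, v)
        insert(adj, *best_edge, leaf, w)
        w += 1
    bound = score_adj(adj)

    best = [bound]
    mp: list = []
    examined = [0]

    def rec(adj, k, w):
        if k == n:
            s = score_adj(adj)
            examined[0] += 1
            if s < best[0] - _TOL:
                best[0] = s
                mp.clear()
            if s <= best[0] + _TOL:
                mp.append({u: set(vs) for u, vs in adj.items()})
            return
        leaf = order[k]
        for u, v in edges_of(adj):
            insert(adj, u, v, leaf, w)
            if score_adj(adj) <= best[0] + _TOL:
                rec(adj, k + 1, w + 1)
            remove(adj, u, v, leaf, w)

    if n == 3:
        mp.append(base_adj())
        best[0] = score_adj(base_adj())
    else:
        rec(base_adj(), 3, n + 1)

    score = best[0]
    mins, maxs = matrix.char_bounds()
    ci = float(mins.sum() / score) if score > _TOL else None
    denom = maxs.sum() - mins.sum()
    ri = float((maxs.sum() - score) / denom) if denom > _TOL else None
    trees = [
        dendropy.Tree.get(data=_adj_to_newick(a, matrix.taxa), schema="newick",
                          preserve_underscores=True)
        for a in mp
    ]
    result = ParsimonyResult(trees, float(score), ci, ri, examined[0])
    result._mp_adjacency = mp  # internal reuse by resampling
    return result


def strict_consensus_splits(result_or_adjs, matrix: MixedMatrix) -> set:
    """Nontrivial splits present in every MP tree (leaf label frozensets)."""
    adjs = getattr(result_or_adjs, "_mp_adjacency", result_or_adjs)
    common = None
    for a in adjs:
        s = _splits_of_adj(a, matrix.n_taxa)
        common = s if common is None else (common & s)
    labels = matrix.taxa
    return {frozenset(labels[i] for i in side) for side in (common or set())}


def resample_support(matrix: MixedMatrix, method: str = "bootstrap",
                     p: float = 0.36, reps: int = 1000,
                     seed: int | None = None) -> dict:
    """Clade support by character resampling.

    Bootstrap resamples characters with replacement; jackknife deletes
    each character independently with probability ``p``.  Continuous
    characters resample as single units like any column.  Support of a
    clade = percent of replicates whose MP strict consensus contains it.
    Returns {frozenset(labels): percent}.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if method not in ("bootstrap", "jackknife"):
        raise ValueError(f"unknown resampling method {method!r}")
    rng = np.random.default_rng(seed)
    m = matrix.n_chars
    counts: dict = {}
    for _ in range(reps):
        if method == "bootstrap":
            idx = rng.integers(0, m, size=m)
        else:
            idx = np.flatnonzero(rng.random(m) >= p)
        if len(idx) == 0:
            continue
        sub = matrix.subset_columns(idx)
        res = exact_search(sub)
        for clade in strict_consensus_splits(res, sub):
            counts[clade] = counts.get(clade, 0) + 1
    return {clade: 100.0 * c / reps for clade, c in counts.items()}


# ---------------------------------------------------------------------------
# synapomorphy mapping


def _rooted_children(adj: dict, root: int):
    post = _postorder(adj, root)
    return post


def _node_optimal_sets_discrete(post, parent_of, leaf_disc_col, n_states):
    """Per-node sets of states taken across all MP reconstructions
    (marginal sets from up/down dynamic programming)."""
    n_taxa = leaf_disc_col.shape[0]
    up = {}
    order = post
    for node, kids in order:
        if not kids:
            up[node] = leaf_disc_col[node][:n_states].copy()
        else:
            acc = (leaf_disc_col[node][:n_states].copy()
                   if node < n_taxa else np.zeros(n_states))
            for k in kids:
                acc += np.minimum(up[k], up[k].min() + 1.0)
            up[node] = acc
    root = order[-1][0]
    down = {root: np.zeros(n_states)}
    for node, kids in reversed(order):
        for c in kids:
            base = down[node].copy()
            if node < n_taxa:  # a leaf used as root constrains its subtree
                base += leaf_disc_col[node][:n_states]
            for sib in kids:
                if sib is not c:
                    base += np.minimum(up[sib], up[sib].min() + 1.0)
            # down[c][t] = min_s base[s] + (s != t)
            down[c] = np.minimum(base, base.min() + 1.0)
    total_min = (up[root] + down[root]).min()
    sets = {}
    for node in up:
        tot = up[node] + down[node]
        sets[node] = frozenset(np.flatnonzero(tot <= total_min + _TOL).tolist())
    return sets


def _node_optimal_sets_continuous(post, values_col):
    """Grid-DP analog for one continuous character: per-node (lo, hi) of
    the values taken across all MP reconstructions."""
    obs = sorted({v for v in values_col if v is not None})
    if len(obs) < 2:
        return None
    g = np.array(obs)
    diff = np.abs(g[:, None] - g[None, :])

    def relax(f):
        return (f[None, :] + diff).min(axis=1)

    n_leaf_rows = len(values_col)
    up = {}
    for node, kids in post:
        if not kids:
            v = values_col[node]
            up[node] = np.zeros(len(g)) if v is None else np.abs(g - v)
        else:
            acc = np.zeros(len(g))
            if node < n_leaf_rows:  # leaf used as root
                v = values_col[node]
                if v is not None:
                    acc += np.abs(g - v)
            for k in kids:
                acc += relax(up[k])
            up[node] = acc
    root = post[-1][0]
    down = {root: np.zeros(len(g))}
    for node, kids in reversed(post):
        for c in kids:
            base = down[node].copy()
            if node < n_leaf_rows:  # leaf used as root
                v = values_col[node]
                if v is not None:
                    base += np.abs(g - v)
            for sib in kids:
                if sib is not c:
                    base += relax(up[sib])
            down[c] = relax(base)
    total_min = (up[root] + down[root]).min()
    sets = {}
    for node in up:
        tot = up[node] + down[node]
        opt = np.flatnonzero(tot <= total_min + 1e-12)
        sets[node] = (float(g[opt[0]]), float(g[opt[-1]]))
    return sets


def map_synapomorphies(tree, matrix: MixedMatrix,
                       outgroup: str = "outgroup") -> SynapomorphyMap:
    """Character state changes supported by every MP reconstruction.

    The tree is rooted at the designated outgroup leaf (polarization is
    undefined without one).  For each character the set of optimal states
    at every node is computed over all most-parsimonious reconstructions;
    a branch change is recorded as non-ambiguous when parent and child
    sets are singletons that differ, and as ambiguous when the sets are
    disjoint but not unique (a change certainly occurs, but its states
    vary between reconstructions).  Continuous characters report the
    guaranteed direction and the minimal magnitude of change.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick",
                                 preserve_underscores=True)
    if isinstance(tree, dendropy.Tree):
        adj = _adjacency_from_tree(tree, matrix.taxa)
    else:
        adj = {u: set(vs) for u, vs in tree.items()}
    if outgroup not in matrix.taxa:
        raise ValueError(
            f"outgroup {outgroup!r} not in the matrix; an unrooted tree "
            "cannot be polarized"
        )
    og = matrix.taxa.index(outgroup)
    if og not in adj:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    post = _postorder(adj, og)
    parent_of = {}
    for node, kids in post:
        for k in kids:
            parent_of[k] = node
    # leaf labels below each node, for branch keys
    below = {}
    for node, kids in post:
        if not kids:
            below[node] = frozenset([matrix.taxa[node]])
        else:
            s = frozenset()
            for k in kids:
                s |= below[k]
            below[node] = s
    comp = matrix.compile()
    entries = []
    d_k = 0
    c_k = 0
    for col in matrix.columns:
        if col.ctype == "continuous":
            sets = _node_optimal_sets_continuous(post, col.values)
            c_k += 1
            if sets is None:
                continue
            for child, parent in parent_of.items():
                plo, phi = sets[parent]
                clo, chi = sets[child]
                if phi < clo - 1e-12:
                    entries.append((below[child], col.name, phi, clo, False))
                elif chi < plo - 1e-12:
                    entries.append((below[child], col.name, plo, chi, False))
        else:
            leaf_col = comp["leaf_disc"][:, d_k, :]
            nst = int(comp["n_states"][d_k])
            d_k += 1
            sets = _node_optimal_sets_discrete(post, parent_of, leaf_col, nst)
            for child, parent in parent_of.items():
                sp, sc = sets[parent], sets[child]
                if len(sp) == 1 and len(sc) == 1 and sp != sc:
                    frm = col.states[next(iter(sp))]
                    to = col.states[next(iter(sc))]
                    entries.append((below[child], col.name, frm, to, False))
                elif not (sp & sc):
                    entries.append((below[child], col.name, None, None, True))
    return SynapomorphyMap(entries)
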