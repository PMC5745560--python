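"""Shared fixtures and independent oracles for the test suite."""

from itertools import product

import numpy as np
import pytest

from plastophylo.io import Alignment


def canon_side(side, taxa):
    """Canonical representative of a split: smaller side, ties by labels."""
    ts = frozenset(taxa)
    side = frozenset(side)
    return min(side, ts - side, key=lambda s: (len(s), tuple(sorted(s))))


def all_unrooted_adjacencies(n_taxa):
    """Enumerate every unrooted binary tree on taxa 0..n-1 as adjacency
    dicts (3, 15, 105, 945 ... trees).  Independent of the search code."""
    trees = []

    def rec(adj, k, w):
        if k == n_taxa:
            trees.append({u: set(v) for u, v in adj.items()})
            return
        for u, v in [(u, v) for u in adj for v in adj[u] if u < v]:
            adj[u].discard(v)
            adj[v].discard(u)
            adj[u].add(w)
            adj[v].add(w)
            adj[w] = {u, v, k}
            adj[k] = {w}
            rec(adj, k + 1, w + 1)
            del adj[w], adj[k]
            adj[u].discard(w)
            adj[v].discard(w)
            adj[u].add(v)
            adj[v].add(u)

    base = {0: {n_taxa}, 1: {n_taxa}, 2: {n_taxa},
            n_taxa: {0, 1, 2}}
    if n_taxa == 3:
        return [base]
    rec(base, 3, n_taxa + 1)
    return trees


def brute_force_discrete_steps(adj, n_taxa, leaf_states, states):
    """Minimum steps of one discrete character by exhaustive enumeration of
    internal-node state assignments.  leaf_states: taxon -> set of allowed
    states (missing = all)."""
    internal = sorted(v for v in adj if v >= n_taxa)
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    best = np.inf
    leaf_choices = [sorted(leaf_states[i]) for i in range(n_taxa)]
    for leaf_assign in product(*leaf_choices):
        for internal_assign in product(states, repeat=len(internal)):
            assign = dict(enumerate(leaf_assign))
            assign.update(zip(internal, internal_assign))
            steps = sum(assign[u] != assign[v] for u, v in edges)
            best = min(best, steps)
    return best


def brute_force_continuous_steps(adj, n_taxa, leaf_values):
    """Minimum total absolute change of one continuous character by grid
    search over observed values at internal nodes (exact: an optimal
    solution exists on that grid)."""
    obs = sorted({v for v in leaf_values if v is not None})
    if len(obs) < 2:
        return 0.0
    internal = sorted(v for v in adj if v >= n_taxa)
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    best = np.inf
    for assign_int in product(obs, repeat=len(internal)):
        assign = dict(zip(internal, assign_int))
        for i in range(n_taxa):
            assign[i] = leaf_values[i]
        total = 0.0
        for u, v in edges:
            a, b = assign[u], assign[v]
            if a is None or b is None:
                continue
            total += abs(a - b)
        best = min(best, total)
    return best


@pytest.fixture
def toy_alignment():
    """3 species, 10 gap-free columns, 2 variable (positions 0 and 5)."""
    return Alignment(
        ["sp1", "sp2", "sp3"],
        ["ACGTACGTAC",
         "CCGTATGTAC",
         "ACGTATGTAC"],
    )


@pytest.fixture
def tree_metric_case():
    """Path distances of ((A:1,B:2):1,(C:3,D:4):2); computed by hand."""
    taxa = ("A", "B", "C", "D")
    d = np.array([
        [0, 3, 7, 8],
        [3, 0, 8, 9],
        [7, 8, 0, 7],
        [8, 9, 7, 0],
    ], dtype=float)
    return taxa, d
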