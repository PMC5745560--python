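"""Weighted split systems (bipartitions of a taxon set).

A split A|B is stored by one of its sides; the canonical representative is
the side *not* containing the first taxon of the system, so that every
bipartition has exactly one stored form.  Split systems may carry a circular
taxon ordering (Neighbour-Net output), in which case every split side is an
interval of that ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Split", "SplitSystem", "splits_from_tree", "splits_compatible"]


@dataclass(frozen=True)
class Split:
    """One weighted bipartition, identified by the stored side."""

    side: frozenset
    weight: float = 1.0

    def separates(self, a, b) -> bool:
        return (a in self.side) != (b in self.side)

    def is_trivial(self, n_taxa: int) -> bool:
        return len(self.side) == 1 or len(self.side) == n_taxa - 1

    def other_side(self, taxa) -> frozenset:
        return frozenset(taxa) - self.side


def _canonical_side(side: frozenset, taxa) -> frozenset:
    first = sorted(taxa)[0]
    if first in side:
        return frozenset(taxa) - side
    return frozenset(side)


@dataclass
class SplitSystem:
    """A collection of weighted splits on a fixed taxon set."""

    taxa: tuple
    splits: list = field(default_factory=list)
    circular_order: tuple | None = None

    def __post_init__(self):
        self.taxa = tuple(self.taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels in split system")
        taxset = set(self.taxa)
        canon = {}
        for s in self.splits:
            if not s.side or not (taxset - s.side):
                raise ValueError("split with an empty side")
            if not s.side <= taxset:
                raise ValueError("split side contains unknown taxa")
            if s.weight < 0:
                raise ValueError("negative split weight")
            key = _canonical_side(s.side, self.taxa)
            if key in canon:
                canon[key] = Split(key, canon[key].weight + s.weight)
            else:
                canon[key] = Split(key, s.weight)
        self.splits = list(canon.values())

    def __len__(self):
        return len(self.splits)

    def nontrivial(self) -> list:
        n = len(self.taxa)
        return [s for s in self.splits if not s.is_trivial(n)]

    def split_sides(self) -> set:
        return {s.side for s in self.splits}

    def weight_of(self, side) -> float | None:
        key = _canonical_side(frozenset(side), self.taxa)
        for s in self.splits:
            if s.side == key:
                return s.weight
        return None

    def induced_distances(self) -> np.ndarray:
        """Pairwise distances implied by the system: sum of weights of the
        splits separating each taxon pair."""
        n = len(self.taxa)
        idx = {t: i for i, t in enumerate(self.taxa)}
        d = np.zeros((n, n))
        for s in self.splits:
            mask = np.zeros(n, dtype=bool)
            for t in s.side:
                mask[idx[t]] = True
            sep = np.logical_xor.outer(mask, mask)
            d[sep] += s.weight
        return d

    def is_circular(self) -> bool:
        """True if every split side is an interval of ``circular_order``."""
        if self.circular_order is None:
            return False
        pos = {t: i for i, t in enumerate(self.circular_order)}
        n = len(self.circular_order)
        for s in self.splits:
            for side in (s.side, frozenset(self.taxa) - s.side):
                ps = sorted(pos[t] for t in side)
                if ps[-1] - ps[0] == len(ps) - 1:
                    break
                # interval may wrap around the circle
                gaps = [(ps[(i + 1) % len(ps)] - ps[i]) % n for i in range(len(ps))]
                if sum(g > 1 for g in gaps) <= 1:
                    break
            else:
                return False
        return True


def splits_compatible(a: frozenset, b: frozenset, taxa) -> bool:
    """Two splits are compatible iff some pair of opposite sides is disjoint."""
    taxset = frozenset(taxa)
    a2, b2 = taxset - a, taxset - b
    return not (a & b) or not (a & b2) or not (a2 & b) or not (a2 & b2)


def splits_from_tree(tree: dendropy.Tree) -> dict:
    """Extract the (leaf-side, branch length) splits of an unrooted tree.

    Returns a mapping ``frozenset(leaf labels) -> branch length`` with one
    entry per edge; degree-2 root edges are merged.  Lengths default to 1.0
    when absent.
    """
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = {}
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in edge.head_node.leaf_iter())
        if not side or side == all_leaves:
            continue
        length = edge.length if edge.length is not None else 1.0
        key = min(side, all_leaves - side, key=lambda s: (len(s), tuple(sorted(s))))
        out[key] = out.get(key, 0.0) + length
    return out
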