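"""Synthetic plastome and mixed-matrix generators with exact ground truth.

These generators stand in for data acquisition so every stage of the
toolkit can be exercised and scored offline: annotated genomes are evolved
along a known tree under a site-independent substitution model (indel-free
unless events are explicitly injected, so coordinates stay exact),
structural events are injected with post-injection truth coordinates, and
mixed character matrices carry planted synapomorphies recorded in a truth
list.  All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from plastophylo.io import AnnotatedGenome, GenomicFeature, revcomp
from plastophylo.parsimony import MixedMatrix, assemble_mixed_matrix

__all__ = [
    "GeneTemplate",
    "SimulationConfig",
    "SimulatedDataset",
    "default_template",
    "random_tree",
    "simulate_dataset",
    "Event",
    "InjectedEvent",
    "inject_events",
    "simulate_mixed_dataset",
    "DEFAULT_PAIR_DIVERGENCE",
]

log = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: expected substitutions/site between the two focal species of a
#: two-genome comparison, set so the expected uncorrected p-distance is
#: 0.0099 under JC, i.e. ~99.01% pairwise identity.
DEFAULT_PAIR_DIVERGENCE = float(-0.75 * np.log(1 - 4 * 0.0099 / 3))


@dataclass
class GeneTemplate:
    """Gene map of the root genome: names, kinds, strands and exon layout
    (0-based half-open intervals on the forward strand)."""

    length: int
    genes: list  # (name, kind, strand, [(start, end), ...])

    def features(self) -> list:
        return [GenomicFeature(n, k, s, [tuple(e) for e in ex])
                for n, k, s, ex in self.genes]


def default_template() -> GeneTemplate:
    """Desk-scale plastome proxy: 20 kb, 12 genes (2 multi-exon), named
    after real plastid genes."""
    genes = [
        ("psbA", "gene", 1, [(300, 1362)]),
        ("trnH", "tRNA", -1, [(1600, 1674)]),
        ("matK", "gene", 1, [(2100, 3630)]),
        ("rps16", "gene", -1, [(4100, 4340), (5200, 5425)]),   # 1 intron
        ("trnK", "tRNA", 1, [(5800, 5837), (6900, 6935)]),     # 1 intron
        ("atpA", "gene", 1, [(7400, 8923)]),
        ("rpoB", "gene", -1, [(9400, 12613)]),
        ("clpP", "gene", 1, [(13100, 13691)]),
        ("petB", "gene", 1, [(14100, 14742)]),
        ("ndhA", "gene", -1, [(15200, 16292)]),
        ("rbcL", "gene", 1, [(16800, 18227)]),
        ("trnS", "tRNA", 1, [(18700, 18787)]),
    ]
    return GeneTemplate(length=20000, genes=genes)


@dataclass
class SimulationConfig:
    tree: str | None = None        # newick; None -> random tree
    n_taxa: int = 8
    model: str = "JC"              # JC | K2P | HKY
    kappa: float = 2.0             # K2P/HKY transition/transversion ratio
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)  # HKY only (ACGT order)
    template: GeneTemplate | None = None
    seed: int = 0
    tree_height: float = 0.02      # random-tree depth, subs/site


@dataclass
class SimulatedDataset:
    genomes: dict                  # taxon -> AnnotatedGenome
    tree: dendropy.Tree
    locus_table: list              # (locus_id, kind, start, end) shared map
    branch_substitutions: dict     # frozenset(clade leaves) -> count
    config: SimulationConfig


def random_tree(n_taxa: int, seed: int, height: float = 0.02) -> dendropy.Tree:
    """Random binary tree by sequential random joins; branch lengths are
    uniform fractions of ``height`` (expected substitutions/site)."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    subtrees = [f"T{i + 1}" for i in range(n_taxa)]
    while len(subtrees) > 2:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        la, lb = rng.uniform(0.3, 1.0, 2) * height
        subtrees.append(f"({a}:{la:.8f},{b}:{lb:.8f})")
    la, lb = rng.uniform(0.3, 1.0, 2) * height
    newick = f"({subtrees[0]}:{la:.8f},{subtrees[1]}:{lb:.8f});"
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def _rate_matrix(model: str, kappa: float, freqs) -> tuple:
    pi = np.asarray(freqs, dtype=float)
    pi = pi / pi.sum()
    if model in ("JC", "K2P"):
        pi = np.full(4, 0.25)
        if model == "JC":
            kappa = 1.0
    elif model != "HKY":
        raise ValueError(f"unknown model {model!r}")
    # state order ACGT; transitions are A<->G and C<->T
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            ti = (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1))
            Q[i, j] = (kappa if ti else 1.0) * pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu, pi  # one expected substitution per unit branch length


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Evolve the template genome along a tree.

    Returns leaf genomes plus exact truth tables: the generating tree, the
    shared non-coding locus map implied by the template, and per-branch
    realized substitution counts (keyed by the leaf set below the branch).
    """
    from scipy.linalg import expm

    rng = np.random.default_rng(cfg.seed)
    template = cfg.template or default_template()
    feats = template.features()
    for f in feats:
        if f.span[1] > template.length:
            raise ValueError(
                f"template gene {f.name} exceeds genome length {template.length}"
            )
    if cfg.tree is not None:
        tree = dendropy.Tree.get(data=cfg.tree, schema="newick",
                                 preserve_underscores=True)
    else:
        tree = random_tree(cfg.n_taxa, cfg.seed + 1, cfg.tree_height)
    Q, pi = _rate_matrix(cfg.model, cfg.kappa, cfg.base_freqs)
    root_states = rng.choice(4, size=template.length, p=pi)
    states = {tree.seed_node: root_states}
    branch_subs = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        parent = states[node.parent_node]
        if t <= 0:
            child = parent.copy()
        else:
            P = expm(Q * t)
            cum = P.cumsum(axis=1)
            u = rng.random(template.length)
            child = (u[:, None] > cum[parent]).sum(axis=1)
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        branch_subs[clade] = int((child != parent).sum())
        states[node] = child
    bases = np.array(_BASES)
    genomes = {}
    for leaf in sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label):
        seq = "".join(bases[states[leaf]])
        genomes[leaf.taxon.label] = AnnotatedGenome(
            id=leaf.taxon.label, sequence=seq, circular=True,
            features=[GenomicFeature(f.name, f.kind, f.strand, list(f.exons))
                      for f in feats],
        )
    return SimulatedDataset(genomes, tree, _locus_table(template),
                            branch_subs, cfg)


def _locus_table(template: GeneTemplate) -> list:
    """Ground-truth non-coding loci implied by the template gene map."""
    rows = []
    for name, kind, strand, exons in template.genes:
        exs = sorted(exons)
        gaps = [(e1, s2) for (s1, e1), (s2, e2) in zip(exs, exs[1:]) if s2 > e1]
        if strand == -1:
            gaps = gaps[::-1]
        for k, (s, e) in enumerate(gaps, 1):
            rows.append((f"{name}_intron{k}", "intron", s, e))
    spans = sorted((min(s for s, _ in ex), max(e for _, e in ex), name)
                   for name, _, _, ex in template.genes)
    for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
        if s2 > e1:
            rows.append((f"{n1}-{n2}", "igs", e1, s2))
    last_s, last_e, last_n = spans[-1]
    first_s, first_e, first_n = spans[0]
    rows.append((f"{last_n}-{first_n}", "igs", last_e,
                 first_s + template.length))
    return rows


# ---------------------------------------------------------------------------
# event injection


@dataclass
class Event:
    kind: str          # palindrome | duplication | inversion | deletion | insertion
    start: int         # anchor coordinate, pre-injection
    length: int
    target: int | None = None   # duplication: insertion point of the copy
    payload: str | None = None  # insertion: explicit sequence


@dataclass
class InjectedEvent:
    kind: str
    intervals: list    # post-injection footprint coordinates
    length: int


def inject_events(genome: AnnotatedGenome, events: list,
                  seed: int = 0) -> tuple:
    """Apply structural events; returns (new genome, truth table).

    Events must not overlap one another or an annotated gene.  They are
    applied in descending coordinate order so earlier coordinates stay
    valid; feature coordinates are shifted across indels and the truth
    table reports post-injection coordinates.  Flanking bases are adjusted
    wherever an accidental match would let a detector's maximal extension
    overrun the injected footprint — this keeps ground truth exact.
    """
    rng = np.random.default_rng(seed)
    footprints = []
    for ev in events:
        footprints.append((ev.start, ev.start + ev.length))
        if ev.kind == "duplication":
            if ev.target is None:
                raise ValueError("duplication requires a target position")
            footprints.append((ev.target, ev.target + 1))
    footprints.sort()
    for (a1, b1), (a2, b2) in zip(footprints, footprints[1:]):
        if a2 < b1:
            raise ValueError("injected events overlap")
    for ev in events:
        for f in genome.features:
            for s, e in f.exons:  # introns and spacers are fair game
                if ev.start < e and ev.start + ev.length > s:
                    raise ValueError(
                        f"event at [{ev.start},{ev.start + ev.length}) "
                        f"overlaps an exon of {f.name}"
                    )
    seq = list(genome.sequence)
    shifts = []         # (position, delta, event_index)
    truth_raw = []      # (event_index, kind, [intervals pre-shift], length)
    for ei, ev in sorted(enumerate(events), key=lambda kv: -kv[1].start):
        s, L = ev.start, ev.length
        if ev.kind == "palindrome":
            arm = L // 2
            left = [str(rng.choice(_BASES)) for _ in range(arm)]
            seq[s : s + 2 * arm] = left + [_COMP[c] for c in left[::-1]]
            if s > 0 and s + 2 * arm < len(seq):
                while _COMP.get(seq[s - 1]) == seq[s + 2 * arm]:
                    seq[s + 2 * arm] = str(rng.choice(_BASES))
            truth_raw.append((ei, "palindrome", [(s, s + 2 * arm)], 2 * arm))
        elif ev.kind == "inversion":
            seg = "".join(seq[s : s + L])
            inv = revcomp(seg)
            if inv == seg:
                raise ValueError("inverted segment is palindromic; undetectable")
            seq[s : s + L] = list(inv)
            if s > 0 and s + L < len(seq):
                # a reverse-strand match against the pre-injection sequence
                # must not extend past the segment on either side
                orig_left, orig_right = seq[s - 1], seq[s + L]
                while seq[s + L] == _COMP.get(orig_left):
                    seq[s + L] = str(rng.choice(_BASES))
                while seq[s - 1] == _COMP.get(orig_right):
                    seq[s - 1] = str(rng.choice(_BASES))
            truth_raw.append((ei, "inversion", [(s, s + L)], L))
        elif ev.kind == "deletion":
            del seq[s : s + L]
            shifts.append((s, -L, ei))
            truth_raw.append((ei, "deletion", [(s, s)], L))
        elif ev.kind == "insertion":
            payload = list(ev.payload) if ev.payload else [
                str(rng.choice(_BASES)) for _ in range(L)]
            if len(payload) != L:
                raise ValueError("payload length mismatch")
            seq[s:s] = payload
            shifts.append((s, L, ei))
            truth_raw.append((ei, "insertion", [(s, s + L)], L))
        elif ev.kind == "duplication":
            t = ev.target
            if not (t <= s - 1 or t >= s + L + 1):
                raise ValueError("duplication target must be non-adjacent")
            copy = seq[s : s + L]
            seq[t:t] = copy
            shifts.append((t, L, ei))
            if t < s:
                ivals = [(t, t + L), (s + L, s + 2 * L)]
            else:
                ivals = [(s, s + L), (t, t + L)]
            # copies must not be extendable: fix flanks of the second copy
            (a1, b1), (a2, b2) = ivals
            if a1 > 0 and a2 > 0:
                while seq[a1 - 1] == seq[a2 - 1]:
                    seq[a2 - 1] = str(rng.choice(_BASES))
            if b1 < len(seq) and b2 < len(seq):
                while seq[b1] == seq[b2]:
                    seq[b2] = str(rng.choice(_BASES))
            truth_raw.append((ei, "duplication", ivals, L))
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")

    def shift(pos, own):
        out = pos
        for at, delta, ei in shifts:
            if ei != own and at <= pos:
                out += delta
        return out

    feats = [
        GenomicFeature(f.name, f.kind, f.strand,
                       [(shift(a, None), shift(b, None)) for a, b in f.exons],
                       f.non_extractable)
        for f in genome.features
    ]
    out = AnnotatedGenome(genome.id, "".join(seq), genome.circular, feats)
    truth = [
        InjectedEvent(kind, [(shift(a, ei), shift(b, ei)) for a, b in ivals],
                      length)
        for ei, kind, ivals, length in sorted(truth_raw)
    ]
    return out, truth


# ---------------------------------------------------------------------------
# mixed matrices with planted synapomorphies


def simulate_mixed_dataset(tree, n_binary: int = 20, n_unordered: int = 0,
                           n_continuous: int = 5, homoplasy_rate: float = 0.0,
                           seed: int = 0, outgroup: str = "outgroup",
                           ensure_coverage: bool = True,
                           dummy_outgroup: bool = True) -> tuple:
    """Mixed matrix generated on a known tree with planted synapomorphies.

    Each character receives a single derived-state change on one internal
    branch of the (ingroup) tree; with probability ``homoplasy_rate`` an
    extra flip on a random leaf adds homoplasy (such characters are removed
    from the planted truth).  With ``ensure_coverage`` the binary
    characters cycle through every internal branch first, so the generating
    tree is the unique MP tree for a homoplasy-free matrix.  Continuous
    characters are planted as a unit step (range standardization maps it
    back to one step).

    Returns (MixedMatrix, planted, rooted_tree) where planted is a list of
    (char_name, clade frozenset, from_state, to_state) and rooted_tree is
    the generating tree with the dummy outgroup attached at the root.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick",
                                 preserve_underscores=True)
    rng = np.random.default_rng(seed)
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    if len(leaves) < 4:
        raise ValueError("need a tree with at least 4 leaves")
    clades = []
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if 2 <= len(below) <= len(leaves) - 2 and below not in clades:
            clades.append(below)
    if not clades:
        raise ValueError("tree has no informative internal branches")
    planted = []
    parts = []

    def plant_discrete(prefix, count):
        cols = {t: [] for t in leaves}
        for j in range(count):
            if ensure_coverage and j < len(clades):
                clade = clades[j]
            else:
                clade = clades[int(rng.integers(len(clades)))]
            for t in leaves:
                cols[t].append("1" if t in clade else "0")
            if rng.random() < homoplasy_rate:
                other = leaves[int(rng.integers(len(leaves)))]
                cols[other][-1] = "1" if cols[other][-1] == "0" else "0"
            else:
                planted.append((f"{prefix}[{j}]", clade, "0", "1"))
        return {t: "".join(v) for t, v in cols.items()}

    if n_binary:
        parts.append(("binary", "binary", plant_discrete("binary", n_binary)))
    if n_unordered:
        parts.append(("unordered", "unordered",
                      plant_discrete("unordered", n_unordered)))
    if n_continuous:
        cols = {t: [] for t in leaves}
        for j in range(n_continuous):
            clade = clades[int(rng.integers(len(clades)))]
            for t in leaves:
                cols[t].append(1.0 if t in clade else 0.0)
            planted.append((f"continuous[{j}]", clade, 0.0, 1.0))
        parts.append(("continuous", "continuous", cols))
    matrix = assemble_mixed_matrix(parts, dummy_outgroup=dummy_outgroup,
                                   outgroup_name=outgroup,
                                   outgroup_coding="primitive")
    if not dummy_outgroup:
        return matrix, planted, tree
    ingroup = tree.as_string(schema="newick", suppress_rooting=True).strip()
    ingroup = ingroup.rstrip(";").strip()
    rooted = dendropy.Tree.get(data=f"({ingroup},{outgroup});",
                               schema="newick", preserve_underscores=True)
    return matrix, planted, rooted
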