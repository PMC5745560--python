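"""Variability scoring and threshold-based marker selection.

Per-locus statistics follow the screening procedure used for plastid
non-coding markers: a normalized divergence ratio
``r = (variable sites / constant sites) / number of species`` and the
average pairwise uncorrected p-distance ``p_bar``.  A locus qualifies as a
marker when it is strictly above the across-locus mean of *both* statistics
(or user-supplied thresholds).  The module also builds concatenated
supermatrices with partition bookkeeping and computes percent pairwise
identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from plastophylo.io import Alignment, UNAMBIGUOUS

__all__ = [
    "SiteCounts",
    "LocusStats",
    "SelectionReport",
    "Supermatrix",
    "locus_stats",
    "rank_and_select",
    "concatenate_partitions",
    "pairwise_identity",
    "IGS_T_RATIO",
    "IGS_T_P",
    "INTRON_T_RATIO",
    "INTRON_T_P",
]

#: Shipped screening thresholds for plastid IGS loci (across-locus means
#: from a 30-spacer survey of *Ilex* plastomes).
IGS_T_RATIO = 0.0023
IGS_T_P = 0.0067
#: Corresponding thresholds from the 18-intron survey.
INTRON_T_RATIO = 0.0016
INTRON_T_P = 0.0042


@dataclass
class SiteCounts:
    total_sites: int
    analysed_sites: int
    variable_sites: int
    constant_sites: int

    def __post_init__(self):
        if self.variable_sites + self.constant_sites != self.analysed_sites:
            raise ValueError("variable + constant must equal analysed sites")


@dataclass
class LocusStats:
    locus_id: str
    n_species: int
    counts: SiteCounts | None
    ratio: float | None   # (V/C)/n; None when C == 0 or locus degenerate
    p_bar: float | None   # mean pairwise uncorrected p-distance
    degenerate: bool = False

    @property
    def defined(self) -> bool:
        return not self.degenerate and self.ratio is not None


@dataclass
class SelectionReport:
    stats: list
    t_ratio: float
    t_p: float
    selected: list  # locus ids, strictly above both thresholds
    ranking: list   # locus ids sorted by (ratio desc, p_bar desc, id)


@dataclass
class Supermatrix:
    taxa: list
    partitions: list  # (locus_id, (start, end)) column spans, 0-based half-open
    alignment: Alignment
    missing_fraction: float

    def partition_slice(self, locus_id: str) -> Alignment:
        for name, (s, e) in self.partitions:
            if name == locus_id:
                return self.alignment.subset_columns(s, e)
        raise KeyError(locus_id)

    def partition_table(self) -> str:
        """RAxML-style partition text, 1-based inclusive."""
        return "\n".join(
            f"{name} = {s + 1}-{e}" for name, (s, e) in self.partitions
        )


def _char_matrix(aln: Alignment) -> np.ndarray:
    return np.array([list(r) for r in aln.rows], dtype="U1")


def locus_stats(aln: Alignment, deletion: str = "complete",
                locus_id: str = "", n_species: int | None = None) -> LocusStats:
    """Site counts, normalized divergence ratio and average p-distance.

    Under complete deletion every column containing a gap, N or IUPAC
    ambiguity is excluded from the analysed sites; under pairwise deletion a
    column is analysed when at least two rows carry unambiguous residues.
    ``p_bar`` always uses pairwise deletion within each sequence pair.  A
    locus with no analysed sites is flagged degenerate; C = 0 leaves the
    ratio undefined (None), never infinite.
    """
    if len(aln) < 2:
        raise ValueError("locus statistics need at least 2 sequences")
    n = n_species if n_species is not None else len(aln)
    m = _char_matrix(aln)
    ok = np.isin(m, list(UNAMBIGUOUS))
    if deletion == "complete":
        analysed_cols = ok.all(axis=0)
    elif deletion == "pairwise":
        analysed_cols = ok.sum(axis=0) >= 2
    else:
        raise ValueError(f"unknown deletion rule {deletion!r}")
    analysed = int(analysed_cols.sum())
    p_bar = _mean_pairwise_p(m, ok)
    if analysed == 0:
        return LocusStats(locus_id, n, None, None, p_bar, degenerate=True)
    sub = m[:, analysed_cols]
    sub_ok = ok[:, analysed_cols]
    variable = 0
    for j in range(sub.shape[1]):
        states = set(sub[sub_ok[:, j], j])
        if len(states) > 1:
            variable += 1
    constant = analysed - variable
    counts = SiteCounts(aln.length, analysed, variable, constant)
    ratio = (variable / constant) / n if constant > 0 else None
    return LocusStats(locus_id, n, counts, ratio, p_bar)


def _mean_pairwise_p(m: np.ndarray, ok: np.ndarray) -> float | None:
    ps = []
    for i, j in combinations(range(m.shape[0]), 2):
        both = ok[i] & ok[j]
        compared = int(both.sum())
        if compared == 0:
            continue
        mism = int((m[i, both] != m[j, both]).sum())
        ps.append(mism / compared)
    return float(np.mean(ps)) if ps else None


def rank_and_select(stats: list, t_ratio: float | None = None,
                    t_p: float | None = None) -> SelectionReport:
    """Threshold selection with the strict-mean rule.

    Thresholds default to the arithmetic means of the defined loci; a locus
    qualifies iff it is strictly above both.  Output ranked by ratio
    descending, ties by p_bar then locus id.
    """
    defined = [s for s in stats if s.defined and s.p_bar is not None]
    if len(defined) < 2:
        raise ValueError("need at least 2 loci with defined statistics")
    if t_ratio is None:
        t_ratio = float(np.mean([s.ratio for s in defined]))
    if t_p is None:
        t_p = float(np.mean([s.p_bar for s in defined]))
    ranking = sorted(defined, key=lambda s: (-s.ratio, -s.p_bar, s.locus_id))
    selected = [s.locus_id for s in ranking
                if s.ratio > t_ratio and s.p_bar > t_p]
    return SelectionReport(stats=list(stats), t_ratio=t_ratio, t_p=t_p,
                           selected=selected,
                           ranking=[s.locus_id for s in ranking])


def concatenate_partitions(partitions: list, fill: str = "?",
                           count_gaps_as_missing: bool = False) -> Supermatrix:
    """Concatenate per-locus alignments into one supermatrix.

    ``partitions`` is a list of (locus_id, Alignment) pairs (bare Alignments
    get positional names).  Taxa become the union in order of first
    appearance; a taxon absent from a partition receives a fill block.  The
    missing fraction counts filled cells only, unless
    ``count_gaps_as_missing`` also counts pre-existing '-'/'?'/'N' cells.
    """
    named = []
    for k, p in enumerate(partitions):
        if isinstance(p, tuple):
            named.append(p)
        else:
            named.append((f"partition{k + 1}", p))
    taxa: list = []
    for _, aln in named:
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    if not taxa:
        raise ValueError("no taxa to concatenate")
    spans = []
    rows = {t: [] for t in taxa}
    filled = 0
    start = 0
    for name, aln in named:
        width = aln.length
        spans.append((name, (start, start + width)))
        start += width
        for t in taxa:
            if t in aln.taxa:
                rows[t].append(aln.row(t))
            else:
                rows[t].append(fill * width)
                filled += width
    matrix = Alignment(list(taxa), ["".join(rows[t]) for t in taxa])
    total = len(taxa) * matrix.length
    missing = filled
    if count_gaps_as_missing:
        m = _char_matrix(matrix)
        missing = int(np.isin(m, ["-", "?", "N"]).sum())
    return Supermatrix(list(taxa), spans, matrix, missing / total)


def pairwise_identity(aln: Alignment) -> np.ndarray:
    """Percent identity matrix.

    identity(i, j) = identical residue columns / columns where not both
    rows are gaps.  A gap against a residue counts as a mismatch; N matches
    nothing (N vs anything, including N, is a mismatch).  Symmetric with a
    diagonal of 100.
    """
    if len(aln) < 2:
        raise ValueError("identity needs at least 2 rows")
    m = _char_matrix(aln)
    gap = (m == "-") | (m == "?")
    resid = np.isin(m, list(UNAMBIGUOUS))
    n = m.shape[0]
    out = np.full((n, n), 100.0)
    for i, j in combinations(range(n), 2):
        compared = ~(gap[i] & gap[j])
        same = (m[i] == m[j]) & resid[i] & resid[j] & compared
        denom = int(compared.sum())
        out[i, j] = out[j, i] = 100.0 * int(same.sum()) / denom if denom else 100.0
    return out
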