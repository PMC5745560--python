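"""Non-coding locus extraction: introns and intergenic spacers (IGS).

Introns are the gaps between consecutive exons of one gene feature, named
``<gene>_intron<k>`` with k counted in the gene's reading direction.  IGS
are the maximal gaps between consecutive gene-level spans along the
(possibly circular) genome, named ``<geneA>-<geneB>`` by the flanking genes
in genomic order.  Features fully nested inside another gene are ignored
for IGS boundaries, and a locus duplicated by the inverted repeat is kept
once per genome (first occurrence by coordinate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from plastophylo.io import AnnotatedGenome, revcomp

__all__ = ["Region", "LocusSet", "extract_noncoding", "harvest_locus", "harvest_all"]

log = logging.getLogger(__name__)


@dataclass
class Region:
    """One extracted non-coding locus in one genome."""

    locus_id: str
    genome_id: str
    start: int  # 0-based half-open, genomic forward strand
    end: int    # may exceed genome length for a wrap-around IGS
    kind: str   # "intron" | "igs"
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class LocusSet:
    """Homologous sequences of one locus across genomes."""

    locus_id: str
    members: dict = field(default_factory=dict)  # genome_id -> sequence
    absent: list = field(default_factory=list)   # genome ids lacking the locus

    def __len__(self):
        return len(self.members)


def _gene_spans(genome: AnnotatedGenome):
    """Gene-level spans for IGS computation.

    One span per gene name (exon union), excluding trans-spliced features
    and features fully nested inside another gene's span.
    """
    spans = {}
    for f in genome.features:
        if f.non_extractable:
            continue
        s, e = f.span
        if f.name in spans:
            ps, pe = spans[f.name]
            spans[f.name] = (min(ps, s), max(pe, e))
        else:
            spans[f.name] = (s, e)
    items = sorted(spans.items(), key=lambda kv: kv[1])
    kept = []
    for name, (s, e) in items:
        nested = any(os <= s and e <= oe and (os, oe) != (s, e)
                     for _, (os, oe) in items)
        if nested:
            log.debug("gene %s nested within another span; ignored for IGS", name)
            continue
        kept.append((name, s, e))
    kept.sort(key=lambda t: (t[1], t[2]))
    return kept


def extract_noncoding(genome: AnnotatedGenome, kind: str) -> list:
    """Extract intron or IGS regions from one annotated genome.

    Zero-length gaps are omitted; overlapping genes produce a negative gap
    which is skipped with a logged warning.  For circular genomes the
    wrap-around IGS (last gene back to the first) is included once.
    """
    if kind == "intron":
        return _extract_introns(genome)
    if kind == "igs":
        return _extract_igs(genome)
    raise ValueError(f"unknown region kind {kind!r}")


def _extract_introns(genome: AnnotatedGenome) -> list:
    regions = []
    seen = set()
    for f in genome.features:
        if f.non_extractable or len(f.exons) < 2:
            continue
        gaps = []
        for (s1, e1), (s2, e2) in zip(f.exons, f.exons[1:]):
            if s2 > e1:
                gaps.append((e1, s2))
        if f.strand == -1:
            gaps = gaps[::-1]  # number introns 5'->3' in the gene direction
        for k, (s, e) in enumerate(gaps, 1):
            locus_id = f"{f.name}_intron{k}"
            if locus_id in seen:
                log.warning("%s: duplicated locus %s kept once", genome.id, locus_id)
                continue
            seen.add(locus_id)
            seq = genome.sequence[s:e]
            if f.strand == -1:
                seq = revcomp(seq)
            regions.append(Region(locus_id, genome.id, s, e, "intron", seq))
    return regions


def _extract_igs(genome: AnnotatedGenome) -> list:
    spans = _gene_spans(genome)
    if len(spans) < 2:
        raise ValueError("need at least 2 gene spans for IGS extraction")
    regions = []
    seen = set()
    n = len(genome.sequence)
    pairs = [(a, b, False) for a, b in zip(spans, spans[1:])]
    if genome.circular:
        pairs.append((spans[-1], spans[0], True))
    for (name_a, sa, ea), (name_b, sb, eb), wrap in pairs:
        start, end = ea, (sb + n if wrap else sb)
        if end < start:
            log.warning("%s: genes %s and %s overlap; IGS skipped",
                        genome.id, name_a, name_b)
            continue
        if end == start:
            continue
        locus_id = f"{name_a}-{name_b}"
        if locus_id in seen:
            log.warning("%s: duplicated locus %s kept once", genome.id, locus_id)
            continue
        seen.add(locus_id)
        regions.append(Region(locus_id, genome.id, start, end, "igs",
                              genome.slice(start, end)))
    return regions


def harvest_locus(genomes: list, locus_id: str) -> LocusSet:
    """Collect one locus across genomes.

    The locus name is matched in either flanking-gene orientation for IGS
    ("A-B" also matches a genome where the spacer was named "B-A"; the
    sequence is reverse-complemented to the requested orientation).
    Genomes lacking the locus are recorded as absent, never padded.
    """
    kind = "intron" if "_intron" in locus_id else "igs"
    flipped = None
    if kind == "igs" and "-" in locus_id:
        a, b = locus_id.split("-", 1)
        flipped = f"{b}-{a}"
    result = LocusSet(locus_id)
    for g in genomes:
        found = None
        for r in extract_noncoding(g, kind):
            if r.locus_id == locus_id:
                found = r.sequence
                break
            if flipped and r.locus_id == flipped and found is None:
                found = revcomp(r.sequence)
        if found is None:
            result.absent.append(g.id)
        else:
            result.members[g.id] = found
    if len(result.members) < 2:
        raise ValueError(
            f"locus {locus_id!r} present in {len(result.members)} genome(s); "
            "need at least 2 for statistics"
        )
    return result


def harvest_all(genomes: list, kind: str, min_members: int = 2) -> list:
    """All loci of a kind shared by at least ``min_members`` genomes."""
    ids = {}
    for g in genomes:
        for r in extract_noncoding(g, kind):
            ids.setdefault(r.locus_id, set()).add(g.id)
    out = []
    for locus_id, carriers in sorted(ids.items()):
        if len(carriers) >= min_members:
            out.append(harvest_locus(genomes, locus_id))
    return out
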