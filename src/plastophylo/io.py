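"""Readers and writers for the standard formats the toolkit touches.

GenBank flat files and FASTA go through biopython, newick through dendropy;
the NEXUS SPLITS block (the interchange format of split-graph viewers) is
written and re-read by a small dedicated serializer since no general-purpose
library covers it.  All coordinates are 0-based half-open internally;
reports print 1-based inclusive.
"""

from __future__ import annotations

import io as _stdio
import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO

from plastophylo.splits import Split, SplitSystem

__all__ = [
    "AnnotatedGenome",
    "GenomicFeature",
    "Alignment",
    "SequenceSet",
    "GenBankError",
    "NewickParseError",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "write_splits_nexus",
    "read_splits_nexus",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv-",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb-")

#: residues considered informative by the statistics modules; everything
#: else (N, IUPAC ambiguity, gaps) is treated as missing.
UNAMBIGUOUS = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenBankError(ValueError):
    pass


class NewickParseError(ValueError):
    def __init__(self, message, offset=None):
        super().__init__(message)
        self.offset = offset


@dataclass
class GenomicFeature:
    """A gene-level feature: one or more exons on one strand.

    Exon intervals are 0-based half-open on the forward strand, sorted by
    start.  ``non_extractable`` marks trans-spliced locations (mixed strands
    or out-of-order parts, e.g. rps12) which are kept for bookkeeping but
    excluded from region extraction.
    """

    name: str
    kind: str  # gene | tRNA | rRNA | CDS
    strand: int  # +1 / -1
    exons: list  # list of (start, end) tuples
    non_extractable: bool = False

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"feature {self.name!r} has no exons")
        self.exons = [tuple(e) for e in self.exons]
        if not self.non_extractable:
            self.exons.sort(key=lambda e: e[0])
            for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
                if s2 < e1:
                    raise ValueError(f"feature {self.name!r} has overlapping exons")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"feature {self.name!r} has an empty exon [{s},{e})")

    @property
    def span(self) -> tuple:
        """Gene-level interval: (min start, max end) over exons."""
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))


@dataclass
class AnnotatedGenome:
    """A (typically circular) plastid sequence with gene-level features."""

    id: str
    sequence: str
    circular: bool = True
    features: list = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty genome sequence")
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.exons:
                if s < 0 or e > n:
                    raise GenBankError(
                        f"feature {f.name!r} interval [{s},{e}) outside genome "
                        f"of length {n}"
                    )

    def __len__(self):
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Subsequence [start, end); ``end <= len + start`` may wrap the
        origin of a circular genome."""
        n = len(self.sequence)
        if end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise ValueError("interval beyond the end of a linear genome")
        return self.sequence[start:] + self.sequence[: end - n]


@dataclass
class Alignment:
    """Equal-length gapped sequences with unique taxon labels."""

    taxa: list
    rows: list

    is_alignment = True

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels in alignment")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self):
        return len(self.rows)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def subset_columns(self, start: int, end: int) -> "Alignment":
        return Alignment(list(self.taxa), [r[start:end] for r in self.rows])


@dataclass
class SequenceSet:
    """Unaligned sequences (records of unequal length)."""

    taxa: list
    rows: list

    is_alignment = False

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate labels in sequence set")


def _as_text(source) -> str:
    """Accept a path, a Path, an open handle, or raw text."""
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        if "\n" in source or source.lstrip().startswith((">", "#NEXUS", "(")):
            return source
        return Path(source).read_text()
    raise TypeError(f"cannot read from {type(source)}")


# ---------------------------------------------------------------------------
# GenBank

_FEATURE_KINDS = {"gene", "CDS", "tRNA", "rRNA"}


def read_genbank(source) -> AnnotatedGenome:
    """Parse a GenBank flat file into an :class:`AnnotatedGenome`.

    gene/CDS/tRNA/rRNA features are captured with strand and exon structure
    (``join(...)`` locations become multiple exons, converted from 1-based
    inclusive to 0-based half-open).  Trans-spliced locations (parts on
    mixed strands or in decreasing order) are flagged ``non_extractable``.
    """
    text = _as_text(source)
    try:
        record = SeqIO.read(_stdio.StringIO(text), "genbank")
    except Exception as exc:  # biopython raises plain ValueError subclasses
        raise GenBankError(f"malformed GenBank record: {exc}") from exc
    seq = str(record.seq).upper()
    if not seq:
        raise GenBankError(f"record {record.id!r} has no sequence")
    circular = record.annotations.get("topology", "linear") == "circular"
    features = []
    for feat in record.features:
        if feat.type not in _FEATURE_KINDS:
            continue
        name = (
            feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("locus_tag", [None])[0]
            or feat.type
        )
        try:
            parts = list(feat.location.parts)
            exons = [(int(p.start), int(p.end)) for p in parts]
            strands = {p.strand for p in parts}
        except Exception as exc:
            raise GenBankError(
                f"malformed location for feature {name!r}: {exc}"
            ) from exc
        trans = len(strands) > 1
        strand = -1 if feat.location.strand == -1 else 1
        # decreasing part order on the forward strand also marks trans-splicing
        fwd = sorted(exons, key=lambda e: e[0])
        if not trans and exons not in (fwd, fwd[::-1]):
            trans = True
        for s, e in exons:
            if s < 0 or e > len(seq):
                raise GenBankError(
                    f"feature {name!r} exceeds sequence length {len(seq)}"
                )
        features.append(
            GenomicFeature(name=name, kind=feat.type, strand=strand,
                           exons=fwd, non_extractable=trans)
        )
    return AnnotatedGenome(
        id=record.id or record.name, sequence=seq, circular=circular,
        features=features,
    )


def write_genbank(genome: AnnotatedGenome, path=None) -> str:
    """Serialize an :class:`AnnotatedGenome` as a GenBank flat file."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16].replace(" ", "_"),
        description="synthetic annotated plastome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
        },
    )
    for f in genome.features:
        parts = [SimpleLocation(s, e, strand=f.strand) for s, e in f.exons]
        if f.strand == -1 and len(parts) > 1:
            parts = parts[::-1]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        record.features.append(
            SeqFeature(loc, type=f.kind, qualifiers={"gene": [f.name]})
        )
    handle = _stdio.StringIO()
    SeqIO.write(record, handle, "genbank")
    text = handle.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source):
    """Read FASTA records; returns an :class:`Alignment` when all records
    have equal length, otherwise a :class:`SequenceSet`."""
    text = _as_text(source)
    taxa, rows = [], []
    for rec in SeqIO.parse(_stdio.StringIO(text), "fasta"):
        label = rec.description.strip() or rec.id
        if label in taxa:
            raise ValueError(f"duplicate FASTA label {label!r}")
        s = str(rec.seq).upper()
        if not s:
            raise ValueError(f"empty FASTA record {label!r}")
        taxa.append(label)
        rows.append(s)
    if not taxa:
        raise ValueError("no FASTA records found")
    if len({len(r) for r in rows}) == 1:
        return Alignment(taxa, rows)
    return SequenceSet(taxa, rows)


def write_fasta(obj, path=None, width: int = 70) -> str:
    """Serialize an Alignment/SequenceSet (or mapping label->seq) to FASTA."""
    if isinstance(obj, dict):
        items = list(obj.items())
    else:
        items = list(zip(obj.taxa, obj.rows))
    out = []
    for label, seq in items:
        out.append(f">{label}")
        for i in range(0, len(seq), width):
            out.append(seq[i : i + width])
    text = "\n".join(out) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Newick


def read_newick(source, unroot: bool = False) -> dendropy.Tree:
    """Parse a newick string into a dendropy Tree.

    Parse errors are re-raised as :class:`NewickParseError` carrying the
    character offset.  With ``unroot=True`` a degree-2 root is suppressed.
    """
    text = _as_text(source)
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at character {i}", offset=i
                )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced parentheses ({depth} unclosed)", offset=len(text)
        )
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        col = getattr(exc, "col_num", None)
        raise NewickParseError(
            f"newick parse error{f' at character {col}' if col else ''}: {exc}",
            offset=col,
        ) from exc
    if unroot:
        tree.is_rooted = False
        if len(tree.seed_node.child_nodes()) == 2:
            tree.collapse_basal_bifurcation()
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    text = tree.as_string(schema="newick", unquoted_underscores=True)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# NEXUS SPLITS block


def _quote_label(label: str) -> str:
    if re.search(r"[\s'()\[\]{}/\\,;:=*\"`+<>]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_splits_nexus(system: SplitSystem, path=None) -> str:
    """Serialize a split system as a NEXUS file with TAXA and SPLITS blocks
    (the format split-graph viewers read).  Each split is encoded by the
    1-based indices of the side containing the first taxon; weights keep 12
    significant digits."""
    if not system.splits:
        raise ValueError("cannot serialize an empty split system")
    taxa = list(system.taxa)
    idx = {t: i + 1 for i, t in enumerate(taxa)}
    lines = [
        "#NEXUS",
        "",
        "BEGIN TAXA;",
        f"    DIMENSIONS NTAX={len(taxa)};",
        "    TAXLABELS",
    ]
    lines += [f"        {_quote_label(t)}" for t in taxa]
    lines += [
        "    ;",
        "END;",
        "",
        "BEGIN SPLITS;",
        f"    DIMENSIONS NTAX={len(taxa)} NSPLITS={len(system.splits)};",
        "    FORMAT LABELS=NO WEIGHTS=YES;",
    ]
    if system.circular_order is not None:
        cyc = " ".join(str(idx[t]) for t in system.circular_order)
        lines.append(f"    CYCLE {cyc};")
    lines.append("    MATRIX")
    for k, s in enumerate(sorted(system.splits,
                                 key=lambda s: tuple(sorted(s.side))), 1):
        side = s.side if taxa[0] in s.side else frozenset(taxa) - s.side
        members = " ".join(str(idx[t]) for t in sorted(side, key=taxa.index))
        lines.append(f"        [{k}] {s.weight:.12g} {members},")
    lines += ["    ;", "END;", ""]
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


def read_splits_nexus(source) -> SplitSystem:
    """Re-read a NEXUS SPLITS file written by :func:`write_splits_nexus`."""
    text = _as_text(source)
    taxlabels_m = re.search(r"TAXLABELS(.*?);", text, re.S | re.I)
    if not taxlabels_m:
        raise ValueError("no TAXLABELS found")
    raw = taxlabels_m.group(1)
    taxa = [
        m.group(1).replace("''", "'") if m.group(1) is not None else m.group(2)
        for m in re.finditer(r"'((?:[^']|'')*)'|(\S+)", raw)
    ]
    cycle_m = re.search(r"CYCLE([^;]*);", text, re.I)
    order = None
    if cycle_m:
        order = tuple(taxa[int(i) - 1] for i in cycle_m.group(1).split())
    matrix_m = re.search(r"MATRIX(.*?);", text, re.S | re.I)
    if not matrix_m:
        raise ValueError("no SPLITS MATRIX found")
    splits = []
    for line in matrix_m.group(1).strip().splitlines():
        line = line.strip().rstrip(",")
        if not line:
            continue
        line = re.sub(r"^\[\d+\]\s*", "", line)
        parts = line.split()
        weight = float(parts[0])
        side = frozenset(taxa[int(i) - 1] for i in parts[1:])
        splits.append(Split(side, weight))
    return SplitSystem(tuple(taxa), splits, circular_order=order)
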