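"""Detection of small structural rearrangements in plastid loci.

Four detectors, all working on desk-scale sequences (<~30 kb):

* reverse-complement palindromes (maximal even-length substrings equal to
  their own reverse complement, optional central spacer),
* dispersed (non-tandem) duplications via maximal repeated substrings,
* local inversions relative to a homologous reference, found by k-mer seed
  chaining on the reverse strand,
* shared/unique indel events read off gap runs in an alignment.

Coordinates are 0-based half-open; default minimum lengths are anchored to
the event sizes typically reported for plastid spacers (palindrome 20,
duplication 15, inversion 20).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from plastophylo.io import revcomp

__all__ = [
    "RearrangementEvent",
    "find_palindromes",
    "find_duplications",
    "find_inversions",
    "gap_events",
]

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class RearrangementEvent:
    kind: str                 # palindrome|duplication|inversion|deletion|insertion
    intervals: list           # list of (start, end); one per occurrence/sequence
    length: int
    carriers: tuple = ()      # taxon labels (alignment-based events)
    sharing: str = ""         # unique | shared
    locus_id: str = ""

    @property
    def start(self):
        return self.intervals[0][0]

    @property
    def end(self):
        return self.intervals[0][1]


def find_palindromes(seq: str, min_len: int = 20, max_spacer: int = 0) -> list:
    """Maximal reverse-complement palindromes of total arm length >= min_len.

    A palindrome with spacer s has arms [c-a, c) and [c+s, c+s+a) with the
    left arm equal to the reverse complement of the right; the reported
    interval spans both arms (spacer included).  Each maximal extent is
    reported once.  N and ambiguity codes never pair.
    """
    seq = seq.upper()
    n = len(seq)
    events = []
    for spacer in range(0, max_spacer + 1):
        for c in range(1, n):  # c = start of the right arm minus spacer
            if c + spacer > n:
                break
            a = 0
            while (c - a - 1 >= 0 and c + spacer + a < n
                   and _COMP.get(seq[c - a - 1]) == seq[c + spacer + a]):
                a += 1
            if 2 * a >= min_len:
                events.append(
                    RearrangementEvent(
                        "palindrome",
                        [(c - a, c + spacer + a)],
                        2 * a + spacer,
                    )
                )
    # collapse events nested inside a longer one at the same locus
    events.sort(key=lambda e: (-(e.end - e.start), e.start))
    kept = []
    for e in events:
        if any(k.start <= e.start and e.end <= k.end for k in kept):
            continue
        kept.append(e)
    kept.sort(key=lambda e: e.start)
    return kept


def find_duplications(seq: str, min_len: int = 15, min_copies: int = 2) -> list:
    """Maximal repeated substrings occurring >= min_copies times with at
    least one non-adjacent (non-tandem) pair of occurrences.

    Seeds of length ``min_len`` are extended to maximal repeats; nested
    reports are collapsed into the maximal extent.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 2 * min_len:
        return []
    kmers = defaultdict(list)
    for i in range(n - min_len + 1):
        kmers[seq[i : i + min_len]].append(i)
    pairs = set()
    for positions in kmers.values():
        if len(positions) < 2:
            continue
        for x in range(len(positions) - 1):
            for y in range(x + 1, len(positions)):
                pairs.add((positions[x], positions[y]))
    # extend each seed pair to its maximal repeated match
    maximal = set()
    for i, j in sorted(pairs):
        li, lj, length = i, j, min_len
        while li > 0 and lj > 0 and lj - 1 > li and seq[li - 1] == seq[lj - 1]:
            li, lj = li - 1, lj - 1
            length += 1
        while (li + length < lj and lj + length < n
               and seq[li + length] == seq[lj + length]):
            length += 1
        maximal.add((li, lj, length))
    # group occurrences by repeated string
    families = defaultdict(set)
    for li, lj, length in maximal:
        s = seq[li : li + length]
        families[s].update({li, lj})
    # drop families nested in a longer family's occurrences
    events = []
    items = sorted(families.items(), key=lambda kv: -len(kv[0]))
    covered = []
    for s, occs in items:
        length = len(s)
        ivals = sorted((o, o + length) for o in occs)
        if all(any(cs <= a and b <= ce for cs, ce in covered) for a, b in ivals):
            continue
        if len(ivals) < min_copies:
            continue
        non_tandem = any(
            b1 < a2 for (a1, b1), (a2, b2) in zip(ivals, ivals[1:])
        ) or any(
            ivals[j][0] - ivals[i][1] > 0
            for i in range(len(ivals))
            for j in range(i + 1, len(ivals))
        )
        if not non_tandem:
            continue
        covered.extend(ivals)
        events.append(RearrangementEvent("duplication", ivals, length))
    events.sort(key=lambda e: e.start)
    return events


def _maximal_rc_matches(query: str, reference: str, k: int, min_len: int):
    """Maximal exact matches between query and revcomp(reference), reported
    in forward coordinates on both sequences."""
    rc = revcomp(reference)
    nq, nr = len(query), len(rc)
    seeds = defaultdict(list)
    for j in range(nr - k + 1):
        seeds[rc[j : j + k]].append(j)
    found = set()
    for i in range(nq - k + 1):
        for j in seeds.get(query[i : i + k], ()):
            qi, rj, length = i, j, k
            while qi > 0 and rj > 0 and query[qi - 1] == rc[rj - 1]:
                qi, rj, length = qi - 1, rj - 1, length + 1
            while (qi + length < nq and rj + length < nr
                   and query[qi + length] == rc[rj + length]):
                length += 1
            if length >= min_len:
                found.add((qi, rj, length))
    out = []
    for qi, rj, length in sorted(found):
        ref_start = nr - (rj + length)
        out.append(((qi, qi + length), (ref_start, ref_start + length)))
    return sorted(set(out))


def find_inversions(query: str, reference: str, min_len: int = 20,
                    k: int = 12) -> list:
    """Segments of the query matching the reference reverse strand but not
    the forward strand.

    Matches are seeded with k-mers against the reverse complement and
    extended to maximal length.  A match is reported as an inversion when
    the query and reference intervals overlap positionally (reciprocal
    overlap >= 50%, i.e. the segment sits at the homologous locus) and the
    forward-strand sequence differs there.  Both coordinate systems are
    reported: ``intervals[0]`` on the query, ``intervals[1]`` on the
    reference.
    """
    query, reference = query.upper(), reference.upper()
    events = []
    for (qs, qe), (rs, re_) in _maximal_rc_matches(query, reference, k, min_len):
        length = qe - qs
        overlap = min(qe, re_) - max(qs, rs)
        if overlap < 0.5 * length:
            continue  # dispersed inverted repeat, not a local inversion
        if query[qs:qe] == reference[qs:qe]:
            continue  # palindromic segment, identical on the forward strand
        events.append(RearrangementEvent("inversion", [(qs, qe), (rs, re_)],
                                         length))
    # keep maximal, de-duplicated events
    events.sort(key=lambda e: (-(e.length), e.start))
    kept = []
    for e in events:
        if any(k_.intervals[0][0] <= e.intervals[0][0]
               and e.intervals[0][1] <= k_.intervals[0][1] for k_ in kept):
            continue
        kept.append(e)
    kept.sort(key=lambda e: e.start)
    return kept


def gap_events(aln, min_len: int = 1) -> list:
    """Indel events from gap runs in an alignment (alignment coordinates).

    Maximal '-' runs identical in (start, length) across rows form one
    event; rows sharing the run are compared against the rest to polarize:
    if the gapped rows are the minority the event is a deletion carried by
    them, otherwise an insertion carried by the ungapped rows (ties count
    as deletions).  Requires >= 3 rows.
    """
    if len(aln) < 3:
        raise ValueError("need >= 3 rows to polarize shared vs unique events")
    runs = defaultdict(list)
    for taxon, row in zip(aln.taxa, aln.rows):
        i = 0
        while i < len(row):
            if row[i] == "-":
                j = i
                while j < len(row) and row[j] == "-":
                    j += 1
                if j - i >= min_len:
                    runs[(i, j)].append(taxon)
                i = j
            else:
                i += 1
    events = []
    n = len(aln)
    for (s, e), gapped in sorted(runs.items()):
        if len(gapped) <= n - len(gapped):
            kind, carriers = "deletion", tuple(gapped)
        else:
            kind = "insertion"
            carriers = tuple(t for t in aln.taxa if t not in gapped)
        events.append(
            RearrangementEvent(
                kind, [(s, e)], e - s, carriers=carriers,
                sharing="unique" if len(carriers) == 1 else "shared",
            )
        )
    return events
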