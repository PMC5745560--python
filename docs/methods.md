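# Methods

This note documents the models, statistics and numerical choices behind
`plastophylo`, and what the synthetic generators do and do not emulate.

## Coordinates and formats

All coordinates are 0-based half-open internally; CLI reports and partition
tables print 1-based inclusive.  GenBank and FASTA pass through biopython,
newick through dendropy.  The NEXUS SPLITS block is written by a dedicated
serializer (index-set encoding of the side containing the first taxon,
weights at 12 significant digits) because no general library emits it.
IUPAC ambiguity codes other than A/C/G/T are preserved on read but treated
as missing by every statistic; trans-spliced gene locations (parts on mixed
strands or out of order, e.g. rps12) are read but flagged non-extractable,
since such genes are never used as marker boundaries.

## Region extraction

Introns are the gaps between consecutive exons of one feature, numbered
5'→3' in the gene's reading direction and reverse-complemented for
minus-strand genes.  IGS are computed between *gene-level* spans (the exon
union of each named gene), matching the conventional `geneA-geneB` marker
names; features wholly nested inside another gene's span are excluded so
that nested tRNAs do not create spurious zero-length spacers.  Overlapping
genes produce a skipped spacer with a logged warning, never an exception.
On circular genomes the wrap-around spacer is emitted once.  A locus
duplicated by the inverted repeat is counted once per genome (first
occurrence by coordinate), avoiding double weight for identical copies.

## Variability statistics and marker selection

For a locus alignment with n sequences:

* normalized divergence ratio r = (V/C)/n, with V variable and C constant
  sites among the analysed columns;
* average uncorrected p-distance p̄ = mean over unordered pairs of
  (mismatches / pairwise-comparable sites).

Site classification uses complete deletion by default (columns containing
any gap, N or ambiguity are excluded), while p̄ always uses pairwise
deletion — the combination a practitioner gets from standard distance
software defaults; both are configurable.  C = 0 leaves r undefined
(reported as such, never ±inf); a locus with no analysed columns is flagged
degenerate rather than dropped silently.  Selection thresholds default to
the across-locus arithmetic means, and a locus qualifies only if strictly
above both (a locus equal to the mean carries no information about being
above it).  The shipped presets (IGS: r > 0.0023, p̄ > 0.0067; introns:
r > 0.0016, p̄ > 0.0042) are the screening references for plastid
non-coding loci at *Ilex*-like divergences.

Percent identity between aligned rows counts identical unambiguous-residue
columns over columns where not both rows are gaps; a gap against a residue
is a mismatch and N matches nothing.  Supermatrix assembly records per-
partition column spans; the missing fraction counts fill cells introduced
for absent taxa (optionally also pre-existing gaps, since published
missing-data figures do not always state which convention they used).

## Rearrangement scanning

Defaults are anchored to the event sizes seen in plastid spacer surveys:
palindromes ≥ 20 bp, duplications ≥ 15 bp, inversions ≥ 20 bp.

* Palindromes: maximal even-length substrings equal to their own reverse
  complement (optional central spacer); each maximal extent reported once,
  nested hits collapsed.
* Duplications: k-mer-seeded maximal repeated substrings with at least one
  non-adjacent pair of occurrences (tandem-only repeats are excluded);
  nested families collapse into the maximal extent.
* Inversions: k-mer seeds (k = 12) against the reverse complement of a
  homologous reference, extended to maximal exact matches; a match is an
  inversion when it sits at the homologous position (reciprocal overlap ≥
  50% between the query and reference intervals) and the forward strands
  differ there.  Full local alignment is unnecessary at the <3 kb locus
  scale this targets.  Against a *diverged* reference a flank substitution
  can shift a reported boundary by a base; exact-coordinate guarantees hold
  against the pre-event sequence.
* Indels: maximal gap runs in an alignment, grouped by identical
  (start, length) — the alignment itself encodes homology, so near-identical
  offsets are deliberately not merged.  Carriers holding the gap form a
  deletion when in the minority; when the gapped rows are the majority, the
  event is an insertion carried by the ungapped rows (ties count as
  deletions).  Polarization needs ≥ 3 rows.

## Neighbour-Net and fit statistics

The circular ordering is built by the canonical agglomeration: clusters are
paths of taxa with only the two endpoint nodes active; cluster pairs are
chosen by the neighbour-joining criterion on cluster-averaged distances,
the concrete endpoints by the same criterion over the candidate nodes, and
each 3-node path created by a join is reduced to two nodes with the
(2/3, 1/3) reduction.  Ties break toward the smallest index, making the
ordering deterministic.  Candidate splits are all n(n−1)/2 intervals of the
ordering; weights come from nonnegative least squares (active-set NNLS) on
the pair-separation design matrix; splits below 1e-6 of the mean weight are
dropped.  The "maximum dimensions" filter (default 4) greedily removes the
lowest-weight split participating in any set of more than four mutually
incompatible splits, found via cliques of the incompatibility graph.  On
tree metrics the output is exactly the tree's splits with branch-length
weights (verified against an independent reference implementation).

Fit statistics between observed distances d and split-induced distances p
(p_ij = sum of weights of splits separating i and j):

    fit   = 100 · (1 − Σ|d_ij − p_ij| / Σ d_ij)
    LSfit = 100 · (1 − Σ(d_ij − p_ij)² / Σ d_ij²)

over unordered pairs; both are 100 exactly when the representation is
exact, and undefined (flagged) for an all-zero matrix.  These are the
network literature's standard definitions, pinned here so tests are exact.
The equal-angle layout is visualization only and carries no contract.

## Z-closure supernetworks

Every branch of every input tree is a partial split on that tree's taxa.
The closure rule: for partial splits A1|B1 and A2|B2 with A1∩A2 ≠ ∅,
B1∩B2 ≠ ∅ and A1∩B2 = ∅, replace the pair by A1|B1∪B2 and A1∪A2|B2.  Full
splits are fixed points, so a single input tree returns exactly its own
splits and duplicated inputs change nothing.  The rule is applied until no
pair fires, independently for a number of seeded random pair orders
(default 10), and completed full splits are pooled.  A closed partial split
with a singleton side is completed by placing the missing taxa on the large
side (a pendant branch says nothing about where the absent taxa attach, so
they go opposite the single taxon).  A full split's weight is the mean
length of the input branches that produced it.  Trees that fail to connect
all taxa through shared leaves trigger a warning; unconnected taxa keep
trivial splits only.

## Mixed-matrix parsimony

Characters: DNA (with the gap as a fifth state when flagged; N/? missing),
binary, unordered multistate (the conservative default for morphology),
and continuous.  Each continuous character is linearly rescaled so its
observed range is exactly one step — a change between the two most
dissimilar observed states costs the same as one discrete step; zero-range
characters are excluded with a warning.  The dummy outgroup used for
polarization is all-'?' by default (it adds no steps) with an all-primitive
option.

Discrete characters are scored by unit-cost dynamic programming (Sankoff
with uniform costs), which equals Fitch optimization on binary trees and
stays exact on multifurcations.  Continuous characters use Farris interval
optimization (exact on binary trees); on multifurcating trees the package
switches to an exact dynamic program over the grid of observed values,
since sequential interval merging can undercount on stars.  Missing data
never forces steps.

Exact search is branch and bound: taxa enter in max–min distance order
(ties lexicographic), the initial bound comes from greedy stepwise
addition, and a partial tree is pruned when its score exceeds the bound
(parsimony length is monotone under taxon addition).  All most-parsimonious
trees are collected; more than 14 taxa are refused — heuristic search is
out of scope.  CI = Σm_i / S and RI = (Σg_i − S)/(Σg_i − Σm_i) with m_i the
per-character minimum (states − 1; observed range for continuous) and g_i
the star-tree maximum (non-missing count minus the modal state count;
absolute deviations from the median for continuous).  CI is undefined at
S = 0 and reported as such.

Support: bootstrap resamples characters with replacement; jackknife deletes
each character independently with probability p (default 0.36 ≈ e^−1, the
probability that a character is absent from a bootstrap pseudoreplicate,
which makes the two schemes comparable); continuous characters resample
as single units.  A clade's support is the percentage of replicates whose
strict consensus of MP trees contains it; an empty replicate contributes to
the denominator only.

Synapomorphy mapping roots the tree at the designated outgroup and
computes, per character, the set of states each node attains across *all*
most-parsimonious reconstructions (marginal sets from an up/down dynamic
program — equivalent to the ACCTRAN∩DELTRAN intersection where that
applies, but exact in general).  A branch change is non-ambiguous iff the
parent and child sets are disjoint singletons; disjoint non-singleton sets
mean a change certainly occurs but its states vary, and such entries are
flagged ambiguous.  Continuous characters report the guaranteed direction
and the minimal magnitude (the gap between the marginal optimal intervals),
computed on the same grid dynamic program.

## Synthetic data: what it does and does not emulate

Genomes evolve site-independently (JC, K2P or HKY) along a known tree from
a 20 kb, 12-gene template (two multi-exon genes) with realistic plastid
gene names — a desk-scale proxy keeping run times in seconds.  No indels
are simulated except explicitly injected events, so every genome shares the
template coordinates and ground truth is exact.  The default two-species
divergence is 0.0099 expected p-distance, the value at which two plastomes
show ~99.01% pairwise identity — the regime of congeneric plastome
comparisons this toolkit targets.  Injected events adjust flanking bases so
that a detector's maximal extension cannot overrun the injected footprint;
without this, ground-truth coordinates would be off by chance matches in
roughly half of fixtures.  Mixed matrices plant one state change per
character on an internal branch (optionally cycling over all branches so
the generating tree is the unique MP tree), with a homoplasy rate adding
extra flips.

Passing tests on these fixtures show the algorithms are correct under
their stated models; they do not show robustness to alignment error,
rate heterogeneity across lineages, IR boundary shifts, or the quadripartite
architecture of real plastomes (not modeled).

## Known limitations

* Alignment construction is out of scope; the toolkit consumes aligned
  FASTA (simulated loci are alignment-free by construction).
* Inversion detection assumes positional homology (coordinate overlap);
  large-scale synteny analysis is explicitly not attempted.
* Exact parsimony is limited to 14 taxa; resampling cost grows linearly in
  replicates times the per-replicate search.
* The acceptance script sizes problems for a single CPU: 100 tree metrics
  (n = 5–12), 20 six-taxon oracle matrices, a 10-species mixed matrix with
  33 non-molecular characters, 1000 jackknife replicates, 20 kb genomes.
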