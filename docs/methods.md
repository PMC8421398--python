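# Methods

## Scope and model

cladeforge implements the computational layer of a phylum-scale MAG
comparison: subgroup delineation on a rooted species tree, marker-based
genome quality, gene-family occurrence and event accounting over
reconciliation output, and [FeFe]-hydrogenase locus characterization. Tree
inference, orthology inference, reconciliation sampling and database
annotation are upstream tools whose outputs this package consumes.

## Trees and supports

Trees are Newick with branch lengths in substitutions per site. Internal
node labels of the form `x/y` carry two supports; because IQ-Tree's label
order depends on how bootstrap and SH-aLRT were requested, the order is an
explicit parameter (`ufboot_first`, default false, i.e. labels read
SH-aLRT/UFBOOT as written by `-bb 1000 -alrt 1000`). Zero-length and
missing branch lengths are accepted with a warning (both are common in MAG
trees); negative lengths are rejected. Polytomies are allowed everywhere.
Rooting by outgroup places the root at the midpoint of the branch
separating a monophyletic outgroup from the rest; total tree length and
all leaf path distances are conserved to 1e-9. Trees whose root has more
than two children are treated as unrooted and rejected by the ultrametric
converter with a pointer to the rooting function; a genuinely rooted basal
polytomy can be expressed by resolving it with a zero-length branch.

## Ultrametric conversion and RED

The ultrametric converter uses mean-path-length (MPL) smoothing: each
node's age is its mean distance to descendant leaves, followed by a
top-down clamp `age(n) <- min(age(n), age(parent))` that guarantees exact
ultrametricity and nonnegative branches. MPL was chosen because it is
deterministic, parameter-free, and hand-checkable; no rate model or
calibration enters. Depth normalization divides all branches by the
root-to-tip depth, making the stem-length threshold scale-free.

RED follows the standard interpolation: `RED(n) = p + (d/u)(1-p)` with
p the parent's RED, d the stem, and u the mean parent-to-leaf distance
through n; root 0, leaves 1, evaluated in preorder. A subtree with u = 0
(all zero branches) inherits its parent's RED with a warning. RED is
computed on the original rooted tree by default, matching common practice
of evaluating divergence on the inferred (non-ultrametric) branch lengths;
a flag computes it on the ultrametric copy instead. On any unit-depth
ultrametric tree the recursion collapses to RED = depth, which the tests
exploit as a closed-form oracle alongside an independent naive recursion.

## Subgroup delineation

A node qualifies iff it is internal, both supports are present and pass
(UFBOOT >= 95, SH-aLRT >= 80), its RED strictly exceeds 0.4 (or a
per-clade override, e.g. 0.3 for a deep-rooted lineage, keyed by an anchor
leaf set so the exception is declarative rather than post-hoc), and its
stem on the depth-normalized ultrametric tree strictly exceeds 0.4.
Support gates are non-strict and RED/stem gates strict, mirroring the
wording "well supported (>=)" versus "exceeded". Selection is maximal
(shallowest qualifying node wins), which guarantees disjoint subgroups.
The stem criterion applies to the subgroup MRCA's stem only. Strict
comparisons carry a 1e-12 guard so binary representation noise cannot
promote a value exactly at a threshold; real margins are orders of
magnitude larger. Both RED and stems are evaluated on the full
outgroup-rooted tree with outgroup leaves marked: clades containing
outgroup leaves are never candidates, and the ingroup root (whose RED and
stem are well defined on that tree) may itself qualify. Labels A, B, C...
follow preorder with children visited by smallest descendant leaf name —
deterministic, though not recoverable from any figure layout.

## Genome quality

The marker matrix holds integer copy counts over a predefined marker set.
Refinement drops markers absent from every genome (uninformative for the
lineage; the default simulation mirrors a 148-marker archaeal set losing 5
markers). Completeness is the percentage of markers present;
contamination counts extra copies per marker. This flat-list estimator is
a deliberate simplification of collocated-marker-set algorithms such as
CheckM's: it is fully specified, unbiased for completeness under
independent marker recovery, and sufficient for gating. Both gates used
downstream are explicit about strictness: the lineage screen is
completeness >= 50% and contamination <= 10%; the reconciliation subset
uses > 79% and < 5%.

## Gene families

Occupancy and size filters operate on a genomes-by-families count matrix:
families with fewer than 4 total sequences are dropped before tree-aware
analyses; single-copy orthologs are families present in at least
ceil(0.85 x genomes) genomes and single-copy everywhere outside an
explicit allow-list. Occurrence per subgroup is the percentage of member
genomes carrying the family (presence = count >= 1), over the subgroup's
total size.

Medoid selection scores all pairs by global alignment under BLOSUM62 with
gap open -11 and extension -1, normalizes to
`d(a,b) = 1 - S(a,b)/max(S(a,a), S(b,b))`, and returns the sequence
minimizing the distance sum, ties broken lexicographically. Only "under
BLOSUM62" is externally fixed; the gap penalties (BLAST defaults for
BLOSUM62) and the normalization are configurable, and any monotone
transform of the scores preserves the argmin when self-scores are equal.
COG-category compositions split multi-letter categories fractionally so
the composition always sums to 1; unannotated families count as NA.

## Reconciliation events

Reconciliation output is a per-family, per-branch table of expected
frequencies for duplications, transfers (within the sampled genomes),
losses and originations (arrivals from unsampled lineages or de novo),
plus expected copies per node. Two dialects are parsed: a simple
long-format TSV and ALE-1.0-style uml_rec branch tables (one family per
file). An event is counted iff its frequency is strictly over tau
(default 0.3), the reading of "frequency over 0.3"; an `inclusive` flag
gives the >= reading, and the same choice applies to copies. Gains on a
branch are D + T + O — printed origination and transfer shares that sum
below 100% imply the third, duplication component. Shares are reported to
the nearest percent and are NA on branches without gains.

## [FeFe]-hydrogenase loci

A locus is `A3_trimeric` iff an H-cluster (catalytic) gene has both a
nuoF-like and a nuoE-like gene within at most one intervening gene on the
same strand; an H-cluster gene without that context is `A_untyped`, and
anything else `not_fefe`. The adjacency window and strand requirement are
parameters: operon organizations are published graphically, not as a
numeric rule, so the rule here is the package's own formalization, chosen
to be invariant under reversing gene order with strand flip. Motif
profiles are per-column empirical residue frequencies (20 amino acids plus
gap) over reference-anchored column windows supplied by the user —
alignment coordinates are never hard-coded. Conservation against
references requires identity with every reference at the column. Residues
are classed by the Kyte–Doolittle hydropathy index (> +0.5 hydrophobic,
< -0.5 hydrophilic, neutral between; scale and thresholds configurable).
Catalytic-site checks require cysteine at every listed column.

## Synthetic data

Each generator draws from its own named stream derived from one seed
(`SeedSequence(seed, spawn_key)`), so outputs are byte-reproducible and
adding a generator never perturbs another. Defaults emulate the target
study's shape: 150 grouped ingroup leaves in 10 subgroups plus 2
ungrouped, a 30-leaf outgroup; 148 markers with 5 absent lineage-wide and
genome completeness uniform on 50–98%; 4562 families comprising
subgroup-enriched families (p_in 0.8 vs p_out 0.1), a 109-family
high-occupancy single-copy core, and exponential-tailed background
presence (mean 0.04) giving the rare-family-heavy size distribution of
real pangenomes; 2320 reconciled families; operons dominated by trimeric
loci; motif alignments mutated at 10% per site with catalytic cysteines
spared (purifying selection).

Two constructions make recovery tests exact rather than statistical.
Trees are built unit-depth ultrametric with planted crowns at depth =
target RED and backbone nodes at depth <= 0.3, so RED targets hold exactly
and non-subgroup nodes can never pass the 0.4 gate. Reconciliation
frequencies are separated by truncation: planted events get
`1 - |N(0, 0.1)|` clipped above tau + 0.05 and non-events noise clipped
below tau - 0.05, so thresholding at tau reproduces the planted counts
exactly. Marker simulation uses common random numbers across
contamination levels, making estimated contamination monotone in the
duplication rate by construction.

What the generator does not emulate: phylogenetic signal in sequences
(branch supports are planted, not estimated), correlated marker loss,
compositional biases, chimeric bins, alignment error, or reconciliation
model misfit. Passing recovery tests therefore demonstrates that the
computations are correct under their stated models, not that the upstream
inference steps are robust on real data.

## Verification problem sizes

The test suite and `scripts/acceptance.py` use: 100 seeded random trees
(9–60 leaves, log-normal length jitter) for the RED oracle; 50 planted
trees (5 clades, 36 grouped leaves, 2 outliers) for delineation recovery;
200 genomes for quality recovery (mean bias within 2 binomial standard
errors); 50 tables of 40 families x 15 branches for the reconciliation
round trip; 20 families of 3–10 random proteins (25–45 residues) for the
medoid cross-check against an independent Gotoh aligner; and 10
operon/motif replicates. The analysis drivers run the full study-scale
configuration. These sizes were chosen so each check has clear power while
the whole suite stays interactive.

## Known limitations

The quality estimator ignores marker collocation and lineage-specific
marker selection; RED on non-ultrametric trees depends on inferred branch
lengths and is not comparable across trees without a shared normalization;
the delineation label order is a package convention; the uml_rec parser
covers the branch-table section only; and the A3 classifier depends on
correct upstream domain labels — it does not detect domains itself.
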