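# Methods

This note documents the models and conventions implemented in `v4clades`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical edge cases.

## ASVs and read filtering

An amplicon single variant (ASV) is the representative of a set of
*strictly identical* reads: dereplication is exact string collapse after
normalization (uppercase, U→T, gaps removed), with no denoising, chimera
removal or clustering. Upstream artifact removal is assumed to have
happened in the producing pipeline; the only read-level filters applied
here are the survey's: reads containing an ambiguity (N) are removed, and
the length filter keeps reads *strictly longer* than 300 bp (a 300-bp read
is removed, a 301-bp read kept). An optional stricter mode removes any
IUPAC ambiguity code; the default removes N only. Every filtering
operation logs counts before and after, and read totals are conserved at
every stage (an internal assertion, not a convention).

ASV identifiers are `ASV_<dataset>_<rank>` with rank by descending total
reads and ties broken by sequence lexicographic order, so tables are
reproducible bit-for-bit.

Two thresholds are printed inconsistently in the literature this workflow
serves ("more than 200" vs "at least 200" reads; "more than 100" vs "at
least 100" group reads per sample). Both floors are implemented
*inclusive* (≥ 200, ≥ 100) and both are configurable
(`PipelineConfig.min_asv_reads`, `.min_sample_group_reads`).

Cross-dataset confirmation treats a major ASV as validated when the second,
independently processed dataset contains a *strictly identical* sequence
(`exact` mode, the default). Because two pipelines may trim amplicons
differently, a `containment` mode (substring in either direction) is also
provided; it is never the default.

## Diagnostic signatures

A (column, character) pair is a *strict* signature of clade C when every
member of C carries the character at that column and no member of any
other clade does. "Carries" is IUPAC-aware: a reference sequence with an
ambiguity code compatible with the candidate character counts as carrying
it, on both sides of the rule. This is the conservative reading — an
ambiguous reference can only suppress diagnostics, never create them. The
gap character is a legitimate diagnostic state by default (indel signatures
are real in V4 alignments) and can be disabled. A `majority` mode relaxes
the within-clade requirement to a configurable fraction while still
demanding zero carriers outside; it exists for noisy reference sets and is
not used by the default pipeline.

Classification demands that a query match *all* of a clade's signature
positions (`min_match_fraction = 1.0`): the clades this workflow targets
have few, fully fixed signatures, and a single mismatched diagnostic
position is grounds for doubt. Ties between clades are reported as
`ambiguous` and never broken — two clades 2 bp apart deserve caution, not a
tiebreak. Queries matching no clade at the required fraction are
`unassigned`.

## Identity and OTU lumping

Percent identity is computed over aligned sequences in two conventions:
`all_columns` (gaps compared like characters, denominator = alignment
length) and `ungapped_pair_columns` (columns where either sequence is
gapped are excluded from numerator and denominator; the default, the
common metabarcoding convention). Reports round half-up to one decimal
(99.35 → 99.4); full precision is kept internally and used for all
comparisons. A pair with no gap-free shared column is an error, not a 0 or
100.

The lumping rule is single linkage: clades A and B are indistinguishable at
OTU threshold *t* when *any* cross-pair of their sequences has identity
≥ *t*, mirroring the behaviour of greedy OTU clustering. Lumped-pair sets
are monotone in the threshold by construction. Within-clade statistics for
singleton clades are reported absent (`None`), never zero.

## Clade criteria and trees

Monophyly is defined on unrooted trees: a leaf set is monophyletic iff some
edge bipartition separates exactly that set from the rest. Rooted newick
input is handled transparently (the two edges of a bifurcating root
represent one unrooted edge; a support annotated on either side belongs to
that bipartition, with the members' own side preferred when both carry
numbers).

A candidate clade *passes* when it is monophyletic in both trees and the ML
tree's defining edge has bootstrap support strictly greater than
`min_bootstrap` (default 70; support exactly 70 fails). The support floor
applies to the ML tree only — no posterior threshold is imposed on the
Bayesian tree beyond monophyly, though an optional `min_posterior` is
exposed. Support scales (0–100 bootstrap vs 0–1 posterior) are declared
per tree by the caller; the parser preserves the stored numbers.

The neighbor-joining builder exists so the criteria can be exercised
end-to-end without external inference software. It is the standard
agglomerative algorithm; Q-matrix ties are broken by the lexicographically
smallest pair of cluster representative labels (the smallest leaf label in
each cluster), making output deterministic. Branch lengths are not clamped
at zero, so additive input matrices are reproduced exactly (path-length
equality); the final three clusters join at a trifurcating seed node and
the tree is emitted unrooted, without supports.

## Biogeography

Abundances are percentages of the per-sample *group* total (all
Mamiellophyceae-like reads), not of the ASV subset, so the values match
what a survey reports per station; when computed over the full group the
per-sample column sums are 100% (asserted to 1e-9 relative). Samples below
the 100-group-read floor are excluded before any percentage is formed; a
retained sample with a zero group total is an error.

Presence uses the 1% rule with the boundary counted present (a taxon at
exactly 1.0% is present; "lower than 1%" is absent). When several ASVs
belong to one species/clade they are pooled *before* thresholding
(`pool_by_taxon`), matching how multi-ASV taxa are summarized in practice.

Latitude bands fold the hemispheres (absolute latitude) and use
conventional oceanographic edges — polar ≥ 66.5°, subpolar ≥ 55°,
temperate ≥ 35°, tropical below. These numeric edges are this package's
choice; the band *names* are standard but no published table defines their
cut-offs. Mediterranean-Sea and lagoon flags are taken from metadata
columns only and never inferred from coordinates.

## Primer screening

Oligo binding is modelled as ungapped sliding-window placement: the oligo
is compared at every offset of the sense target (or of its reverse
complement for the reverse primer), degenerate positions match when the
IUPAC base sets intersect (permissive: degenerate-vs-degenerate counts as
a match if any concrete pairing is compatible), and the reported site
minimizes mismatches with ties going leftmost. No indels and no
thermodynamics — this is a mismatch census, not a binding-energy model,
and the limitation is deliberate. Mismatch positions are 1-based from the
oligo 5′ end; any mismatch within the 3′-terminal window (default 3
bases, configurable) raises a separate flag because such mismatches are
the most likely to abolish amplification. The hydrolysis probe is tried on
both strands and the better orientation is reported, since probes may be
designed on either. An oligo longer than its target is reported as
"binding site not found" with absent counts rather than an error at the
set level.

The canonical mismatch pattern this module targets — a novel clade with
one forward (3′-terminal), one probe and two reverse mismatches against an
assay designed for its sisters — is exercised on constructed synthetic
sequences; the historical assay oligos and environmental target sequences
are not distributed with the package.

## Synthetic data

The generator produces the structure the analysis assumes, with planted
truth for recovery tests:

* **Reference clades** (`gen_reference_clades`; defaults k = 5, 341
  columns, 2 diagnostic columns per clade, 3 members, 1 private variant
  per non-prototype member): each clade's diagnostic columns are strictly
  exclusive *by construction*, and intra-clade variation sits at globally
  unique non-diagnostic columns so the planted positions are exactly the
  strictly diagnostic ones. For k = 2 the non-focal clade is made
  polymorphic at focal diagnostic columns to prevent mirror signatures;
  for k ≥ 3 the shared consensus base is kept fixed instead, preserving
  the clades' phylogenetic coherence (within-clade distances stay below
  between-clade distances). Clades need at least two members: with
  singletons, private variant columns would themselves be strict
  signatures and the planted truth would be wrong. The default alignment
  length and clade count echo the scale of a five-clade V4 analysis; the
  alignment is generated ungapped so read and alignment coordinates
  coincide.
* **Samples** (`gen_samples`; defaults 100 stations, latitudes uniform in
  ±75°, mean depth 5000 group reads): each clade occupies one latitude
  band with occupancy probability 0.9; within a station the composition of
  occupying clades is Dirichlet with concentration 0.3, so one or two
  clades dominate — clades rarely co-occur, as observed in coastal
  surveys. Rectangular band niches are the simplest structure that
  exercises the habitat summary; real niches are smooth in several
  variables.
* **Reads** (`gen_reads`): two datasets are drawn from the *same* true
  haplotypes with independent count and error draws, emulating one water
  sample processed by two independent pipelines. Errors are independent
  per-base substitutions (each base flips with probability `error_rate` to
  a uniform other base); there are no indels, no chimeras and no primer
  bias — substitution-only errors keep the spurious-ASV space enumerable,
  and at any realistic error rate spurious variants are almost all
  singletons, which is exactly the property the 200-read major-ASV floor
  exploits. Realized per-sample clade and haplotype counts are returned as
  ground truth, so error-free recovery tests can assert exact equality
  rather than statistical closeness.

All generators are deterministic given their seed.

What passing the recovery tests shows — and what it does not: the pipeline
recovers planted clade counts, compositions and prevalences exactly at
error 0 and degrades gracefully at 1% per-base error *under this error
model*. Real amplicon data add chimeras, indel errors, primer bias and
copy-number variation, none of which the generator emulates; performance
on those axes is out of scope here.

## Problem sizes and tolerances

The test suite runs the full survey scale (100 stations × 5000 reads, two
datasets, ≈10⁶ reads at the error-rate settings) once per property; random
tree suites use 100 trees of up to 8 leaves (monophyly vs brute-force
bipartition enumeration) and 100 five-leaf additive matrices (NJ
path-length equality at 1e-9). The graceful-degradation bound — mean
absolute composition error below 0.05 at 1% error — comes from the
binomial sampling noise of the surviving error-free reads (~3% of reads at
e = 0.01, 341 bp), not from tuning. Exact integer checks (read sums,
ASV counts) use no tolerance at all.

## Known limitations

* Signature discovery is combinatorial over single columns; correlated
  multi-column signatures and probabilistic/entropy scoring are out of
  scope.
* The NJ builder is for self-contained testing, not inference: no
  bootstrap, no model corrections (distances are used as given).
* OTU lumping reasons from the identity matrix; it does not re-cluster
  reads.
* Queries must already be aligned to the reference coordinate system;
  alignment construction is external.
* The published-table module ships read counts and taxon labels only — the
  printed table carries no sequences, so its `AsvTable` uses deterministic
  placeholder sequences, which is sufficient for read-count arithmetic and
  nothing else.
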