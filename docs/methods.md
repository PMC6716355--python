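# Methods

This note documents the models, procedures and numerical choices behind
`casecomm`, and what the synthetic benchmark does and does not establish.

## Study design and the contamination model

The generator (`casecomm.synthetic`) emulates a mushroom-cultivation
sampling design: 150 libraries over six stages (I–III, V–VII), three casing
treatments (normal 90, no-casing 24, sterilized 36) and up to four
compartments (casing soil, upper/lower substrate, fruit body), six
replicates each.  Stage-II libraries (sterilised substrate before
inoculation, normal treatment) are the negative controls — biologically
they should be sterile, so whatever amplifies in them defines the
contaminant background.

Communities are modelled at the genus scale: each (stage, compartment) has
a fixed expected profile over `n_taxa` (default 50) taxa.  The dominant
*Burkholderia*-like taxon follows the casing-soil trajectory
11.95% → 55.79% → 35.14% → 45.60% (stages I, V, VI, VII); in other
compartments it sits at 30%.  The remaining mass is a seeded symmetric
Dirichlet draw (total concentration 200, a free parameter — replicate
variability between profiles is not separately modelled; within-stage
replicate variation comes from the multinomial read draw only).

Contamination follows a reagent model: one contaminant profile (10
genotypes, Dirichlet(5) weights) shared by *all* libraries.  Experimental
libraries mix it at `contamination_fraction` (default 2%) scaled by a
per-sample lognormal load factor (σ = 0.3); negative controls draw from the
contaminant profile alone.  Noise sequences are sample-private, with
expected relative abundance `noise_fraction / n_noise_per_sample`
(default 0.0003/6 = 0.005%), so at the default depth range
(20,000–40,000 reads, echoing per-library totals in the tens of thousands)
they appear as singletons/doubletons.  These choices make decontamination
*recoverable by design*: each contaminant's relative abundance in any
experimental library stays far below one tenth of its abundance in the
controls, and noise sits far below the 0.1% floor.

Sequences are random 250-mers with ≥ 5% enforced pairwise divergence
between taxa, so 97% clustering should recover taxa exactly.  The FASTQ
writer emits 150-bp mates (barcode + primer prefixes, phred+33, constant
Q38) whose trimmed reads overlap by 50 bp; with `error_rate=0` the intake
pipeline reconstructs the input count table exactly, which is tested.

## Read processing

Demultiplexing is exact-match on both mates (6-bp barcode + primer; the
forward mate is canonical for sample assignment).  Merging scans all
overlaps ≥ 10 bp between the 3′ end of mate 1 and the reverse complement of
mate 2, requires ≥ 90% identity (a guard against spurious merges; the
minimum-overlap rule alone does not constrain identity), picks the overlap
with the most matches (ties → longer), resolves mismatches by the
higher-quality base (mate 1 on ties) and takes the column-wise maximum
quality.  The quality filter removes reads shorter than 200 bp, with any
ambiguous base, or with mean quality ≤ 30.  The mean-Q30 removal rule is
implemented verbatim as specified for this analysis even though it is
strict by common standards; both thresholds are configurable
(`min_length`, `min_mean_quality`).

## The decontamination procedure

Within one iteration, on the current table: (1) a unique sequence is kept
only if some experimental library carries it at ≥ `control_ratio` (10)
times its maximum relative abundance across negative controls — sequences
absent from every control are kept if present in any experimental library;
(2) relative abundances are recomputed on the reduced (post-step-1)
libraries and sequences below `min_relabund` (0.1%) in every experimental
library are removed; (3) samples retaining < 25% of their *starting* (pre-
procedure) reads are discarded — the boundary case (exactly 25% retained)
is kept, since only strictly "over 75% filtered" is discarded.  Steps 1–3
repeat until a full pass removes nothing.  Controls never count as
experimental libraries in steps 1–2 but are themselves subject to step 3 —
in practice they lose essentially all reads in step 1 and drop out in the
first iteration.

Decisions where the procedure's text is silent:

- step 2 uses post-step-1 (current) library sizes; `step2_on_current=False`
  switches to iteration-start sizes;
- abundance thresholds are inclusive (≥, "at least"), the step-3 discard is
  strict (>, "over");
- samples discarded by step 3 stop contributing to every later
  relative-abundance maximum;
- a table without controls is accepted with a warning, step 1 degenerating
  to a presence filter.  This keeps the procedure idempotent — its own
  output usually contains no controls — which is a tested law, along with
  monotone shrinkage and equivalence to an independently written
  brute-force reference on small random tables.

## OTUs and rarefaction

Clustering is greedy abundance-sorted centroid clustering: sequences in
decreasing total-count order (ties by sequence string, making the result
independent of input order) join the first centroid at ≥ 97% identity or
found a new OTU.  Identity is global Needleman–Wunsch (match +1, mismatch
−1, gap −2, Biopython's aligner) counted as matches over alignment columns
excluding terminal gaps.  This is a deterministic stand-in for unspecified
pipeline clustering; equivalence with any particular external tool is not
claimed.  Rarefaction is a seeded multivariate hypergeometric draw (without
replacement) to a common depth (default 7,096 reads) applied *after*
clustering, to the OTU table; samples below depth are dropped with a
warning.

## Diversity, ordination, tests

Shannon uses the natural log (configurable base); ACE uses the standard
abundance-based coverage estimator with rare cutoff 10, falling back to
observed richness when no taxon is rare and to Chao1 when every rare taxon
is a singleton.  Group contrasts are two-sided Welch *t*-tests (the
*t*-variant is unspecified in the field description; Welch is the safer
default) with Benjamini–Hochberg adjustment across pairwise contrasts,
replacing letter displays with a reproducible table.

Ordination Hellinger-transforms counts (square root of relative abundances;
rows then have unit L2 norm, making Bray–Curtis depth-invariant), computes
Bray–Curtis dissimilarities, and embeds them by NMDS: Kruskal stress-1,
`sqrt(Σ(d − d̂)² / Σ d²)`, with disparities d̂ from pool-adjacent-violators
monotone regression (primary treatment of ties — pairs stably sorted by
observed dissimilarity, PAV averaging within tied blocks), configurations
updated by Guttman-transform (SMACOF) steps.  Start 0 is classical scaling;
the remaining starts (default 20) are seeded random configurations;
convergence is a relative stress change < 1e−7 or 500 iterations, and the
lowest-stress start is reported together with its per-iteration trace and a
convergence flag (non-convergence is reported, not fatal).  ANOSIM is the
rank-based R = (mean between-group rank − mean within-group rank)/(M/2)
with midranks, and p = (1 + #{R_perm ≥ R_obs})/(1 + n_perm) over label
permutations (default 999).  Both are cross-checked against scikit-bio in
the tests; type-I error of Welch, Kruskal–Wallis and ANOSIM is verified by
null Monte-Carlo.

## Biomarker scoring

Features are scaled per-million per sample so scores land on the familiar
log10 scale where the 4.0 threshold is meaningful.  A Kruskal–Wallis screen
(midrank H, chi-square p) excludes features at p ≥ α (0.05); survivors are
scored over 30 bootstraps (2/3 of each class, at least 2 samples): per
class pair, the discriminant direction w solves `(S_w + εI) w = Δμ`
(pooled within-class covariance, ε = 1e−6), loadings are rescaled to
`max |w_f| = 1`, and a feature's effect is
`(|w_f·Δμ_f| + |Δμ_f|) / 2` — its discriminant-weighted *own* contribution
to the projected separation averaged with its raw mean difference.  The
score is `log10(mean bootstrap effect, floored at 1)`; multi-class scores
take the maximum over class pairs, and the enriched class is the one with
the highest mean abundance.  Using the feature's own contribution rather
than the full projected separation keeps each feature's effect bounded by
its raw difference; with few samples and many features the covariance solve
is near-singular, and an unbounded projection term lets strong markers leak
effect into unrelated features.  No subclass (within-class) stage is
applied — the emulated design has none.

The planted-marker benchmark plants one 20-fold-enriched marker per class
(equal base weights, so closure affects all classes equally) with Dirichlet
replicate dispersion at concentration 10 per unit weight (per-replicate CV
≈ 30% for a ~1.5% feature).  With much looser replicates (CV ≳ 55%) the
*raw* between-class gap of null features can exceed the absolute 10⁴-ppm
effect that a 4.0 score demands from 6 replicates — the moderate dispersion
is the regime in which an LDA = 4.0 threshold is informative.

## Networks

Edges connect top-20 (by total count) OTU pairs with |Spearman ρ| ≥ 0.75
and p < 0.05 on per-sample relative abundances of the rarefied table
(no multiple-testing correction by default; a BH flag exists).  The
strong-correlation threshold is read against ρ, not against the p-value.
Zero-variance OTUs are skipped with a warning.  Per-group networks can be
intersected (same pair, same sign, in ≥ 2 networks) as an optional
consensus step; this construction is provided without claiming equivalence
to any particular published intersection rule.

## Problem sizes and what the benchmark shows

Default runs use 50 taxa, 10 contaminants, 150 libraries at 20k–40k reads —
a desk-scale emulation, not a re-analysis of any deposited dataset.
Passing tests establish that the *procedures* behave as specified
(recovery, calibration, exactness on hand-computed examples), on data whose
generative assumptions are known.  Real amplicon data add features the
generator deliberately omits: chimeras, PCR-cycle and primer bias,
overdispersed replicate profiles, taxonomically structured sequence
similarity, and contaminants correlated with input biomass.  Conclusions
about any particular real dataset therefore do not follow from the
benchmark; the pipeline's value there is that every rule and threshold is
explicit and testable.

Numerical conventions throughout: seeded `numpy` generators everywhere
randomness occurs, with per-stage seeds derived from one master seed;
deterministic tie-breaks (canonical sequence/id ordering); TSV output with
`%.10g` floats so repeated runs are byte-identical.
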