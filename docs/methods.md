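# Methods

This note records the models, numerical choices and open design decisions
behind `tcrpair`, and what the simulation-based tests do and do not
demonstrate.

## Data model

The unit record is the GEM: TCR contig observations (locus, V/J/C genes,
CDR3 at amino-acid and nucleotide level, UMI count, full-length and
productive flags), a sparse pMHC UMI vector, a sparse hashing UMI vector,
and optional gene-expression summaries (gene count, mitochondrial
fraction, vendor cell calls).  Zero counts are never materialized;
absence means 0, and computations that need dense vectors (the
expected-binder test) impute 0 at evaluation time.  HLA alleles are
canonicalized to two-field star notation ("A0301", "HLA-A*03:01" and
"A*03:01" all become "A*03:01") so haplotype matching is independent of
notation.

## Clonotyping

Clonotypes are merged and imputed on the key (Vα, Jα, CDR3α; Vβ, Jβ,
CDR3β) with amino-acid CDR3s (a nucleotide switch exists, default off —
the amino-acid level is what makes two receptors functionally identical).
Merging requires exact key equality; during imputation only, a GEM's
missing chain acts as a wildcard, and a single-chain GEM joins an
existing clonotype only when exactly one clonotype matches its defined
chain — ambiguity founds a new single-chain clonotype instead, avoiding
false merges.  A GEM is consistent with its vendor clonotype when its
defined chains match the group's modal key; contradicting GEMs are
reassigned by the imputation rule with a warning.  Dominant-chain
selection (per locus, highest UMI) runs after clonotype definition;
UMI ties break toward the lexicographically smallest CDR3 nucleotide
sequence for determinism and flag the GEM chain-ambiguous so the
complete-TCR filter can drop it.

## Hashing demultiplexing

Counts are CLR-normalized within each GEM (log1p counts minus their
mean), clustered with a deterministic PAM k-medoids (greedy BUILD +
steepest-descent SWAP, ties to the lowest index) into k = n_samples + 1
clusters.  Per barcode, a negative binomial is fitted by profile maximum
likelihood (mean fixed at the pool mean, size optimized; Poisson fallback
when the pool is under-dispersed) to the raw counts of the background
pool, and a GEM is positive when its raw count strictly exceeds the
fitted 0.99 quantile.

The background pool excludes the cluster with the highest average count
of the barcode *and* any other cluster whose average CLR value for that
barcode is positive.  With k one larger than the number of samples and no
hashing-negative population present, the surplus cluster can split one
sample's GEMs in two; excluding only the single top cluster would then
leave half of that barcode's signal in its own background pool and
inflate the threshold.  The enriched-cluster rule coincides with
single-cluster exclusion whenever samples map one-to-one onto clusters
(the intended regime) and is robust when they do not.

## Expected binder and concordance

Per clonotype with ≥ 10 GEMs (`min_gems`, configurable), the two pMHCs
with the highest mean UMI across members are compared one-sidedly at
α = 0.05.  The default test is the paired Wilcoxon signed-rank over
per-GEM differences — both candidates are measured in the same droplets,
making pairing the natural choice — with an unpaired rank-sum variant
available (`variant="ranksum"`) since the original description does not
name one.  Zero differences are discarded; for n ≤ 25 the exact null
distribution of the positive-rank sum is computed by a
generating-function convolution over doubled midranks (exact under ties,
unlike textbook tables); above 25 a normal approximation with tie and
continuity corrections is used.  A clonotype observing a single pMHC
across ≥ 10 GEMs is assigned that target degenerately (p undefined,
logged).  Mean-UMI ties when selecting the top two break toward the pMHC
seen in more GEMs, then lexicographically.

Binding concordance is the fraction of a clonotype's unambiguous GEMs
(top pMHC not tied) supporting each pMHC; tied GEMs are excluded from
numerator and denominator and reported separately.  "Average binding
concordance" is GEM-weighted by default — each unambiguous GEM
contributes its clonotype's fraction for its own top pMHC — paralleling
the GEM-wise accuracy definition; a clonotype-weighted switch exists.

## Threshold grid search

Training labels (expected binders) are fixed on unfiltered data and never
re-derived during the search.  Count grids span the integers 0 to the
median per-GEM top-UMI of the class; ratio grids use the ladder 0, 1,
1.5, 2, 3, 4, 5, … capped at the median per-GEM ratio.  Either grid is
thinned (counts to ≤ 15 values, ratios to ≤ 12, always retaining the
endpoints and the 0/1/1.5/2 head of the ladder) to keep the joint
six-feature grid tractable; the thresholds a practitioner actually
selects sit at the bottom of the ladder, far below the caps.  Counts
compare with ≥, ratios strictly with >; a threshold of 0 disables its
criterion.  Objective ties prefer higher retention, then component-wise
lower thresholds.  A grid point whose surviving training set is empty
scores an accuracy contribution of 0 and is flagged in the audit table.

## Filter cascade

Steps only ever remove GEMs.  HLA matching uses the union of implicated
donors' haplotypes for hashing doublets and removes hashing-negative
GEMs and GEMs with a tied top pMHC (no defined specificity to match).
The complete-TCR filter uses pre-selection chain multiplicity (a GEM that
had two α chains is incomplete even after dominant-chain substitution).
Specificity-multiplet support is recounted on the set the filter
receives, which makes it the only order-sensitive step.  The viability
filter retains 200 ≤ genes ≤ 2500 and mitochondrial fraction ≤ 0.2, and
is skipped with a warning when summaries are absent; vendor cell flags
are pass-through predicates, never recomputed.

## CDR3 similarity kernel

The raw kernel K(s, t) sums, over k = 1 … min(|s|, |t|) and every pair of
k-mers (one per string), the product over aligned positions of a residue
similarity; the reported score is K(s,t)/√(K(s,s)·K(t,t)), exactly 1 for
identical strings.  Residue similarities are BLOSUM62 scores affinely
rescaled to (0, 1] via (s − min + 1)/(max − min + 1), keeping all values
positive so products never vanish; the matrix and a maximal k are
configurable.  No flank trimming is applied by default (a
remove-first-and-last-residue option exists).  Per peptide, each
both-chain clonotype's intra score is its maximal summed α+β similarity
to same-label clonotypes; the inter score is the maximum over a seeded
uniform sample, without replacement, of other-label clonotypes of equal
size (all of them when fewer exist).  Clonotype labels are the expected
target, falling back to the highest-concordance pMHC.  Intra scores act
as positives and inter scores as negatives in a rank AUC (ties counted
half); the paired intra-vs-inter test reuses the exact signed-rank
machinery.

## Multimer validation

Fluorescent-multimer response frequencies (percent of CD8 T cells) are
converted to adjusted sorted-cell counts by splitting each donor's 1800
sorted cells proportionally to its response frequencies (so per-donor
adjusted counts sum to 1800); a raw-frequency × capacity normalization is
available since the published calculation sheet is not part of the main
text.  A response is detected with ≥ 10 events at ≥ 0.002%, or ≤ 10
events at ≥ 0.01%.  Binary agreement with the set of (donor, pMHC) pairs
retaining ≥ 1 GEM yields MCC, recall and precision; counts are compared
by Pearson correlation over pairs with ≥ 1 adjusted cell or ≥ 1 GEM, and
by OLS in log10–log10 space over pairs positive on both axes (zeros are
dropped, not offset, matching the published equation form; the fit is
skipped when fewer than two distinct x values remain).

## Simulation

Defaults: 300 clonotypes, clone sizes from a truncated power law
(exponent 1.5, max 60 — a heavy tail that yields both singleton clones
and testable ≥ 10-GEM clones), 10 pMHCs over a standard class-I allele
pool, 4 donors with 6-allele haplotypes, pMHC signal NB(mean 8, size 5),
TCR chain signal NB(5, 5), hashing signal NB(80, 10) against background
NB(2, 5), ambient contamination Poisson(0.5) per non-target pMHC per GEM,
chain dropout 0.10 (α) / 0.05 (β), doublet rate 0.05 (pairs of GEMs
merged wholesale), and 10% of GEMs lacking a vendor clonotype id to
exercise imputation.  Planted targets are always consistent with the
donor's haplotype unless `hla_mismatch_fraction` is raised;
cross-reactive clonotypes (a second target) are off by default.  CDR3s
are alphabet-uniform between fixed "CA…F"/"CASS…F" flanks, lengths 10–18,
unique per clonotype.

What the simulation does *not* emulate: realistic CDR3 sequence
similarity structure within a specificity (intra- and inter-similarities
are therefore statistically indistinguishable and the similarity AUC
hovers near 0.5 on simulated data — the AUC machinery is validated by
construction against brute-force pair counting instead), transcriptome
content beyond per-GEM scalars, empty droplets, and barcode-swapping
artifacts.  Passing recovery tests therefore demonstrates the statistics
and the filter logic, not sequencing-level realism.

Problem sizes used by the test suite and the acceptance script — ~1600
GEMs, ~45 testable clonotypes, a ~200k-point threshold grid — were chosen
so a complete run finishes in well under a minute on one CPU while every
code path is exercised.

## Known limitations

* The expected-binder test conditions on the top two mean-UMI pMHCs only;
  a genuinely cross-reactive clonotype receives at most one target.
* PAM k-medoids is exact enough for well-separated hashing clusters but
  is a local search; with heavily overlapping samples the background fit,
  not the clustering, carries the classification.
* The deposited full-scale dataset of the original study is not bundled;
  full-scale counts are reproducible only when those files are supplied
  to the same entry points.
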