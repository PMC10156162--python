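# tcrpair

Data-driven denoising and TCR–pMHC pairing for DNA-barcoded single-cell
immune profiling.

## The problem

Droplet-based single-cell immune profiling (10x Chromium with feature
barcoding) can, in principle, read out a T cell's receptor and its
antigen in the same droplet: each GEM (gel-bead in emulsion) captures TCR
α/β transcripts, DNA barcodes from peptide–MHC (pMHC) multimers bound to
the cell surface, and a sample-hashing barcode identifying the donor,
each quantified by UMI counts.  In practice the readout is noisy —
ambient barcodes partition into droplets they do not belong to, chains
drop out, droplets capture two cells — so the most abundant pMHC in a GEM
is not always the T cell's true target.  `tcrpair` turns the raw vendor
output into high-confidence TCR–pMHC pairs by exploiting the structure of
the data itself: many droplets per T cell clone, donor haplotypes that
constrain which pMHCs are plausible, and UMI count distributions that
separate signal from ambient noise.

## The method

1. **Clonotyping.** Contigs that are not full length or not productive
   are removed; clonotypes with identical VJ-CDR3αβ are merged; GEMs
   without a vendor clonotype are imputed into the merged set by the same
   key, or founded as new clonotypes.  For multi-chain GEMs the most
   abundant chain per locus represents the TCR (after clonotype
   definition).
2. **Hashing demultiplexing.** The CLR-normalized hashing matrix is
   clustered by k-medoids into k = n_samples + 1 clusters; per barcode, a
   negative binomial is fitted to the raw counts of the background pool
   and a GEM is positive when its count exceeds the 0.99 quantile.
   Exactly one positive barcode → singlet; several → doublet; none →
   negative.
3. **Expected binder.** Per clonotype (≥ 10 GEMs), the two pMHCs with the
   highest mean UMI are compared with a one-sided paired Wilcoxon
   signed-rank test (exact null distribution for n ≤ 25, ties handled by
   midranks); p < 0.05 assigns the top pMHC as the clonotype's expected
   target.  Annotation *accuracy* is the fraction of GEMs whose most
   abundant pMHC matches their clonotype's target; *binding concordance*
   is the per-clonotype fraction of GEMs agreeing on a specificity.
4. **Threshold optimization.** For each feature class (pMHC, TRA, TRB) a
   minimum UMI count and a minimum UMI ratio

       UMI_ratio = UMI_max / (UMI_sec + 0.25)

   are searched exhaustively on a grid from 0 to the per-class median,
   maximizing the objective

       o = (2·acc + f) / 3

   where f is the fraction of GEMs retained.
5. **Filter cascade.** Optimal UMI thresholds, donor-haplotype/HLA
   matching, hashing singlets, complete TCRs, specificity multiplets
   (each TCR–pMHC pair seen ≥ 2 times), vendor cell calls, and
   gene-expression viability bounds (200 ≤ genes ≤ 2500, mitochondrial
   fraction ≤ 0.2) — applicable individually or cumulatively, with a
   metric report after every step.
6. **Similarity evaluation.** TCRs of the same specificity should be more
   alike than TCRs of different specificities.  CDR3 similarity is a
   normalized substring kernel (BLOSUM62-derived residue similarities,
   summed over all k-mer pairs); per clonotype, the maximal intra- and
   inter-specificity scores feed a rank AUC and a one-sided paired
   Wilcoxon test.

A seeded simulator (`tcrpair.simulate`) generates datasets with planted
clonotype→pMHC truth plus ambient contamination, dropout, doublets and
hashing noise, so every stage is testable end to end.

## Worked example

```python
from tcrpair import (SimulationParams, simulate_dataset, demultiplex_hashing,
                     grid_search_thresholds, annotation_accuracy)
from tcrpair.clonotyping import (filter_dataset_contigs,
                                 collapse_and_impute_clonotypes,
                                 select_dominant_chains_dataset)
from tcrpair.specificity import expected_binders_for_dataset

ds, truth = simulate_dataset(SimulationParams(seed=1))
ds, _ = filter_dataset_contigs(ds)
ds = collapse_and_impute_clonotypes(ds)
ds = select_dominant_chains_dataset(ds)
expected = expected_binders_for_dataset(ds)
print("raw accuracy:", round(annotation_accuracy(ds, expected), 3))
best, _ = grid_search_thresholds(ds, expected)
print("optimal thresholds:", best.thresholds.min_umi, best.thresholds.min_ratio)
print("filtered accuracy:", round(best.acc, 3), "retained:", round(best.retained_fraction, 3))
```

prints

```
raw accuracy: 0.935
optimal thresholds: {'pmhc': 0, 'tra': 0, 'trb': 0} {'pmhc': 1.0, 'tra': 0.0, 'trb': 0.0}
filtered accuracy: 0.966 retained: 0.961
```

Under these simulation conditions 93.5% of droplets already display their
clone's true target on top; requiring the top pMHC to be more than 1×
as abundant as the runner-up (no count threshold needed at this noise
level) lifts accuracy to 96.6% while keeping 96.1% of GEMs — the search
discards the ambiguous droplets where ambient counts tie the signal.

A `tcrpair` console script exposes the same stages
(`simulate`, `demux`, `gridsearch`, `run`) for file-based 10x-style
inputs; see `tcrpair --help`.

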