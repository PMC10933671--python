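# Methods

This note records the models behind each stage, the defaults and why they
were chosen, and what the synthetic generators do and do not emulate.

## Dual-layer count model

A metabolic-labeling scRNA-seq experiment yields, for every gene × cell
entry, a count of *new* transcripts (synthesised during the labeling
window and chemically converted/detected) and *old* transcripts.  The
package treats the two layers as the primary data and derives totals on
demand (`total = new + old` is an identity, never a stored field, so the
layers cannot drift apart).  Conventional unlabeled data is the degenerate
case `new ≡ 0`.

The generator draws total counts per gene × cell from a negative binomial
(Gamma–Poisson, Var = m + d·m²; defaults m = 8, d = 0.4 — overdispersion
typical of UMI data at moderate depth) and splits them binomially into
new/old with a per-gene, per-group NTR mean.  Baseline NTR means are drawn
from Beta(2, 4) (mean 1/3): a realistic nascent fraction for a labeling
window of a few hours, while still leaving room for downward shifts.
Defaults of 300 cells/group × mean 8 give ≈2400 total counts per gene per
group, enough to estimate a gene-level NTR to a binomial SE of ≈0.01.

Two distinct perturbation mechanisms are exposed, because they answer
different questions:

* **`ntr_shift`** (default: G150 −0.05, combination −0.25 on the program
  genes) shifts the *partition* of a fixed total — total counts remain
  identically distributed across groups, old counts rise as new counts
  fall.  This is the right tool for testing NTR/ΔNTR estimation: the
  default contrast between G150 and the combination is exactly 0.2.
  Shifted means are clipped to [0.001, 0.999] with a logged warning.
* **`synthesis_drop`** (off by default) thins the *new* counts of program
  genes binomially, leaving old counts untouched — the generative model of
  transcription inhibition.  Only under this mechanism is "the groups
  differ only through nascent RNA" literally true, which is what the
  per-layer distance comparison needs: new RNA separates most, total
  (diluted by unchanged old RNA) less, old least.

Labeling efficiency enters as a single multiplicative thinning of the NTR
mean (the simplest identifiable nuisance parameter; real conversion
chemistry is not modeled).  The ground-truth record reports both the
configured NTR and the effective expected NTR after thinning, so recovery
tests compare against the quantity an ideal estimator actually converges
to.

The cohort generator draws unlabeled counts with per-gene lognormal base
means and multiplicative (log-fold) effects of marker sets in designated
cell types/cohorts (defaults: Tfh markers +1.0 in Tfh-tumor cells, CSPS
+0.8 in tumor cells and +0.4 in the relapsed/refractory cohort, exhaustion
+0.6 in tumor cells — clear but not overwhelming effects, chosen once as
plausible for tumor-defining markers).  Tfh cells are confined to 2 of 6
clusters, mirroring designs where tumor cells concentrate in a few
clusters.  A single root seed governs every draw.

Neither generator models ambient RNA, doublets, batch effects or UMI-level
errors; passing tests show estimator correctness under the stated
generative model, not robustness to those artifacts.

## Module scoring

The binned-control score (25 expression bins, 100 control genes sampled
per signature gene, seeded) is the standard construction for "a score
based on the expression of N marker genes".  Normalisation is fixed at
counts-per-10k + log1p throughout the package.  Binning ranks genes by
(mean expression, gene id), so scores are invariant to gene and cell
ordering; the control pool excludes signature genes; bins are reduced with
a warning when the matrix has fewer genes than bins.  Tumor-cluster
assignment ranks clusters by mean score and flags the top k (k = 3 by
default, matching designs that call the three top-scoring clusters tumor),
with ties at the k-th rank broken by lexicographic cluster label.

Quadrant phenotyping calls a gene positive when its *raw* count reaches a
threshold (default ≥ 1).  In dropout-heavy scRNA data any higher threshold
is arbitrary; using raw counts also makes calls independent of the
normalisation of other genes.  Whether published positivity calls used raw
or normalised expression is generally ambiguous; the threshold and layer
are parameters.

The shipped `default_signatures.gmt` contains *placeholder* gene lists for
the Tfh, CSPS and exhaustion signatures — plausible members, clearly
labeled as editable defaults for users to replace with their study's
lists.

## NTR estimation

Gene-level NTR uses the pseudobulk ratio of sums rather than the mean of
per-cell ratios: per-cell ratios of small counts are biased and noisy,
while the ratio of sums is the maximum-likelihood estimate under the
binomial split.  Entries with total support below `min_total` (default 10,
bounding the binomial SE of the ratio below ≈0.16) are reported as NaN —
explicitly missing, never 0.  Per-cell NTR uses all genes (no feature
selection).  ΔNTR ranking uses the signed value descending (the definition
"G150 minus combination" is directional); ranking by |ΔNTR| is available
behind a flag.  Ties break by gene id.

## Group distances

The inter-group distance procedure is: per-layer PCA (CP10k + log1p,
n_pcs = 20 — past the elbow for data of this complexity; each layer gets
its own embedding), then the Euclidean distance between the two sides'
centroids, a side being one group or a pooled union (e.g. DMSO + G150
versus combination).  Centroid distance was chosen over mean pairwise
cell–cell distance because it is symmetric, metric (triangle inequality
exact), cheap, and measures shift of the population centre rather than
mixing dispersion into the statistic; the pairwise variant remains
available via `metric="pairwise"`.  Uncertainty comes from resampling
cells within each side with replacement (default 1000 replicates).  PCA
sign is fixed by making each component's largest-magnitude loading
positive, so embeddings are reproducible across runs.

Note that the bootstrap distance of two *identical* distributions
concentrates near a small positive value (≈ sampling noise of the two
centroids), not at exactly 0; it shrinks as group size grows.

## Enrichment

Over-representation uses the exact hypergeometric upper tail
P[X ≥ k] with the universe defaulting to all genes with a defined ΔNTR —
the ranking's support is the honest background — and Benjamini–Hochberg
step-up across sets.  This is a deterministic, offline stand-in for web
enrichment services; it makes no attempt to reproduce any specific
meta-database or term clustering.

## Bench scores

The IRS bins are half-open on the percentage line ([0,5] → 0, (5,25] → 1,
(25,50] → 2, (50,75] → 3, (75,100] → 4), resolving the printed 5%/6% gap
so every fraction maps to exactly one score.  Ki67 bands are [0,0.5) low,
[0.5,0.7] mid, (0.7,1] high (edges assigned to the middle band).

Dose-response uses the Chou–Talalay median-effect model — the standard
meaning of "combination index < 1" — fitted by least squares on the
log-linearised form with affected fractions clipped to (1e-4, 1−1e-4);
an R² below 0.9 is flagged.  The combination index is the
mutually-exclusive (Loewe) form CI = d_A/IC_x(A) + d_B/IC_x(B) at the
combination's affected fraction; it is exactly 1 for a drug combined with
itself at additivity and scale-invariant under a common change of dose
units.

## Pipelines and determinism

The two workflows (`run_cohort`, `run_dynamics`) run from a JSON config,
write tidy TSVs (fixed float format) and a manifest recording the seed,
config and library versions.  Identical config + seed produce
byte-identical TSVs; every stage is also runnable independently from the
intermediate TSVs via the CLI.  Config validation happens before any
computation.

## Problem sizes used in checks

The packaged checks run the generators at 3000 genes × 300 cells/group for
NTR/ΔNTR recovery (≥2000 counts/gene/group), 1000 × 150 over 20 seeds for
the per-layer distance ordering, 150 × 60 over 200 seeds for null
calibration, and 600 genes × 300 cells over 20 seeds for signature
recovery — sizes at which the binomial and Monte-Carlo error bounds quoted
in the tests are comfortably resolvable.

## Known limitations

* The generators' clean group structure makes recovery easier than on real
  data with batch effects and heterogeneous labeling efficiency.
* Labeling efficiency is confounded with the NTR mean (only their product
  is identifiable without spike-ins or conversion-rate modeling); the
  package estimates the product.
* Kinetic-rate inference (synthesis/degradation), RNA velocity, clustering
  and embedding visualisation are out of scope; cluster labels are inputs.
* The quadrant positivity threshold on raw counts is depth-sensitive:
  deeper sequencing calls more cells positive.
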