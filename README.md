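# scdyn

Dynamic-transcriptome and marker-signature analysis for single-cell RNA
data, built for two recurring study designs in lymphoma biology:

1. **Cohort phenotyping.**  Given an scRNA-seq cohort (e.g. lymph-node
   biopsies spanning normal, newly-diagnosed and relapsed/refractory
   disease), score marker-gene modules per cell — a T-follicular-helper
   (Tfh) tumor score, a cGAS–STING pathway score (CSPS), an exhaustion
   score — call tumor cells as the top-scoring clusters, and partition
   cells into joint-positivity quadrants for a gene pair (cGAS+/STING+,
   cGAS+/STING−, cGAS−/STING+, cGAS−/STING−).
2. **Metabolic-labeling dynamics.**  Given dual-layer counts from
   metabolic-labeling scRNA-seq (every transcript classified *new* —
   synthesised during the labeling window — or *old*), quantify nascent
   transcription via the new-to-total RNA ratio (NTR), rank genes by the
   NTR difference between treatments (ΔNTR), and measure how far treatment
   groups drift apart in PC space separately for the new, old and total
   RNA layers.

A seeded synthetic-data module generates both designs with known ground
truth, so every stage is testable end to end without external downloads.

## The statistics at the core

**Module score.**  For a signature *S* (e.g. seven cGAS–STING pathway
genes), expression is normalised (counts-per-10k, log1p) and each cell is
scored as

    score(c) = mean_{g∈S} x̃(g,c) − mean_{g∈ctrl(S)} x̃(g,c)

where the control genes are sampled from expression-matched bins (25 bins,
100 controls per signature gene, seeded) — the standard binned-control
construction, so a score of 0 means "no enrichment beyond
expression-matched background".

**NTR and ΔNTR.**  Per cell, NTR(c) = Σ_g new(g,c) / Σ_g total(g,c).  Per
gene and group the estimator is the pseudobulk ratio of sums
NTR(g, grp) = Σ_c new / Σ_c total (unbiased and stable for sparse genes),
reported as missing below a minimum total support.  ΔNTR(g) =
NTR(g, G150) − NTR(g, combination); the top-*k* genes by signed ΔNTR feed
hypergeometric over-representation with Benjamini–Hochberg correction.

**Group distances.**  Each RNA layer is embedded independently by PCA
(CP10k + log1p, 20 PCs); the distance between two (possibly pooled) groups
is the Euclidean distance between their centroids, with a within-side
bootstrap for uncertainty.

**Bench-side scores.**  IHC immunoreactivity score IRS = staining degree
(0–3) × positive-rate points (0–4; bins 0–5 / 6–25 / 26–50 / 51–75 / >75
percent), range 0–12; Ki67 banding (<50 / 50–70 / >70 percent); and
Chou–Talalay median-effect fits with the Loewe combination index
CI = d_A/IC_x(A) + d_B/IC_x(B) (CI < 1 ⇒ synergy).

## Worked example

Simulate the three-arm labeling experiment (DMSO, G150, G150+TG003) in
which the combination arm has nascent synthesis of 200 program genes
thinned to 30%, then run the dynamics analyses:

```python
from scdyn import synthetic_data as sd, dynamics, geometry

params = sd.DynGenParams(
    n_genes=2000, n_cells_per_group=200,
    ntr_shift={"G150": -0.05, "GT": -0.05},
    synthesis_drop={"GT": 0.3}, seed=42)
matrix, truth = sd.generate_labeled_counts(params)

ntr = dynamics.cell_ntr(matrix)
print(ntr.groupby(matrix.groups()).median().round(3))

table = dynamics.gene_group_ntr(matrix)
delta = dynamics.delta_ntr(table, "G150", "GT")
top = dynamics.top_k_genes(delta, k=200)
print(len(set(top) & set(truth.program_genes)) / 200)

for layer in ("new", "old", "total"):
    emb = geometry.pc_embedding(matrix, layer=layer, n_pcs=20, seed=42)
    res = geometry.bootstrap_distances(
        emb, matrix.groups(), ["DMSO", "G150"], "GT", n_boot=200, seed=42)
    print(layer, round(res.point_distance, 2), round(res.median, 2))
```

prints

```
group
DMSO    0.336
G150    0.330
GT      0.316
Name: ntr, dtype: float64
0.91
new 11.7 11.72
old 0.58 0.91
total 3.62 3.67
```

The combination group's median per-cell NTR is depressed (0.316 vs 0.336),
the top-200 ΔNTR ranking recovers 91% of the truly suppressed program
genes, and the (DMSO + G150)-versus-combination distance is longest in new
RNA and shortest in old RNA — the separation between treatments lives in
nascent transcription.

The same analyses run from the shell:

```bash
scdyn simulate --mode dynamics --out sim/ --seed 42
scdyn ntr --matrix sim/
scdyn delta --ntr-table ntr_gene_group.tsv --minuend G150 --subtrahend GT --top-k 500
scdyn distance --matrix sim/ --layer new --side-a DMSO,G150 --side-b GT
scdyn run-dynamics --out run/ --seed 42    # the whole workflow + manifest
```

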