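# immunonet

Integrated network analysis of case-control PBMC transcriptomics:
signed co-expression modules with cross-cohort preservation, moderated
differential expression, differential transcription-factor involvement,
master-regulator ranking by Laplacian centrality, signature-based cell
deconvolution, and PLS-DA prediction of cell-proportion groups — all
exercised end to end on synthetic two-cohort case-control data with
planted, exported ground truth.

## The scientific problem

In inflammatory diseases such as sarcoidosis, bulk PBMC (peripheral
blood mononuclear cell) expression profiles mix two signals: *which*
genes each cell type expresses, and *how many* of each cell type are
circulating.  Disease-associated shifts — e.g. monocyte expansion with
CD4+ T-cell depletion — are therefore entangled with transcriptional
re-programming.  This package implements a combinatorial strategy to
disentangle them:

1. **Modules.** A signed weighted co-expression network is built on the
   reference cohort with adjacency
   `a_ij = ((1 + cor(x_i, x_j))/2)^β`, the soft threshold β chosen by
   scale-free topology fit.  Topological-overlap dissimilarity
   `1 − TOM` is clustered (average linkage, static cut, iterative
   eigengene merging) into modules; each module is summarised by its
   eigengene (first principal component of the standardised module
   block).  Module–trait association uses Spearman correlation.
2. **Preservation.** Modules replicate in an independent cohort when
   their permutation Z-summary — the mean of median density and
   connectivity z-scores against size-matched random gene sets —
   exceeds 10.
3. **Differential expression** uses the empirical-Bayes moderated
   t-statistic (variances shrunk toward a scaled-F prior fitted by
   moments of log s²; cross-checked against limma to machine
   precision), with Benjamini–Hochberg FDR control at 10%.
4. **Differential TF involvement (dTFI).** Bipartite TF→gene networks
   are inferred per state (controls = baseline, cases = perturbed) by
   blending a motif prior with expression-correlation evidence.  A
   ridge-regression transition matrix τ maps the baseline network onto
   the perturbed one; for TF *j*,
   `dTFI_j = Σ_{i≠j} τ²_ij / Σ_i τ²_ij ∈ [0, 1]`
   measures how much of its perturbed targeting profile must be
   borrowed from *other* TFs' baseline profiles.  Significance comes
   from re-running the entire inference under sample-label permutation
   (z-score against the permutation null, BH FDR < 0.1).
5. **Subnetworks and master regulators.** The differential subnetwork
   keeps significant-dTFI TFs, differentially expressed target genes
   annotated to cell-fate processes (apoptosis, cell cycle,
   proliferation, …), and edges stronger in cases; nodes are ranked by
   Laplacian centrality, the relative drop in graph energy
   `E = Σ_v s_v² + 2 Σ_{u<v} w²_uv` upon node removal.
6. **Deconvolution and prediction.** Cell-type fractions are estimated
   per sample by NNLS (or linear ν-SVR) against a marker-gene signature
   matrix; cases and controls are compared by Mann–Whitney U; samples
   are median-split into high/low groups; and PLS-DA classifiers
   (median-centred, unit-variance scaled, NIPALS) trained on
   master-regulator target genes predict those groups in the validation
   cohort.  Feature relevance uses VIP scores (`Σ VIP² = p`, VIP > 1 =
   influential); paired ROC curves are compared with Venkatraman's
   rank-exchange permutation test.

Because the real cohorts are external, the package ships a first-class
synthetic-data generator that plants every structure the analysis is
supposed to find — modules (preserved and not), a differential TF,
differentially expressed targets, cell mixtures with monocyte-enriched
/ CD4-depleted cases, and a gene-wise affine platform effect for the
second cohort — and exports the ground truth for recovery testing.

## Worked example

```python
from immunonet.pipeline import PipelineConfig, run_pipeline, render_report

report = run_pipeline(PipelineConfig(seed=7), outdir="out")
print(render_report(report), end="")
```

prints

```
immunonet pipeline report (schema v1, seed 7)

modules: 6 detected (beta=19), 102 grey genes
z_summary: M1=21.4, M2=35.8, M3=27.8, M4=1.7, M5=1.9, M6=13.8
preserved: M1, M2, M3, M6
disease modules: M2 (rho=-0.86), M3 (rho=+0.75)
DE genes at FDR 0.1: 75
dTFI (M3): significant = TF00, TF01, TF02, TF05, TF06; top = TF00
subnetwork: 32 nodes, 74 edges; regulators: TF00, TF06, TF01, TF02
deconv cohort 1 MWU p: B_cell=0.569, CD14_monocyte=3.02e-11, CD4_T=3.02e-11, CD8_T=0.807, NK_cell=0.171
deconv cohort 2 MWU p: B_cell=0.959, CD14_monocyte=3.34e-11, CD4_T=3.02e-11, CD8_T=0.0963, NK_cell=0.935
plsda [CD14_monocyte] control_1: AUC=0.457; control_2: AUC=0.620; signal: AUC=0.947
plsda [CD4_T] control_1: AUC=0.431; control_2: AUC=0.637; signal: AUC=0.974
```

Reading the output: six modules were detected in the reference cohort;
four replicate in the validation cohort (Z-summary > 10) and the two
scrambled negative-control modules (M4, M5) do not.  Two preserved
modules associate with disease (one over-, one under-expressed — here
M3 and M2).  Within the over-expressed module, the planted differential
TF (TF00) has the top dTFI and is permutation-significant; it also tops
the Laplacian-centrality ranking of the filtered cell-fate subnetwork.
Deconvolved monocyte and CD4+ T-cell proportions differ between cases
and controls in both cohorts (MWU p ≈ 3e-11) while bystander cell types
do not.  PLS-DA models on the planted TF's target genes predict the
validation cohort's high/low monocyte and CD4 groups with AUC ≈ 0.95,
whereas random gene lists from the non-preserved modules stay near
chance.

The same pipeline is exposed on the command line:

```bash
immunonet run --outdir out --seed 7        # full pipeline
immunonet simulate --outdir data --seed 7  # synthetic data only
immunonet modules --expression data/cohort1_expression.tsv --outdir mods
```

Real expression matrices (genes × samples, TSV/CSV, log scale),
phenotype CSVs, motif-prior TSVs, GMT gene sets and signature TSVs are
accepted wherever the synthetic counterparts are used.

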