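# Methods

This note records the models implemented in `immunonet`, the
assumptions behind them, the defaults and why they were chosen, what
the synthetic generator does and does not emulate, and the numerical
choices that a maintainer would otherwise have to reverse-engineer.

## Co-expression networks and modules

The network is signed: `a_ij = ((1 + r_ij)/2)^β` with Pearson `r` on
log-scale expression, so perfectly anti-correlated genes get adjacency
0, not 1.  β is chosen as the smallest candidate whose scale-free
topology fit (signed R² of the binned log₁₀ p(k) vs log₁₀ k
regression, 10 equal-width bins) reaches 0.8, with fallback to the
maximiser plus a warning flag.  On block-structured synthetic data the
degree distribution is bimodal rather than scale-free, so the fallback
path is the *typical* path there; that is expected and harmless — the
chosen β still maximises contrast.

Topological overlap uses the standard formula
`TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`
with `k` excluding the diagonal; the matrix is symmetrised and clipped
to [0, 1], diagonal set to 1.

Module detection is deliberately a **static** height cut on
average-linkage clustering of `1 − TOM` (default 0.995 × the maximum
merge height), followed by iterative merging of modules whose
eigengenes are closer than `merge_threshold = 0.25` (1 − correlation),
clusters under `min_size` going to "grey".  The dynamic hybrid cut used
by the reference toolchain is *not* implemented: the static cut is
deterministic, has two parameters instead of eight, and recovers the
planted partitions at ARI ≥ 0.98; treat this as a documented divergence
when comparing module boundaries with other software.  Module labels
are "M1", "M2", … in decreasing size order, which makes detection
invariant to gene ordering.

Eigengenes are the first right singular vector of the gene-standardised
module block, scaled to unit sample variance, with sign fixed so the
eigengene correlates non-negatively with mean module expression.

## Preservation (Z-summary)

For each module, five statistics are computed on the (reference, test)
cohort pair: mean intramodular correlation and mean intramodular signed
adjacency in the test cohort (density), and the correlations of
intramodular connectivity vectors, of the vectorised intramodular
correlation matrices, and of module-membership (kME) vectors between
cohorts (connectivity).  The null re-computes all five with the
*test-side* gene set replaced by a size-matched random draw from the
shared universe; randomising only the test side breaks module
correspondence without breaking cohort structure (randomising both
sides leaves random sets perfectly "preserved" with themselves and
centres the connectivity null away from zero).  `z_density` and
`z_connectivity` are medians of their component z-scores and
`z_summary` their mean; > 10 is called strongly preserved, following
the published convention.  This five-statistic composite is a subset of
the full published preservation family, chosen to keep the permutation
cost desk-scale; it separates planted preserved (Z ≈ 20–35 at defaults)
from scrambled modules (Z < 5) with a wide margin.

## Moderated t

Gene-wise residual variances are shrunk toward a scaled-F prior whose
parameters (d₀, s₀²) are fitted by moments of log s² with
digamma/trigamma corrections; the trigamma equation is inverted by
Newton iteration, and a non-positive moment estimate yields d₀ = ∞
(complete shrinkage).  The implementation agrees with limma's
`lmFit`/`eBayes` to ~1e-15 on t and p (a permanent cross-check test
runs limma through Rscript).  Fold changes are group mean differences
on the already-log-scale matrix.  The Mann–Whitney U approximation is
tie-corrected but applies **no** continuity correction, making the
two-group Kruskal–Wallis test exactly equivalent; exact enumeration is
used for small tie-free samples.  Pearson χ² likewise applies no
continuity correction and drops all-zero categories first — both
choices are required to reproduce the printed cohort-table p-values.

## Differential TF involvement

State networks: `w = α·motif + (1−α)·cor(TF, gene)` with α = 0.5
(exposed), correlations within each state's samples.  The transition
matrix solves `min ‖B_·j − A τ_·j‖² + λ‖τ_·j‖²` per column; the default
λ = 0.1·tr(AᵀA)/m is intentionally heavy.  Within a module all genes
share a latent factor, so every TF's direct-evidence column contains a
nearly identical "block-constant" noise component of magnitude ~1/√n;
with light regularisation the resulting collinearity lets the regression
convert that noise into large spurious off-diagonal mass.  λ was chosen
by scanning 1e-3…3 for stable planted-TF recovery; it plateaus from
~0.1 and the null (permutation) calibration is unaffected because the
null pipeline uses the same λ.  dTFI is the proportion of squared
off-diagonal mass per column, in [0, 1]; the original algorithm's
scaling differs across descriptions, so this normalised form is a
documented choice.  Significance re-runs the *entire* inference (both
networks and τ) per label permutation, preserving gene–gene dependence.

An important structural fact discovered during development and encoded
in the generator design: a targeting change is only visible to a
transition matrix if the gained (or lost) targeting direction exists in
the *baseline column space* — a gained block orthogonal to every
baseline column is absorbed into the regression residual, not into
off-diagonal mass.  The generator therefore plants the change as a
**source switch**: donor TFs drive disjoint disease-module target
blocks in the control state, and the differential TF drives the same
blocks (at equal strength, keeping variance state-balanced) in the case
state, with the gained block absent from its motif prior.

## Subnetwork and Laplacian centrality

Filters: TF dTFI q < 0.1; gene DE q < 0.1 *and* annotated to at least
one process matching a cell-fate keyword (case-insensitive substring;
"aging/senescence" split into alternatives; "apoptot" added because
GO's adjectival phrasing "apoptotic process" is never matched by the
noun "apoptosis"); edge kept iff the case weight strictly exceeds the
control weight, weighted by the difference.  Centrality is computed on
the symmetrised weight matrix — the graph is strictly bipartite, so TF
strengths are pure out-strengths and gene strengths pure in-strengths —
with energy `E = Σ s_v² + 2Σ_{u<v} w²` and the closed-form removal drop
`ΔE(v) = s_v² + 2 Σ_u s_u w_uv + Σ_u w²_uv` (full neighbour strengths),
verified against brute-force recomputation on random graphs to 1e-10.
Ranking ties break by dTFI z, then lexicographically.

## Deconvolution

NNLS per sample (default; deterministic) or linear ν-SVR over
ν ∈ {0.25, 0.5, 0.75} with the best reconstruction RMSE, coefficients
clipped at 0 and normalised to sum to 1.  Standardisation is
scale-only: each mixture column is scaled to unit mean (hence estimated
proportions are invariant to a sample's global expression scale) and
each gene row of both signature and mixture is divided by the signature
row's SD (equalising gene influence across platforms).  Centering is
deliberately omitted — a shared per-gene scale preserves the exact
linear mixing identity `m = S p` (so noiseless mixtures are recovered
to 1e-6), while per-gene centering would break it unless Σp = 1 exactly
held *before* normalisation.  Clinical-vs-imputed concordance reports
Pearson/Spearman coefficients, RMSE on the percentage scale, and the
count of samples whose high/low median-split labels (computed within
each measurement separately) agree.

## PLS-DA

PLS1 NIPALS with the class coded +1/−1; X and y are **median**-centred
and scaled to unit SD (median, not mean, following the described
procedure; sklearn's PLSRegression cannot median-centre, which is why
NIPALS is implemented here — sklearn serves as a cross-check on
symmetric data where median = mean).  Classification thresholds the
predicted response at 0, ties to "high".  The calibration gate
(misclassifications < 5 and accuracy > 70%) is evaluated by
*resubstitution* on component 1; whether the original procedure used
resubstitution or cross-validation is ambiguous, and resubstitution is
the chosen reading.  Note its known property: with many more features
than samples the component-1 training accuracy is optimistic by
construction and random labels can clear the gate — the pipeline's
models are in the p < n regime where the gate discriminates.  Default
2 components (configurable); the number used beyond the first is not
specified by the source procedure.  VIP uses
`VIP_j = √(p Σ_a SSY_a w²_aj / Σ_a SSY_a)` with `SSY_a = q_a² t_aᵀt_a`,
so `Σ VIP² = p` exactly.  AUC is the tie-aware Mann–Whitney concordance
probability.  Venkatraman's test rank-transforms both markers with one
shared per-sample tie-breaking jitter (so identical or
monotone-equivalent markers give statistic 0 and p = 1 exactly), uses
the integrated absolute difference of the error curves over all rank
thresholds, and builds the null by exchanging the two markers' ranks
within each sample with probability ½, re-ranking with fresh shared
jitter; `p = (1 + #{null ≥ obs})/(1 + B)`.  The cited test is
permutation-based, so the "10,000 bootstraps" of the source description
are implemented as permutations (default 2,000 in the pipeline,
configurable).

## The synthetic generator

Expression follows an additive latent-factor model
`X_gs = μ_g + λ_g f_{m(g),s} + ε_gs` with λ ~ U(0.8, 1.2),
ε ~ N(0, noise_sd²), factors standard normal; disease-module factors
are shifted by ±`factor_effect` in cases.  Grey genes are pure noise.
TF transcripts are their own activities plus a gene-level mean.
Cohort 2 re-draws factors (new samples), applies a gene-wise affine
platform distortion (scale ~ N(1, 0.15²) clipped at 0.2, offset
~ N(0, 0.3²)), and re-assigns non-preserved-module genes to fresh
cohort-2-only factors — their cohort-1 co-expression simply does not
replicate, and, because the fresh factors carry no disease shift, the
negative-control gene lists drawn from them stay near chance AUC.
Mixtures are `signature × proportionsᵀ + N(0, noise_sd²)` clipped at 0,
proportions Dirichlet per sample.

Defaults (the study conditions for every recovery test): 300 genes +
12 TFs, 6 modules of 25–40 genes (2 disease ± , 2 neutral preserved, 2
non-preserved), 30 cases + 30 controls per cohort, `factor_effect = 3`,
`noise_sd = 0.5`, `targeting_shift = 1.5` with 3 donor TFs,
Dirichlet concentrations (60, 48, 40, 24, 88) for cases and
(100, 48, 40, 24, 48) for controls over (CD4 T, CD8 T, B, NK, CD14
monocyte) — monocyte-enriched, CD4-depleted cases with ~3–4 SE group
separation.  These sizes keep the full pipeline under ~10 s and the
complete permutation experiments under ~2 min on one core while leaving
each recovery criterion a comfortable margin.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: count noise (expression is Gaussian
on the log scale, no mean–variance relationship), library-size and
batch effects beyond the gene-wise affine platform distortion,
correlated cell-type composition effects on the module genes
themselves (mixtures live in a separate marker-gene space), motif-prior
errors, TF post-transcriptional regulation (TF activity equals TF
transcript), and any overlap structure between modules.  Recovery
results quantify internal consistency of the method chain, not its
field performance.

## Degenerate inputs and conventions

All-identical values: Kruskal–Wallis and MWU report statistic 0 / p = 1
by convention; an all-identical gene gets t = 0, p = 1.  Constant
traits and zero-variance correlation inputs are reported missing with a
warning, not errors.  Zero-variance genes are dropped (with a warning)
by PLS-DA but are an error in network construction, where they poison
every correlation.  Empty subnetworks after filtering are returned
empty with a warning.  Median splits send ties to "high"
(value ≥ median).  BH re-application is not idempotent in the strict
same-rejections sense (re-adjusted q-values can only rise); the test
suite asserts the direction that actually holds.
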