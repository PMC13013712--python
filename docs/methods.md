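# Methods

This note records the models behind `visig`, the defaults that matter, what
the synthetic-data generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Differential expression

Each gene is modeled as negative binomial with log link,
`E[y] = μ`, `Var = μ + φμ²`, and offsets `log(lib_size · norm_factor)`
where the norm factors come from TMM (doubly trimmed — 30% on M-values, 5%
on A-values — inverse-variance-weighted mean of log ratios against the
sample whose 75th-percentile count fraction is closest to the cohort mean;
factors rescaled to geometric mean 1). The expression filter (CPM > 1 in
≥ ceil(0.10·n) samples) uses raw library sizes, pre-TMM, matching the
standard toolkit convention. logCPM uses a prior count of 0.5 (not dictated
by anything; it is the common default and only affects near-zero counts).

The VI-vs-LMP test is a likelihood-ratio test between the full design
(intercept + NST + VI dummies, optionally extra covariates such as an LI
indicator) and the design with the contrast column(s) dropped, both fitted
by IRLS at a fixed per-gene dispersion, with χ² reference on the number of
dropped coefficients. Fits are batched across genes (shared design, per-gene
working weights, batched 3×3 solves), which keeps a 2,000-gene cohort DE
run around 0.3 s.

Dispersion is estimated per gene by method of moments on depth-normalized
counts, `φ = max((s² − m)/m², 10⁻⁶)`, then shrunk toward a lowess trend of
log φ on mean logCPM. The trend carries a prior weight of 10 pseudo-genes
against the gene's residual degrees of freedom, so with ~100 samples the
per-gene estimate dominates; this weighting is what keeps the null p-value
distribution calibrated (the tests assert a Kolmogorov distance < 0.05 from
uniform and 3–7% of p < 0.05 on a 2,000-gene null cohort). Full
empirical-Bayes adjusted-profile-likelihood machinery is deliberately out of
scope; calibration is asserted by simulation instead of by equivalence to a
reference DE package. Genes whose IRLS does not converge are flagged
(p = NA) and excluded from the BH adjustment.

## Clustering and choice of k

Significant genes (FDR < 0.01) are clustered on per-gene z-scores of logCPM
(mean 0, sd 1, ddof = 1) with Ward2 agglomeration on Euclidean distance.
Consensus clustering subsamples 80% of genes 100 times per candidate k
(k = 2…10), reclusters, and accumulates a co-clustering matrix normalized
by co-sampling counts. The area under the CDF of the off-diagonal consensus
values equals `1 − mean(consensus)` and is used directly. The chosen k is
the last k in an unbroken run whose area gain over k−1 is at least 0.1 of
the k = 2 area — "substantial improvement up to but not beyond k". The
threshold is explicit configuration because the original judgment is
qualitative; the contiguous rule prevents a late spurious gain (a stable
split inside a true cluster) from dragging k upward. Gene subsampling is
the default axis; sample subsampling is available as a flag. Known
limitation: on noiseless, perfectly crisp clusters with internal
substructure the delta-area heuristic can overshoot k, a documented
weakness of consensus clustering generally.

## The 48-gene predictor

Slots are apportioned to clusters by largest remainder on the clusters'
shares of the significant set; within clusters genes are ranked by
ascending p (ties: larger |log2FC|, then gene ID). The within-cluster rule
is an assumption — only the proportionality of the selection is a stated
constraint of the design being reproduced.

The classifier minimizes `−(1/n)·Bernoulli log-likelihood + (λ/2)‖β‖²`
(intercept unpenalized) on per-gene standardized logCPM by damped Newton
iterations to gradient norm < 10⁻⁸; at λ = 0 a separating direction is
detected and reported as an error. λ comes from stratified 5-fold inner CV
over 25 log-spaced values in [10⁻³, 10³] (the original grid is
unpublished), maximizing mean inner AUROC with ties to the larger penalty.
Outer evaluation repeats the whole derivation — filter, TMM, DE,
clustering, selection, standardization, inner CV — on each of 100
stratified 70/30 training splits; outer splits are stratified by VI label
to guarantee class presence (stratification is a choice; the 70/30 ratio
is not). Selection contrasts VI vs LMP, evaluation is VI vs non-VI. The
decision threshold is the Youden point over midpoints of adjacent distinct
training scores, ties resolved toward the lower cutoff (favoring
sensitivity); positivity downstream is strictly `score > cutoff`.

Cross-cohort harmonization (`reference_adjust`) matches each gene's logCPM
mean and variance in the target cohort to the reference:
`x' = (x − m_t)/s_t · s_r + m_r`; the reference is never altered. Note a
structural fact the tests document: for a linear model scored by AUROC,
a cohort-wide per-gene additive shift cancels entirely (ranks are
invariant), so the adjustment's measurable benefit comes only from
re-weighting genes whose within-cohort variance was distorted (e.g. by
multi-batch structure). With the generator's additive batch shifts the
benefit is real but small — the 48-gene model's redundancy makes it robust
to per-gene distortion, the same redundancy that underlies its robustness
to intra-tumor heterogeneity. The adjustment matters most for applying the
*cutoff*, which is not rank-invariant.

## Heterogeneity and spatial layers

Multi-region tumors are down-sampled to one intra-tumor region pair each;
an equal number of inter-tumor pairs is drawn (two distinct tumors per
draw, one random region each, tumors replaced across draws), and intra vs
inter |Δscore| are compared by two-sided rank-sum. Region-pair agreement
is Spearman; for a tumor latent sd σ and region noise sd τ the expected
product-moment attenuation is `1/(1 + τ²/σ²)`, which the generator
reproduces. Gene-level reproducibility ranks use Spearman across matched
pairs (the original's correlation flavor is unstated; Spearman keeps
consistency with the pair-level analysis).

Preranked GSEA walks the ranking in descending order; hits gain
`|value|^w / Σ_set |value|^w` (w = 1), misses lose `1/(N − |set|)`; ES is
the running-sum extremum, the null is set-label permutation, NES divides
by the mean |null ES| of the same sign, and the p-value is the two-sided
permutation tail `(1 + #{|ES_perm| ≥ |ES|})/(1 + n_perm)` — calibrated
uniform under random sets by construction.

Spot QC keeps spots with ≥ 250 detected genes. Module scores bin all genes
into 24 equal-frequency bins of average expression (ties to the lower bin)
and subtract the mean of 100 per-set-gene control draws from the matching
bin — the cited scoring function's defaults, since the original settings
are unstated. Spot counts are log-normalized (`log1p` of depth-normalized
× 10⁴) in place of the variance-stabilizing transform used upstream, which
is out of scope. The spatially weighted correlation rank-transforms both
scores globally, then computes a kernel-weighted Pearson per spot
(bisquare kernel, bandwidth = 5 lattice units, i.e. 5 × spot spacing) and
averages over spots; bandwidth unit, kernel, and method are configurable
because the original's unit convention is ambiguous. Distance binning
labels focus spots and anything within 1 mm of one (inclusive at exactly
1 mm) as proximal; samples without foci are entirely distal.

## Diagnostic accuracy

Confusion counts at the prespecified cutoff give sensitivity and
specificity with Clopper–Pearson exact intervals
(`BetaQuantile(α/2; k, n−k+1)` to `BetaQuantile(1−α/2; k+1, n−k)`), and
uniform-prior conjugate posteriors `Beta(1+TP, 1+FN)`, `Beta(1+TN, 1+FP)`.
10,000 paired draws are pushed through
`PPV = se·p / (se·p + (1−sp)(1−p))` and
`NPV = sp(1−p) / ((1−se)·p + sp(1−p))` at prevalences 0.15–0.35;
summaries are the median and 2.5/97.5 linear-interpolation (type-7)
percentiles. PPV is nondecreasing and NPV nonincreasing in prevalence for
every draw, which the tests assert.

## The synthetic cohorts

`generate_bulk_cohort` defaults: 100 tumors (35 LMP / 35 NST / 30 VI — VI
prevalence 30%), 2,000 genes, four planted clusters of 115/37/182/140
genes (474 signature genes) with VI-vs-LMP log2 fold changes
(1.5, 2.0, 1.2, −1.5) — the small remodeling-type cluster strongest, the
down-regulated differentiation-type cluster negative. NST tumors carry
half the VI effect (`nst_effect_scale = 0.5`, a modeling choice: the
intermediate grade's effect size is not documented), producing the
LMP < NST < VI gradient. Counts are gamma-Poisson with shared dispersion
0.15 (BCV ≈ 0.39, typical of bulk tumor RNA-seq), library sizes log-normal
around e^16.1 ≈ 10⁷. Baselines are log-normal with ~5% of background genes
planted below the CPM filter.

Two structural features make the planted clusters behave like real
co-expression modules rather than interchangeable DE gene lists: each
cluster has a per-sample latent activity (sd 0.8 on the log2 scale, gene
loadings ≈ N(1, 0.2)) shared by its members, and the activities of
clusters 1 and 3 are correlated at 0.8 — emulating the observed situation
where those two up-regulated programs overlap biologically and are each
other's nearest neighbors in the dendrogram. Without the latent factors,
clustering could not tell the three up-regulated clusters apart; without
the 1–3 correlation, the delta-area curve has no elbow at k = 4 because
the last merge would involve the small cluster 2 and release almost no
consensus mass. Batch effects are per-gene additive log-scale offsets per
batch, N(0, batch_shift_sd²), off by default.

What the generators do **not** emulate: gene–gene correlation beyond the
planted modules, per-gene dispersion trends of real transcriptomes,
read-level artifacts, isoforms, platform-specific GC/length biases, and
spatial spot deconvolution structure. Passing recovery tests therefore
demonstrates the pipeline's correctness and statistical calibration under
its own model class, not clinical performance on real cohorts.

Problem sizes used in the test suite — 2,000 genes × 100 samples for the
discovery cohort, 100 outer CV splits, 63 tumors for the heterogeneity
suite, 10,000 Monte-Carlo draws — are the defaults of the emulated design;
the full suite runs in a few minutes on one core.

## Degenerate inputs and tie rules (summary)

Constant genes z-score to 0 with a warning; all-zero samples are rejected
before TMM; TMM with fewer than 2 trimmed genes falls back to factor 1
with a warning; empty filter results warn rather than error; ranking ties
break by |log2FC| then gene ID; Ward merges are deterministic given input
order; cluster quotas exceeding cluster size spill to the next-largest
remainder with a warning; missing predictor genes are an error unless
imputation at training means is requested; single-class label vectors are
rejected by AUROC, Youden and the confusion/posterior layers.
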