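# Methods

This note documents the statistical procedures `gutshift` implements, the
choices made where conventions diverge, and what the synthetic-cohort
benchmarks do and do not establish.

## Data model

Profile tables are features × samples matrices of non-negative abundances;
absence is 0, never missing — missingness exists only for metadata
covariates. Taxon tables (MetaPhlAn merged-abundance dialect) are kept in
percent and every single-rank sample column is renormalised to 100; a column
off by more than 1% triggers a logged warning first (MetaPhlAn rounding
routinely produces sums of 99.99–100.01, hence the tolerance). Pathway
tables (HUMAnN pathabundance dialect) drop taxon-stratified rows by default
and are total-sum scaled to 10⁶ (cpm). Whether pathway abundances should be
renormalised at all is not settled practice; cpm was chosen so taxon and
pathway tables enter every downstream statistic on a closed, comparable
scale, and it is what the renormalising distance computation would impose
anyway. Pathway ids keep the full `PWY-XXXX: description` string as the key.

`align()` intersects table and metadata sample ids and *reports* subjects
left without a complete pre/post pair rather than dropping them: alpha
diversity, enrichment and prevalence use all retained samples, while
matched distances and the paired test use complete pairs only.

## Alpha diversity

Shannon entropy is computed in nats (the base is a parameter); "Simpson"
means the Gini-Simpson index 1 − Σp², with dominance and inverse variants
behind a flag — the name is ambiguous in the literature and the chosen form
matches the common QIIME 2 default. Richness counts features strictly above
a detection threshold, default 0, matching profiler output semantics where
any reported abundance is a detection.

## Beta diversity, matched distances, PERMANOVA

Sample columns are renormalised before Bray-Curtis so that unequal totals
never masquerade as compositional difference. The matched distance is the
Bray-Curtis distance between the pre and post sample of one subject; it is
the per-subject effect size the responder stratification uses.

PERMANOVA follows the distance-based one-way formulation: with total
sum-of-squares `SS_T = Σᵢ<ⱼ d²ᵢⱼ / n` and within-group
`SS_W = Σ_g Σᵢ<ⱼ∈g d²ᵢⱼ / n_g`, the statistic is
`F = (SS_T − SS_W)/(k−1) ÷ SS_W/(n−k)`. Significance comes from full label
permutations (no subject blocking — the group comparisons here are
between-subject) with the add-one estimator
`p = (1 + #{F* ≥ F})/(1 + N)`, so p is never 0 and is a deterministic
function of the seed. The permuted statistics are computed vectorised; the
default N = 999 costs milliseconds. The implementation is cross-checked
against an independent PERMANOVA implementation (identical pseudo-F) and
against classical one-way ANOVA, which it reproduces exactly on Euclidean
distances of univariate data.

## Responder stratification

Subjects are split at the median of matched distances (standard
midpoint-of-middle-two for even n); a subject exactly at the threshold is a
large-shift responder (≥ rule). An explicit threshold — e.g. a previously
realized cohort cut such as 0.36 — overrides the median. Baseline contrasts
(richness, nutrient intakes) default to Mann-Whitney because per-group n is
single-digit, where a t-test's normality assumption has no support; the
t-test is available by flag. All variables contrasted in one call form one
BH family, which reproduces the familiar "raw p < 0.05, adjusted p > 0.05"
pattern of small-cohort nutrient contrasts.

## Exact small-sample tests

At this package's target cohort sizes, asymptotic rank-test p-values are
the main reproducibility hazard, so the tests switch to exact enumeration
below documented limits:

* **Kruskal-Wallis gate** — exact permutation tail of the tie-corrected H
  over all C(n, n₁) group assignments for two groups with ≤ 8 samples
  total; the chi-square approximation above. A feature constant across all
  samples carries no signal and is assigned p = 1 rather than an error.
* **Mann-Whitney** — scipy's exact distribution when there are no ties
  (combined n ≤ 20); in-package enumeration when ties block it (n ≤ 14);
  asymptotic with tie correction otherwise.
* **Wilcoxon signed-rank** — zero differences are dropped (Wilcoxon's
  original policy, also the dominant scipy behaviour), then the exact
  distribution of W⁺ is built by the rank-sum convolution for ≤ 25 pairs
  (tied midranks are doubled to integers, which keeps the sign-flip null
  exact); normal approximation with tie and continuity correction above.
* **Spearman** — rho is Pearson on midranks. Below n = 10 the two-sided p
  is the exact permutation tail over all n! rank arrangements (vectorised
  through a cached permutation-index array): the package's subgroup screens
  run at n = 7, where the t approximation is materially wrong. At n ≥ 10
  the t approximation is used, matching scipy's `spearmanr`.

Each exact path is validated against an independent brute-force oracle
(exhaustive assignment enumeration, 2ⁿ sign enumeration, n! permutation)
in the test suite.

## Differential enrichment (Kruskal gate + LDA effect size)

The enrichment screen is a two-stage procedure in the LEfSe family, reduced
to its two-group core: no subclass (pairwise-Wilcoxon) consistency stage and
no one-against-all multiclass strategy; an optional bootstrap mode (B rounds
of class-stratified 2/3 subsampling, default B = 30 when enabled) is kept
for compatibility with the original LEfSe's score averaging.

Stage 1 gates features at Kruskal-Wallis p < α (default 0.05), with no
multiple-testing correction — the LEfSe convention; the correlation screens,
by contrast, always correct.

Stage 2 computes the effect size. Abundances are total-sum scaled to 10⁶
per sample (a single-feature table is left on its input scale — closing a
one-dimensional composition would map every sample to the same constant and
erase the signal). On the gated features a two-class discriminant direction
is obtained in closed form, `w ∝ S_w⁻¹(μ₁ − μ₀)`, normalised to unit
length; the within-class scatter carries a relative ridge of
1e-6 × mean(diag S_w) (configurable) so rank-deficient scatters — more
gated features than samples — stay solvable without distorting
well-conditioned ones. The per-feature score is

    score_f = sign(Δ_f) · log₁₀(max(|w_f · Δ_f|, 1)),   Δ_f = μ₁,f − μ₀,f

i.e. the class-mean separation the discriminant attributes to that feature,
in cpm units, floored at 1 so no-signal features score 0. The + sign marks
the designated second group (post, or the large-shift responder group). At
vanishing within-group noise the discriminant aligns with the differing
feature and the score tends to log₁₀ of the raw mean difference; the
conventional significance threshold |score| ≥ 2 therefore means a
separation of at least 100 cpm (0.01% abundance) along the discriminant.
The exact effect-size formula is the one genuinely open design choice in
this procedure — published variants differ — and the direction is
cross-checked against scikit-learn's `LinearDiscriminantAnalysis`
coefficients on well-conditioned fixtures.

## Prevalence dynamics

Prevalence is the fraction of a timepoint group's retained samples where a
feature exceeds the detection threshold (default 0, flag-adjustable).
Denominators are per-timepoint retained counts — they differ when samples
were dropped — and both are reported. Bands split at 1/3 and 2/3 (low
< 1/3, high > 2/3, cut points closed on the low side). Prevalence changes
are reported descriptively and ranked by |Δ| (ties broken lexicographically
by feature id); no test is attached.

## Correlation screens

Every (feature × covariate) pair at one timepoint — optionally within a
subject subset such as the large-shift group — is one screen and one BH
family; degenerate pairs (constant vectors, fewer than 3 complete pairs)
are excluded before correction and flagged in the output. Missing covariate
values are handled pairwise-complete with n recorded per pair. BH
adjustment delegates to statsmodels' `multipletests(fdr_bh)`. Defining the
family per screen invocation is the most reproducible reading of "adjusted
p-values" when the alternative family definitions (per covariate, per data
block, global) are all defensible; the family size is recorded in the
output header so a reader can re-correct differently.

## Synthetic paired cohorts

The generator emulates the statistical structure of a ~17-subject paired
expedition cohort:

* **Rank-abundance shape** — species pool intensities are log-normal with
  σ = 2, giving the long right tail of gut metagenomes (a Dirichlet of any
  reasonable concentration is too even). Between-subject spread is a
  per-feature log-normal factor (σ = 1 by default).
* **Richness control** — per-sample presence is drawn by weighted
  without-replacement sampling (Gumbel top-k on abundance-dependent
  detection weights), hitting a per-subject richness count drawn around the
  cohort target. Defaults mirror the emulated study's per-sample detected
  features: species 200 ± 69 before and 179 ± 53 after, pathways 76 ± 8 and
  77 ± 8 (the between-subject SDs are taken as the spread of the count
  draw; the shape of that distribution is otherwise a free choice and is
  normal, rounded and clipped). When pre and post targets are equal the
  post presence mask reuses the pre mask, so a cohort with no planted
  effects and zero shift heterogeneity yields exactly identical pre/post
  samples — matched Bray-Curtis 0 — a property the tests rely on.
* **Within-subject shift** — post log-abundances are the subject's own
  baseline plus `s_i · ε`, ε ~ N(0,1) per feature, with
  `s_i = shift_heterogeneity × u_i` and `u_i` log-normal (σ = 0.5) or
  user-supplied (e.g. bimodal for classification benchmarks). The default
  `shift_heterogeneity = 1.0` was calibrated once so the default cohort's
  median matched Bray-Curtis lands around 0.36, the realized median of the
  emulated study; the median increases monotonically in the parameter.
* **Planted effects** — enrichment multiplies one group's values by the
  fold change before closure; prevalence planting sets exactly
  round(p·n) subjects present (deterministic at the extremes, so a plan of
  1.0 realizes 1.0 regardless of dropout); covariate coupling goes through
  a Gaussian copula on rank-derived normal scores with
  `ρ_Gauss = 2 sin(π ρ_S / 6)`, so the planted ρ is on the Spearman scale
  the downstream screen estimates. Sample dropout (whole samples, uniform
  at random — emulating profiling rejects) happens last.
* **Closure** — taxon samples sum to 100 (±1e-6), pathway samples to 10⁶.
  Everything is a pure function of (spec, seed): one `numpy` Generator is
  threaded through all draws, and identical specs give bit-identical
  tables.

`realized_effects()` recomputes what each planted effect actually looks
like in the finite cohort (realized fold, prevalence, sample ρ); recovery
tests compare discoveries against these realized values, not the nominal
plan.

What the generator does **not** model: phylogenetic or co-occurrence
correlation between features, sequencing depth and compression artefacts,
compositional spurious-correlation structure beyond closure itself, or
longitudinal drift beyond a single pre→post step. Passing benchmarks
therefore demonstrate correctness and calibration of the statistics under
a realistic marginal structure — not robustness to every dependence
pattern of real gut metagenomes.

## Standard benchmarks

* **Enrichment recovery** — 300 species, 5 planted at fold 4, 10 subjects
  per group, low noise (σ_subject = 0.5, shift 0.15), 20 seeds; planted
  features are drawn from the upper-middle abundance range of a probe run
  because a fold change on a feature below the detection floor is
  unrecoverable by construction. Measured sensitivity ≥ 0.8 with FDR
  ≤ 0.25; empirically ≈ 0.94 and ≈ 0.
* **Null calibration** — two independent groups of 10 baseline samples with
  no planted effects: the Kruskal gate fires at ≈ the nominal 5%.
* **Correlation recovery** — one ρ = 0.95 coupling (planted on a fully
  detected feature; zeros tie the ranks and cap the attainable ρ) among 200
  nulls at n = 17, recovered at q < 0.05 in ≥ 18 of 20 seeds; all-null
  screens yield ≥ 1 discovery in well under 10% of seeds.
* **Responder classification** — bimodal subject shift scales (0.3 vs 2.0,
  8 + 8 subjects): median-split labels match ground truth with ≥ 0.9
  accuracy over 20 seeds.
* **PERMANOVA calibration** — 500 null cohorts (n = 16, 999 permutations):
  type-I error within 0.05 ± 0.03; two separated clusters give the minimum
  attainable p of 1/1000.

Problem sizes throughout (pool sizes, permutation counts, seed counts) are
chosen to estimate each property to useful Monte-Carlo precision while
keeping the full suite runnable in well under a minute per benchmark.

## Pipeline

`run_all` executes align → diversity → beta/matched/PERMANOVA → pre-vs-post
enrichment → paired signed-rank follow-up on flagged features → prevalence
→ responder classification → baseline contrasts and baseline enrichment →
configured correlation screens, writing one subdirectory per stage and a
`summary.json` that enumerates every parameter used (no silent defaults).
Each stage draws randomness from its own generator seeded by hashing the
master seed with the stage name, so stages reproduce independently of
execution order, and reruns with the same config are byte-identical.

## Known limitations

* The enrichment effect size is one member of a family of LEfSe-like
  scores; absolute score values are comparable within this package, not
  across implementations (the optional bootstrap mode narrows, but does not
  close, the gap to the original tool).
* PERMANOVA offers no subject-level blocking or strata; it is meant for
  between-subject contrasts.
* The correlation screens test marginal rank association only — no partial
  correlations and no compositional (e.g. CLR) transforms, which would be a
  different, stricter analysis.
* Exact Spearman enumeration is capped below n = 10; between 10 and ~25 the
  t approximation is used even though it is only adequate there, not exact.
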