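# Methods

This note records the models, conventions and numerical choices behind
commflux, and what the synthetic studies do and do not demonstrate.

## Abundance model and ecology statistics

Genus tables are samples × genera matrices of counts or row-normalized
proportions.  All group comparisons are nonparametric: two-sided Wilcoxon
rank-sum tests, exact for combined n ≤ 20 without ties and
normal-approximated with tie correction otherwise (scipy's automatic
policy).  The Shannon index is reported in nats (divide by ln 2 for bits);
richness counts strictly positive genera, so H ≤ ln(richness) with
equality on uniform support.

**PERMANOVA** uses Anderson's pseudo-F computed from pairwise squared
Bray–Curtis dissimilarities, with free (unstratified) label permutations.
Sampled mode requires a seed and reports p = (1 + #{F_perm ≥ F_obs}) /
(1 + n_perm); exhaustive mode enumerates every distinct label arrangement
and is exact (used for small cohorts and for verifying the sampled mode).
Perfectly separated groups give SS_within = 0; the statistic is reported
as +∞ and permutations that reproduce the same partition count as ties.

**PCoA** eigen-decomposes the Gower-centred −½ J D² J.  Negative
eigenvalues (non-Euclidean dissimilarities) are reported but never
returned as axes; a Cailliez correction is available behind a flag and off
by default.

**Permutation FDR.**  For feature g with observed p-value p_g and B label
permutations, q_g = median_b #{null p in permutation b ≤ p_g} /
max(1, #{observed p ≤ p_g}), clipped to [0, 1] and made monotone
non-decreasing in p by a running maximum in ascending-p order (the
conservative direction).  Null p-values use the tie-corrected normal
approximation without continuity correction so the whole permutation
stream vectorizes over features; column ranks are permutation-invariant
and computed once.  The median-based numerator is integer-granular: the
few strongest features are typically floored at q = 0 (ties), which is why
"smallest q" statements should be read tie-tolerantly.  Calibration is
verified by simulation (global-null mean fraction of features at q < 0.1
stays below 0.1), not by any distributional claim.

**Compartmentalization.**  A genus is "present" above a configurable
relative-abundance threshold (default 0: any detection).  Pooled Venn
counts use presence in ≥1 sample of the compartment–group; per-individual
shared percentage is 100·|oral_i ∩ faecal_i| / |oral_i ∪ faecal_i| and
group differences are tested by rank-sum.  Cross-compartment association
is the full Spearman matrix over subjects sampled in both compartments
(≥3 required); constant genera give rho = 0, p = 1.  Display stars follow
the conventional p < 0.05 / p < 0.01 thresholds but raw p-values are
always emitted.

## Community flux balance analysis

Per-taxon reconstructions are stoichiometric models with `internal` and
`extracellular` metabolite tags, bounded reactions in arbitrary flux
units, a linear objective, and exchange reactions touching exactly one
extracellular metabolite (coefficient −1; positive flux = secretion).

**Merge.**  Individuals get their own community model.  Genera are
selected cohort-wide at strictly > 1% relative abundance in at least one
individual.  For the modelled taxa of a sample, weights are the relative
abundances renormalized to sum to 1; the raw sum is recorded as
*coverage* (samples below a configurable floor are flagged, never
dropped).  Each taxon's metabolites are namespaced; its former exchange
reactions become taxon→pool transfer reactions onto a shared extracellular
pool (orientation preserved: positive = secretion into the pool), and one
community exchange reaction per pooled metabolite connects the pool to the
environment with medium bounds (−10, 1000) by default — no diet is
imposed.  All of a taxon's bounds and its objective contribution are
scaled by its weight.  Consequences used as test invariants: a single
taxon at weight 1 reproduces its solo optimum exactly; non-interacting
taxa are additive (community boundary flux = weight × solo flux); weights
are scale-invariant.

**Solving.**  LPs are solved with HiGHS via scipy.  Optimal FBA bases are
degenerate, so a parsimonious second stage minimizes Σ|v| with the primary
objective locked (tolerance 1e-9), making flux profiles deterministic.
Solutions must satisfy |S·v|∞ ≤ 1e-6; boundary fluxes are quantized at
1e-6 because sub-tolerance solver jitter is not signal and would otherwise
fabricate rank structure across samples.

**Bioavailability index.**  Boundary fluxes are signed, and a ratio across
a sign change is meaningless, so the index is
log2((|s_case| + ε) / (|s_control| + ε)) with pseudo-flux ε = 1e-6,
carrying the sign of the case summary; a separate *switch* flag marks
metabolites whose group summaries have opposite nonzero signs.  Group
summaries are means by default (medians behind a flag).  Significance
combines the rank-sum p with the permutation FDR at p < 0.05 and
FDR < 0.1.  Modelling is strictly per-individual; no pooled-group model is
provided.

## Classification

Logistic regression is fitted by Newton/IRLS with step-halving,
converging at max |score| < 1e-8 or 100 iterations.  Complete separation
is detected (log-likelihood at its supremum, or diverging coefficients
without score convergence) and flagged; separated coefficients are not
identified.  Stepwise selection starts from the intercept-only model,
scores every single addition and removal, and accepts the best move only
if it strictly decreases AIC = 2k − 2ℓ; the accepted trace is stored.
Features are z-scored before selection and the standardization is frozen
into the model; external validation never refits anything.  Wald p-values
of selected coefficients are reported for display only — they are
post-selection quantities and carry no inferential guarantee.  ROC curves
sweep distinct score thresholds with simultaneous steps on ties; AUC is
the trapezoidal area and equals the concordance fraction.  The default
operating point is Youden's J on the training curve.  Batch correction is
per-feature per-cohort mean-centering over the shared feature set.
t-SNE uses scikit-learn's exact implementation (default perplexity 10 for
small cohorts, 1000 iterations, mandatory seed) with the final KL
divergence reported.

Known behaviour worth stating plainly: at small n with strong effects,
maximum-likelihood stepwise selection often walks into complete separation
after two or three entries, after which no further feature can decrease
AIC; joint recovery of *all* planted features therefore plateaus well
below the per-feature inclusion rate (R's stepAIC behaves identically).
And because AIC admits a feature iff its likelihood-ratio statistic
exceeds 2 (null probability ≈ 0.157 per candidate), intercept-only
retention under a global null decays geometrically in the number of
candidates — AIC is a prediction criterion, not a test at conventional
levels.

## Synthetic data

Cohorts are Dirichlet-multinomial: group mean proportion vectors (random
gamma-based or explicitly specified), per-sample Dirichlet draws at a
concentration (default 200–300, a realistic 16S-like overdispersion) and
multinomial counts at Poisson depth (default 20,000 reads).  Planted
effects multiply or divide mean proportions *before* renormalization, so
realized fold changes are attenuated by compositional closure; recovery
expectations account for this.  Paired cohorts share genus names between
compartments: a target shared fraction f fixes the common-name count via
C = f(n_oral + n_faecal)/(1 + f), group differences are imposed by
suppressing co-presence beyond each group's count, and requested
cross-compartment correlations are induced by a per-subject latent factor.
Toy reconstructions couple each signature to the objective — secretion as
an obligate growth byproduct, consumption as an extra assimilation route —
so the signature survives parsimonious FBA; every generated model is
solved at generation time and construction fails loudly if infeasible or
wrong-signed.  Validation cohorts re-draw counts from an independent
substream of the same seed and add one fixed per-genus count offset to all
samples (a cohort-level location batch effect, removable by
mean-centering).  All randomness flows through named substreams of a
single seed.

What this emulates — compositionality, overdispersion, detection dropout,
paired structure, batch shifts — and what it does not: real 16S data have
taxonomic misclassification, library-size artefacts, and genuinely
structured (not gamma-exchangeable) abundance landscapes; real
reconstructions have thousands of coupled reactions whose community
behaviour is not additive.  Passing recovery tests shows the pipeline's
statistics and algebra are correct under known ground truth, not that any
particular real-data finding would replicate.

## Reference study conditions and problem sizes

The characterization studies fixed in `commflux.studies`: the secretion
study uses 10 taxa with five planted secretors at ~1.2% control-side
abundance each (so selection at the 1% threshold is exercised) doubled in
cases, n = 20 per group — the realized flux fold is ≈ 2/1.06 (log2 ≈
0.92).  The classifier study uses n = 40 with 3 informative features among
17 noise features at 1.0 sd per-feature shift, chosen from the Gaussian
closed form Φ(d√3/√2) to give a joint population AUC near 0.9, with a
validation batch shift of ~3 sd.  Simulation-based checks run at
moderated inner permutation counts (B = 100–200 against the pipeline
default of 1000) and replicate counts of 50–500 per property; these sizes
are the package's chosen desk-scale study conditions and are recorded in
each result's `n`.

## Limitations

- The community model is purely stoichiometric: no growth-rate coupling,
  dynamic FBA, flux sampling, or diet constraints.
- The permutation FDR is an estimator with integer granularity at small B;
  q-values near 0 are tied.
- Post-selection Wald p-values are descriptive; no selective inference is
  attempted.
- The SBML reader covers a Level-3 FBC subset (species compartments,
  bounds, objective) sufficient for AGORA/VMH-style files, not the full
  standard; the JSON dialect is canonical.
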