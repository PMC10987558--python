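# commflux

Dysbiosis statistics and abundance-weighted **community flux balance
analysis** for genus-level 16S cohorts, with a stepwise-AIC classifier of
disease status on the inferred metabolite fluxes.

The package is aimed at microbiome studies that compare a patient group
against healthy controls across body compartments (e.g. oral and faecal
samples) and want to go beyond taxonomy: from *which genera shifted* to
*which microbially derived metabolites should become more or less
available*, and finally to *can those metabolite fluxes discriminate
patients from controls in an independent cohort*.

## The method

Three layers, chained per individual:

1. **Community ecology.** On relative-abundance tables: Shannon index
   H = −Σᵢ pᵢ ln pᵢ and specific richness; Bray–Curtis dissimilarity
   D(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) with PERMANOVA (pseudo-F over label
   permutations, seeded or exhaustively enumerated) and PCoA; per-genus
   Wilcoxon rank-sum tests corrected by a SAM-style permutation FDR;
   oral↔faecal Spearman correlation matrices, shared-genus Venn summaries
   with per-individual shared percentages, age–diversity association, and
   qPCR ΔΔCt relative quantification (level = 2^−ΔΔCt).

2. **Community FBA.** Genera above 1% relative abundance in at least one
   individual are matched to per-taxon metabolic reconstructions. For each
   individual the reconstructions are merged into one community model: each
   taxon keeps a namespaced internal network, extracellular metabolites
   with identical ids are pooled, former exchange reactions become
   taxon→pool transfers, and every taxon's bounds and objective
   contribution are scaled by its renormalized relative abundance.  FBA
   (max c·v s.t. S·v = 0, lb ≤ v ≤ ub, with a parsimonious secondary
   minimization of Σ|v|) yields community boundary fluxes — positive = net
   secretion.  Per metabolite, the **bioavailability index** is the log2
   fold change of the group-summarized fluxes (magnitudes with a
   pseudo-flux; a *switch* flag marks production↔consumption reversals),
   tested by rank-sum + permutation FDR and filtered at p < 0.05 and
   FDR < 0.1.

3. **Discrimination.** Logistic regression fitted by Newton/IRLS with
   bidirectional stepwise selection minimizing AIC = 2k − 2ℓ from the
   intercept-only model; z-scored features with the training
   standardization frozen into the model; ROC/AUC with a Youden-J
   operating point; external validation applies the frozen model to an
   independent cohort after per-cohort mean-centering batch correction.
   t-SNE embeddings of flux profiles are provided for visual inspection.

A first-class synthetic-data module generates every input with planted
ground truth: Dirichlet-multinomial cohorts with fold-change effects,
paired compartments with controlled genus sharing and cross-compartment
coupling, toy reconstruction libraries whose taxa secrete or consume
signature metabolites (verified feasible at generation time), and
batch-shifted validation cohorts.

## Worked example

`examples/02_community_fba.py` plants a 2-fold case-side enrichment of five
secretor taxa and recovers the metabolite shifts:

```
Community models solved for 40 individuals
Mean coverage (abundance with a reconstruction): 100.00%

Bioavailability shifts passing p<0.05 & FDR<0.1 (5 metabolites):
       mean_case  mean_control  log2_fold_change   p_value  q_value
met00     0.1173       0.04982             1.235 8.597e-06        0
met01    0.09249        0.0598            0.6293  0.002561        0
met02     0.1161       0.05374             1.112 2.041e-05        0
met03     0.1201       0.06072            0.9837  2.69e-06        0
met04     0.1179       0.06451            0.8698 5.896e-05        0
```

Each planted metabolite's log2 fold change sits near +1 (the 2× secretion,
mildly attenuated by compositional closure) and passes the significance
filter.  `examples/03_classifier_validation.py` continues to the
classifier: stepwise selection finds the informative features (training
AUC 0.945) and the frozen model transfers to a batch-shifted independent
cohort at AUC 0.805.  The other examples cover the dysbiosis statistics
and the paired-compartment analyses.

A thin CLI mirrors the stages (`commflux simulate|diversity|diffabund|
crosstalk|permanova|fba|classify|run`); `commflux run --config cfg.yaml`
executes the whole pipeline with full provenance and bit-reproducible
outputs given the same seeds.

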