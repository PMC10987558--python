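"""Per-individual community FBA and the bioavailability index.

Builds a toy reconstruction library in which the first five taxa secrete a
signature metabolite as a growth byproduct, plants a 2-fold case-side
enrichment of those taxa, merges abundance-weighted community models per
individual, and converts the community boundary fluxes into per-metabolite
log2 fold changes with the p < 0.05 & FDR < 0.1 significance filter.
"""

import pandas as pd

from commflux import bioavailability, cohort_fluxes
from commflux.studies import secretion_recovery_study

table, truth, library = secretion_recovery_study(seed=7)

result = cohort_fluxes(table, library)
print(f"Community models solved for {len(result.profiles)} individuals")
print(f"Mean coverage (abundance with a reconstruction): {result.coverage.mean():.2%}")
print("\nBoundary fluxes of the first individuals (positive = net secretion):")
print(result.profiles.head(3).round(4).to_string())

groups = pd.Series(truth.sample_groups)
bio = bioavailability(result.profiles, groups, "MS", "HV", n_perm=500, seed=8)
sig = bio[bio["significant"]].sort_values("q_value")
print(f"\nBioavailability shifts passing p<0.05 & FDR<0.1 ({len(sig)} metabolites):")
print(sig[["mean_case", "mean_control", "log2_fold_change", "p_value", "q_value"]]
      .to_string(float_format="%.4g"))
print(f"\nPlanted directions: {truth.expected_bioavailability}")
print("A log2FC near +1 reflects the planted 2x secretion, mildly attenuated")
print("by compositional closure of the abundance weights.")
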