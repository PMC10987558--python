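"""Reference synthetic study conditions.

These fix, in one place, the planted-ground-truth scenarios on which the
package's recovery behaviour is characterized: a two-group cohort whose
case group doubles the abundance of five secretor taxa (so five signature
metabolites must shift bioavailability upward), and a classifier study
with three informative flux features among noise, including an
independent batch-shifted validation cohort.  The same conditions are used
by the test suite and by the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import MetabolicReconstruction
from .abundance import AbundanceTable
from .synthetic import (
    CohortSpec,
    ModelLibrarySpec,
    SyntheticTruth,
    expected_flux_directions,
    generate_cohort,
    generate_model_library,
    substream,
)

#: secretion-recovery study: 10 taxa, 5 planted 2x secretors at ~1.2% each
N_TAXA = 10
N_PLANTED = 5
PLANTED_FOLD = 2.0
PLANTED_BASE = 0.012
N_PER_GROUP = 20
READ_DEPTH = 20_000
DISPERSION = 300.0


def secretion_recovery_study(
    seed: int,
) -> tuple[AbundanceTable, SyntheticTruth, dict[str, MetabolicReconstruction]]:
    """Cohort + toy library with five planted case-side 2x secretions.

    Planted taxa sit near the 1% selection threshold on the control side
    (~1.2% mean) so the study also exercises taxon selection; the realized
    flux fold change is attenuated only mildly by compositional closure
    (2 / 1.06 ~ 1.9, log2 ~ 0.92).
    """
    taxa = [f"t{i:02d}" for i in range(N_TAXA)]
    planted = taxa[:N_PLANTED]
    signature = {t: (f"met{i:02d}", "secrete") for i, t in enumerate(planted)}
    rest = (1.0 - N_PLANTED * PLANTED_BASE) / (N_TAXA - N_PLANTED)
    base = [PLANTED_BASE] * N_PLANTED + [rest] * (N_TAXA - N_PLANTED)
    spec = CohortSpec(
        n_per_group=N_PER_GROUP,
        n_genera=N_TAXA,
        genus_ids=taxa,
        planted_genera=[(t, "up", PLANTED_FOLD) for t in planted],
        base_proportions=base,
        dispersion=DISPERSION,
        read_depth=READ_DEPTH,
        seed=seed,
    )
    table, truth = generate_cohort(spec)
    library = {
        m.taxon_id: m
        for m in generate_model_library(
            ModelLibrarySpec(
                n_taxa=N_TAXA,
                n_extracellular_metabolites=N_TAXA,
                signature_map=signature,
                seed=seed,
            )
        )
    }
    truth.expected_bioavailability = expected_flux_directions(
        spec.planted_genera, signature
    )
    truth.informative_features = sorted(truth.expected_bioavailability)
    return table, truth, library


#: classifier study: 3 informative features among 17 noise, n = 20 + 20
N_FEATURES = 20
N_INFORMATIVE = 3
EFFECT_SIZE = 1.0  # per-feature shift in sd units; joint AUC ~ 0.9
BATCH_SHIFT = 3.0


def classifier_study(
    seed: int, n_per_group: int = 20, informative: bool = True
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Gaussian flux-like feature matrix with planted informative features."""
    rng = substream(seed, "classifier-train")
    y = np.repeat([0, 1], n_per_group)
    X = rng.normal(size=(2 * n_per_group, N_FEATURES))
    informative_ids = [f"flux{j:02d}" for j in range(N_INFORMATIVE)]
    cols = informative_ids + [f"noise{j:02d}" for j in range(N_FEATURES - N_INFORMATIVE)]
    if informative:
        X[:, :N_INFORMATIVE] += EFFECT_SIZE * y[:, None]
    return pd.DataFrame(X, columns=cols), y, (informative_ids if informative else [])


def classifier_validation_study(
    seed: int, n_per_group: int = 20, batch_shift: float = BATCH_SHIFT
) -> tuple[pd.DataFrame, np.ndarray]:
    """Independent cohort with the same planted signal plus a location batch
    effect of ``batch_shift`` sd units on every feature."""
    rng = substream(seed, "classifier-validation")
    y = np.repeat([0, 1], n_per_group)
    X = rng.normal(size=(2 * n_per_group, N_FEATURES))
    X[:, :N_INFORMATIVE] += EFFECT_SIZE * y[:, None]
    offsets = batch_shift * rng.uniform(0.5, 1.5, size=N_FEATURES)
    X = X + offsets[None, :]
    cols = [f"flux{j:02d}" for j in range(N_INFORMATIVE)] + [
        f"noise{j:02d}" for j in range(N_FEATURES - N_INFORMATIVE)
    ]
    return pd.DataFrame(X, columns=cols), y
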