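"""Per-individual abundance-weighted community models and their boundary fluxes.

The community construction mirrors how community FBA treats multi-taxon
consortia: every member keeps its own namespaced internal network, the
extracellular metabolites shared by name form a common pool, and each
taxon's former exchange reactions become taxon→pool transfers.  Per-taxon
reaction bounds and objective contributions are scaled by the taxon's
relative abundance (renormalized over the modelled taxa), so a taxon at
weight 1 reproduces its solo model exactly and non-interacting taxa
contribute additively to the community boundary fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import AbundanceTable, to_relative
from .fba import FluxSolution, fba
from .models import CommunityModel, MetabolicReconstruction, Reaction

#: default medium bounds of community exchange reactions (uptake 10, free secretion)
DEFAULT_MEDIUM = (-10.0, 1000.0)

#: taxon selection threshold: strictly more than 1% in at least one sample
SELECTION_THRESHOLD = 0.01


def select_taxa(table: AbundanceTable, threshold: float = SELECTION_THRESHOLD) -> set[str]:
    """Genera whose relative abundance exceeds ``threshold`` in >=1 sample.

    The inequality is strict: a genus at exactly the threshold everywhere is
    excluded.  Requires a normalized table.
    """
    if not table.normalized:
        raise ValueError("select_taxa requires a normalized table")
    maxima = table.values.max(axis=0)
    return {g for g, m in zip(table.genus_ids, maxima) if m > threshold}


def build_community_model(
    models: list[MetabolicReconstruction],
    abundances: dict[str, float],
    medium: tuple[float, float] = DEFAULT_MEDIUM,
) -> CommunityModel:
    """Merge taxon reconstructions into one abundance-weighted community model.

    ``abundances`` maps each modelled taxon to its (relative) abundance in
    the sample; weights used inside the model are renormalized to sum to 1,
    while ``coverage`` records the raw sum.
    """
    taxa = [m.taxon_id for m in models]
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon ids in model list")
    missing = [t for t in taxa if t not in abundances]
    if missing:
        raise ValueError(f"abundance missing for modelled taxa: {missing}")
    raw = np.array([abundances[t] for t in taxa], dtype=float)
    if (raw < 0).any():
        raise ValueError("abundances must be non-negative")
    total = raw.sum()
    if total <= 0:
        raise ValueError("zero total abundance over modelled taxa")
    weights = raw / total
    coverage = float(total)

    metabolites: dict[str, str] = {}
    reactions: list[Reaction] = []
    pooled: set[str] = set()
    for model, w in zip(models, weights):
        # every taxon metabolite gets a namespaced copy; extracellular ones
        # additionally appear as a shared pool metabolite under their own id,
        # reachable only through the taxon's former exchange reactions
        rename = {}
        for met, comp in model.metabolites.items():
            name = f"{model.taxon_id}__{met}"
            rename[met] = name
            metabolites[name] = "internal"
            if comp == "extracellular":
                pooled.add(met)
                metabolites[met] = "extracellular"
        for rxn in model.reactions:
            if rxn.exchange:
                # solo: met -> environment (positive flux = secretion); the
                # environment side becomes the shared pool, orientation and
                # bounds keep their meaning
                (met,) = rxn.stoich
                s = rxn.stoich[met]  # conventionally -1
                stoich = {rename[met]: s, met: -s}
            else:
                stoich = {rename[m]: coef for m, coef in rxn.stoich.items()}
            reactions.append(
                Reaction(
                    id=f"{model.taxon_id}__{rxn.id}",
                    stoich=stoich,
                    lb=rxn.lb * w,
                    ub=rxn.ub * w,
                    exchange=False,
                    objective=rxn.objective * w,
                )
            )
    exchange_ids = {}
    for met in sorted(pooled):
        ex_id = f"EX_{met}"
        exchange_ids[met] = ex_id
        reactions.append(
            Reaction(
                id=ex_id,
                stoich={met: -1.0},
                lb=medium[0],
                ub=medium[1],
                exchange=True,
            )
        )
    return CommunityModel(
        member_weights=dict(zip(taxa, weights)),
        coverage=coverage,
        metabolites=metabolites,
        reactions=reactions,
        exchange_ids=exchange_ids,
    )


@dataclass
class BoundaryFluxProfile:
    """Net community exchange flux per extracellular metabolite.

    Positive values are net secretion into the environment, negative values
    net consumption from it.
    """

    sample_id: str
    fluxes: dict[str, float]
    coverage: float = 1.0


def boundary_fluxes(
    solution: FluxSolution, model: CommunityModel, sample_id: str = ""
) -> BoundaryFluxProfile:
    """Extract the secretion-positive exchange fluxes from an optimal solution."""
    if solution.status != "optimal":
        raise ValueError(f"solution status is {solution.status!r}, not optimal")
    # quantize at the solver tolerance: sub-tolerance jitter is not signal
    # and would otherwise fabricate rank structure across samples
    fluxes = {
        met: round(float(solution.fluxes[ex_id]), 6)
        for met, ex_id in model.exchange_ids.items()
    }
    return BoundaryFluxProfile(sample_id, fluxes, model.coverage)


@dataclass
class CohortFluxResult:
    profiles: pd.DataFrame  # samples × metabolites, missing exchanges = 0
    coverage: pd.Series
    low_coverage: list[str] = field(default_factory=list)


def cohort_fluxes(
    table: AbundanceTable,
    model_library: dict[str, MetabolicReconstruction],
    min_coverage: float = 0.5,
    medium: tuple[float, float] = DEFAULT_MEDIUM,
    selection_threshold: float = SELECTION_THRESHOLD,
) -> CohortFluxResult:
    """One community model and boundary-flux profile per sample.

    Taxa are selected cohort-wide (> threshold in at least one sample), then
    each sample's community is built from the selected taxa that have a
    reconstruction and nonzero abundance in that sample.  Samples whose
    coverage falls below ``min_coverage`` are flagged, never dropped.
    """
    rel = to_relative(table)
    selected = select_taxa(rel, selection_threshold)
    modelled = sorted(selected & set(model_library))
    rows: list[dict[str, float]] = []
    coverages: dict[str, float] = {}
    low: list[str] = []
    for sample in rel.sample_ids:
        sample_ab = rel.data.loc[sample]
        taxa = [t for t in modelled if sample_ab[t] > 0]
        if not taxa:
            raise ValueError(f"sample {sample!r} has zero modelled taxa")
        cm = build_community_model(
            [model_library[t] for t in taxa],
            {t: float(sample_ab[t]) for t in taxa},
            medium=medium,
        )
        sol = fba(cm, direction="max")
        if sol.status != "optimal":
            raise RuntimeError(f"community model for {sample!r} is {sol.status}")
        profile = boundary_fluxes(sol, cm, sample)
        rows.append(profile.fluxes)
        coverages[sample] = cm.coverage
        if cm.coverage < min_coverage:
            low.append(sample)
    profiles = pd.DataFrame(rows, index=rel.sample_ids).fillna(0.0)
    return CohortFluxResult(profiles, pd.Series(coverages, name="coverage"), low)
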