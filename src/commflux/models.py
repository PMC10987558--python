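"""Stoichiometric model containers.

A :class:`MetabolicReconstruction` is a per-taxon constraint-based model:
metabolites tagged ``internal`` or ``extracellular``, reactions with a
sparse stoichiometry, flux bounds in arbitrary units, an objective, and an
exchange flag marking boundary reactions.  Exchange reactions touch exactly
one extracellular metabolite; with the conventional coefficient −1, a
positive flux is net secretion into the environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

COMPARTMENTS = ("internal", "extracellular")


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    lb: float
    ub: float
    exchange: bool = False
    objective: float = 0.0

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ValueError(f"reaction {self.id!r}: lb {self.lb} > ub {self.ub}")
        if not self.stoich:
            raise ValueError(f"reaction {self.id!r} has empty stoichiometry")


@dataclass
class MetabolicReconstruction:
    """Per-taxon stoichiometric model."""

    taxon_id: str
    metabolites: dict[str, str]  # metabolite id -> compartment tag
    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for met, comp in self.metabolites.items():
            if comp not in COMPARTMENTS:
                raise ValueError(
                    f"metabolite {met!r}: unknown compartment {comp!r}"
                )
        seen: set[str] = set()
        has_objective = False
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ValueError(f"duplicate reaction id {rxn.id!r}")
            seen.add(rxn.id)
            for met in rxn.stoich:
                if met not in self.metabolites:
                    raise ValueError(
                        f"reaction {rxn.id!r} references unknown metabolite {met!r}"
                    )
            if rxn.exchange:
                if len(rxn.stoich) != 1:
                    raise ValueError(
                        f"exchange reaction {rxn.id!r} must touch exactly one metabolite"
                    )
                (met,) = rxn.stoich
                if self.metabolites[met] != "extracellular":
                    raise ValueError(
                        f"exchange reaction {rxn.id!r} metabolite {met!r} "
                        "must be extracellular"
                    )
            if rxn.objective != 0:
                has_objective = True
        if not has_objective:
            raise ValueError(
                f"model {self.taxon_id!r} has no nonzero objective coefficient"
            )

    @property
    def extracellular_metabolites(self) -> list[str]:
        return [m for m, c in self.metabolites.items() if c == "extracellular"]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]


@dataclass
class CommunityModel:
    """Abundance-weighted merge of several taxon reconstructions.

    Internal metabolites and all taxon reactions are namespaced by taxon;
    extracellular metabolites with identical ids are pooled into a shared
    compartment balanced by one community exchange reaction per metabolite
    (positive flux = net secretion to the environment).  ``coverage`` is the
    sum of the un-renormalized member abundances; the weights stored here
    are renormalized to 1 over the modelled taxa.
    """

    member_weights: dict[str, float]
    coverage: float
    metabolites: dict[str, str]
    reactions: list[Reaction]
    exchange_ids: dict[str, str]  # pooled extracellular metabolite -> EX reaction id

    @property
    def extracellular_metabolites(self) -> list[str]:
        return [m for m, c in self.metabolites.items() if c == "extracellular"]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]
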