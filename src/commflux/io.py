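"""Readers and writers for the pipeline's plain-text formats.

Canonical formats are TSV for tables (abundance: samples in rows, genera in
columns, both labelled) and JSON for metabolic reconstructions and ground
truth.  The model dialect is::

    {"taxon_id": ..., "metabolites": [{"id": ..., "compartment": ...}, ...],
     "reactions": [{"id": ..., "stoich": {met: coef, ...}, "lb": ..., "ub": ...,
                    "exchange": bool, "objective": float}, ...]}

All validation happens at load time so later pipeline stages never see a
malformed object.  An optional reader for an SBML Level-3 FBC subset is
provided when libsbml is importable.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .abundance import AbundanceTable, METADATA_COLUMNS, validate_metadata
from .models import MetabolicReconstruction, Reaction


def read_abundance(path: str | Path) -> AbundanceTable:
    """Load a samples × genera TSV of non-negative counts or proportions."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric abundance value ({exc})") from exc
    neg = values.lt(0)
    if neg.any().any():
        col = neg.any().idxmax()
        row = neg[col].idxmax()
        raise ValueError(f"{path}: negative value at sample {row!r}, genus {col!r}")
    return AbundanceTable(values)


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", index_col="sample_id")
    return validate_metadata(md)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata[METADATA_COLUMNS].to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# model JSON dialect


def _schema_error(path, json_path: str, message: str) -> ValueError:
    return ValueError(f"{path}: at {json_path}: {message}")


def read_model(path: str | Path) -> MetabolicReconstruction:
    """Load one taxon reconstruction, enforcing all model invariants."""
    with open(path) as fh:
        raw = json.load(fh)
    for key in ("taxon_id", "metabolites", "reactions"):
        if key not in raw:
            raise _schema_error(path, "$", f"missing key {key!r}")
    mets: dict[str, str] = {}
    for i, m in enumerate(raw["metabolites"]):
        loc = f"$.metabolites[{i}]"
        if "id" not in m or "compartment" not in m:
            raise _schema_error(path, loc, "metabolite needs 'id' and 'compartment'")
        mets[m["id"]] = m["compartment"]
    rxns = []
    for i, r in enumerate(raw["reactions"]):
        loc = f"$.reactions[{i}]"
        for key in ("id", "stoich", "lb", "ub"):
            if key not in r:
                raise _schema_error(path, loc, f"missing key {key!r}")
        try:
            rxns.append(
                Reaction(
                    id=r["id"],
                    stoich={k: float(v) for k, v in r["stoich"].items()},
                    lb=float(r["lb"]),
                    ub=float(r["ub"]),
                    exchange=bool(r.get("exchange", False)),
                    objective=float(r.get("objective", 0.0)),
                )
            )
        except ValueError as exc:
            raise _schema_error(path, loc, str(exc)) from exc
    try:
        return MetabolicReconstruction(raw["taxon_id"], mets, rxns)
    except ValueError as exc:
        raise _schema_error(path, "$", str(exc)) from exc


def write_model(model: MetabolicReconstruction, path: str | Path) -> None:
    raw = {
        "taxon_id": model.taxon_id,
        "metabolites": [
            {"id": m, "compartment": c} for m, c in model.metabolites.items()
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": r.stoich,
                "lb": r.lb,
                "ub": r.ub,
                "exchange": r.exchange,
                "objective": r.objective,
            }
            for r in model.reactions
        ],
    }
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=2, sort_keys=True)


def read_model_library(directory: str | Path) -> dict[str, MetabolicReconstruction]:
    """Load every ``*.json`` model in a directory, keyed by taxon id."""
    library: dict[str, MetabolicReconstruction] = {}
    for path in sorted(Path(directory).glob("*.json")):
        model = read_model(path)
        if model.taxon_id in library:
            raise ValueError(f"duplicate taxon id {model.taxon_id!r} in {directory}")
        library[model.taxon_id] = model
    if not library:
        raise ValueError(f"no model JSON files found in {directory}")
    return library


def write_model_library(
    library: dict[str, MetabolicReconstruction] | list[MetabolicReconstruction],
    directory: str | Path,
) -> None:
    models = library.values() if isinstance(library, dict) else library
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for model in models:
        write_model(model, directory / f"{model.taxon_id}.json")


def read_sbml_model(path: str | Path) -> MetabolicReconstruction:
    """Read a subset of SBML Level-3 FBC (species, bounds, objective).

    Species in compartments named/ending 'e' are treated as extracellular;
    reactions touching a single extracellular species are exchanges.
    Requires libsbml.
    """
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("libsbml is required for SBML input") from exc
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ValueError(f"{path}: SBML parse errors")
    sbml = doc.getModel()
    fbc = sbml.getPlugin("fbc")
    mets = {}
    for i in range(sbml.getNumSpecies()):
        sp = sbml.getSpecies(i)
        comp = "extracellular" if sp.getCompartment().rstrip("0").endswith("e") else "internal"
        mets[sp.getId()] = comp
    objective = {}
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective()
        for i in range(active.getNumFluxObjectives()):
            fo = active.getFluxObjective(i)
            objective[fo.getReaction()] = fo.getCoefficient()
    params = {
        sbml.getParameter(i).getId(): sbml.getParameter(i).getValue()
        for i in range(sbml.getNumParameters())
    }
    rxns = []
    for i in range(sbml.getNumReactions()):
        rx = sbml.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rfbc = rx.getPlugin("fbc")
        lb = params.get(rfbc.getLowerFluxBound(), -1000.0) if rfbc else -1000.0
        ub = params.get(rfbc.getUpperFluxBound(), 1000.0) if rfbc else 1000.0
        exchange = len(stoich) == 1 and mets[next(iter(stoich))] == "extracellular"
        rxns.append(
            Reaction(rx.getId(), stoich, lb, ub, exchange, objective.get(rx.getId(), 0.0))
        )
    return MetabolicReconstruction(sbml.getId() or Path(path).stem, mets, rxns)
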