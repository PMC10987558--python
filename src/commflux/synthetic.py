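"""Synthetic cohorts, paired compartments, and toy metabolic model libraries.

Every generator is seeded through named substreams of one global seed and
emits data with a serializable ground truth, so downstream recovery tests
can read the truth without regenerating it.

Count model
-----------
Genus tables are Dirichlet-multinomial: per group a mean proportion vector,
per sample a Dirichlet draw around it (concentration = ``dispersion``) and a
multinomial with Poisson-distributed depth.  Planted effects multiply or
divide the mean proportion of chosen genera *before* renormalization;
closure attenuates the realized fold change slightly, which recovery tests
must tolerate.

Toy reconstructions
-------------------
Each taxon imports a shared extracellular substrate, converts it through a
cytosolic intermediate and maximizes a growth-like objective.  A taxon with
a ``secrete`` signature produces its signature metabolite as an obligate
byproduct of growth (so secretion survives parsimonious FBA); a ``consume``
signature taxon gains extra objective flux from importing its metabolite,
so consumption is forced at the optimum.  Generated models are verified by
solving them: an infeasible or wrong-signed construction raises instead of
being emitted.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .abundance import AbundanceTable, METADATA_COLUMNS
from .fba import fba
from .models import MetabolicReconstruction, Reaction

GROUPS = ("HV", "MS")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent named child stream of one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# specs


@dataclass
class CohortSpec:
    n_per_group: int = 20
    n_genera: int = 40
    planted_genera: list[tuple[str, str, float]] = field(default_factory=list)
    dispersion: float = 200.0
    read_depth: int = 20000
    seed: int = 0
    group_names: tuple[str, str] = GROUPS
    #: explicit genus namespace; defaults to g000..gNNN
    genus_ids: list[str] | None = None
    #: explicit group-1 mean proportions (normalized internally); random when None
    base_proportions: list[float] | None = None

    def __post_init__(self) -> None:
        if self.base_proportions is not None:
            if len(self.base_proportions) != self.n_genera:
                raise ValueError("base_proportions length must equal n_genera")
            if min(self.base_proportions) < 0 or sum(self.base_proportions) <= 0:
                raise ValueError("base_proportions must be non-negative with positive sum")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_genera < 1:
            raise ValueError("n_genera must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if self.genus_ids is not None and len(self.genus_ids) != self.n_genera:
            raise ValueError("genus_ids length must equal n_genera")
        names = set(self.genus_namespace())
        for genus, direction, fold in self.planted_genera:
            if genus not in names:
                raise ValueError(f"planted genus {genus!r} not in genus set")
            if direction not in ("up", "down"):
                raise ValueError(f"direction must be 'up'/'down', got {direction!r}")
            if fold <= 0:
                raise ValueError("fold effects must be > 0")

    def genus_namespace(self) -> list[str]:
        return list(self.genus_ids) if self.genus_ids else genus_names(self.n_genera)


@dataclass
class PairedCohortSpec:
    oral: CohortSpec
    faecal: CohortSpec
    shared_genus_fraction: dict[str, float] = field(
        default_factory=lambda: {"HV": 0.11, "MS": 0.17}
    )
    cross_correlation: list[tuple[str, str, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.oral.n_per_group != self.faecal.n_per_group:
            raise ValueError("oral and faecal compartments must pair per subject")
        for g, f in self.shared_genus_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"shared_genus_fraction[{g!r}] must be in [0,1]")
        # rebase both compartments onto the paired namespace (s*/o*/f* ids)
        oral_names, faecal_names = paired_genus_namespaces(
            self.oral.n_genera, self.faecal.n_genera, self.shared_genus_fraction
        )
        self.oral = CohortSpec(**{**asdict_spec(self.oral), "genus_ids": oral_names})
        self.faecal = CohortSpec(
            **{**asdict_spec(self.faecal), "genus_ids": faecal_names}
        )


def asdict_spec(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["planted_genera"] = [tuple(p) for p in d["planted_genera"]]
    d["group_names"] = tuple(d["group_names"])
    return d


def shared_genus_count(n_oral: int, n_faecal: int, fraction: float) -> int:
    """Shared-name count C with |∩|/|∪| = fraction: C = f·(nO+nF)/(1+f)."""
    return min(int(round(fraction * (n_oral + n_faecal) / (1.0 + fraction))), n_oral, n_faecal)


def paired_genus_namespaces(
    n_oral: int, n_faecal: int, fractions: dict[str, float]
) -> tuple[list[str], list[str]]:
    """Genus id lists for the two compartments; shared names come first."""
    c_max = max(
        (shared_genus_count(n_oral, n_faecal, f) for f in fractions.values()),
        default=0,
    )
    shared = [f"s{i:03d}" for i in range(c_max)]
    oral = shared + [f"o{i:03d}" for i in range(n_oral - c_max)]
    faecal = shared + [f"f{i:03d}" for i in range(n_faecal - c_max)]
    return oral, faecal


@dataclass
class ModelLibrarySpec:
    n_taxa: int = 10
    n_extracellular_metabolites: int = 8
    signature_map: dict[str, tuple[str, str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        mets = set(metabolite_names(self.n_extracellular_metabolites))
        for taxon, (met, mode) in self.signature_map.items():
            if met not in mets:
                raise ValueError(
                    f"signature metabolite {met!r} not in extracellular namespace"
                )
            if mode not in ("secrete", "consume"):
                raise ValueError(f"signature mode must be secrete/consume, got {mode!r}")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying generated data (JSON-serializable)."""

    planted_genera: list[tuple[str, str, float]] = field(default_factory=list)
    sample_groups: dict[str, str] = field(default_factory=dict)
    shared_genus_fraction: dict[str, float] = field(default_factory=dict)
    cross_correlation: list[tuple[str, str, int]] = field(default_factory=list)
    expected_bioavailability: dict[str, str] = field(default_factory=dict)
    informative_features: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        raw = json.loads(text)
        raw["planted_genera"] = [tuple(x) for x in raw.get("planted_genera", [])]
        raw["cross_correlation"] = [tuple(x) for x in raw.get("cross_correlation", [])]
        return cls(**raw)


def genus_names(n: int, prefix: str = "g") -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(n)]


def metabolite_names(n: int) -> list[str]:
    return [f"met{i:02d}" for i in range(n)]


# ---------------------------------------------------------------------------
# cohort generation


def _group_means(spec: CohortSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = spec.genus_namespace()
    if spec.base_proportions is not None:
        base = np.asarray(spec.base_proportions, dtype=float)
    else:
        base = rng.gamma(2.0, 1.0, size=spec.n_genera)
    m1 = base / base.sum()
    m2 = m1.copy()
    index = {g: i for i, g in enumerate(names)}
    for genus, direction, fold in spec.planted_genera:
        i = index[genus]
        m2[i] = m1[i] * fold if direction == "up" else m1[i] / fold
    if (m2 > 1.0).any():
        bad = names[int(np.argmax(m2))]
        raise ValueError(f"fold effect drives proportion of {bad!r} above 1")
    m2 = m2 / m2.sum()
    return m1, m2, names


def _sample_counts(
    means: np.ndarray, n: int, spec: CohortSpec, rng: np.random.Generator
) -> np.ndarray:
    """Dirichlet-multinomial rows around a mean proportion vector."""
    counts = np.zeros((n, means.size), dtype=int)
    support = means > 0
    alpha = spec.dispersion * means[support]
    for i in range(n):
        p = np.zeros(means.size)
        p[support] = rng.dirichlet(alpha)
        depth = max(1, rng.poisson(spec.read_depth))
        counts[i] = rng.multinomial(depth, p)
    return counts


def generate_cohort(spec: CohortSpec) -> tuple[AbundanceTable, SyntheticTruth]:
    """Two-group Dirichlet-multinomial genus table with planted effects."""
    rng_base = substream(spec.seed, "base-proportions")
    m1, m2, names = _group_means(spec, rng_base)
    rng_counts = substream(spec.seed, "counts")
    g1, g2 = spec.group_names
    c1 = _sample_counts(m1, spec.n_per_group, spec, rng_counts)
    c2 = _sample_counts(m2, spec.n_per_group, spec, rng_counts)
    ids = [f"{g1}_tr{i:02d}" for i in range(spec.n_per_group)] + [
        f"{g2}_tr{i:02d}" for i in range(spec.n_per_group)
    ]
    table = AbundanceTable(
        pd.DataFrame(np.vstack([c1, c2]), index=ids, columns=names)
    )
    truth = SyntheticTruth(
        planted_genera=list(spec.planted_genera),
        sample_groups={s: (g1 if s.startswith(g1) else g2) for s in ids},
    )
    return table, truth


def generate_validation_cohort(
    spec: CohortSpec, truth: SyntheticTruth, shift: float
) -> tuple[AbundanceTable, SyntheticTruth]:
    """Independent cohort with the same planted signal plus a batch effect.

    The batch effect is an additive cohort-level location shift: every
    sample receives the same per-genus count offset of expected magnitude
    ``shift · read_depth`` (uniform per-genus weights), emulating a
    systematic protocol difference removable by per-cohort mean-centering.
    """
    if [tuple(p) for p in truth.planted_genera] != [
        tuple(p) for p in spec.planted_genera
    ]:
        raise ValueError("validation spec must carry the training planted signal")
    rng_base = substream(spec.seed, "base-proportions")  # same genus landscape
    m1, m2, names = _group_means(spec, rng_base)
    rng_counts = substream(spec.seed, "validation-counts")
    g1, g2 = spec.group_names
    c1 = _sample_counts(m1, spec.n_per_group, spec, rng_counts)
    c2 = _sample_counts(m2, spec.n_per_group, spec, rng_counts)
    counts = np.vstack([c1, c2])
    if shift != 0:
        rng_batch = substream(spec.seed, "batch-offsets")
        offsets = np.round(shift * spec.read_depth * rng_batch.uniform(size=len(names)))
        counts = counts + offsets.astype(int)[None, :]
    ids = [f"{g1}_va{i:02d}" for i in range(spec.n_per_group)] + [
        f"{g2}_va{i:02d}" for i in range(spec.n_per_group)
    ]
    table = AbundanceTable(pd.DataFrame(counts, index=ids, columns=names))
    val_truth = SyntheticTruth(
        planted_genera=list(truth.planted_genera),
        sample_groups={s: (g1 if s.startswith(g1) else g2) for s in ids},
        expected_bioavailability=dict(truth.expected_bioavailability),
        informative_features=list(truth.informative_features),
    )
    return table, val_truth


# ---------------------------------------------------------------------------
# paired compartments


def generate_paired_cohort(
    spec: PairedCohortSpec,
) -> tuple[AbundanceTable, AbundanceTable, SyntheticTruth]:
    """Paired oral/faecal cohorts with controlled genus sharing and coupling.

    The shared-genus fraction f of a group fixes the number of genus names
    common to both compartments for that group's individuals via
    C = f·(n_oral + n_faecal)/(1 + f), so that with full detection the
    per-individual shared percentage |∩|/|∪| matches f.  Requested
    cross-compartment correlations are induced by a per-subject latent
    factor multiplying the two genera's Dirichlet means in the requested
    orientation.
    """
    nO, nF = spec.oral.n_genera, spec.faecal.n_genera
    fractions = spec.shared_genus_fraction
    shared_counts = {
        g: shared_genus_count(nO, nF, f) for g, f in fractions.items()
    }
    c_max = max(shared_counts.values(), default=0)
    shared_names = [f"s{i:03d}" for i in range(c_max)]
    oral_names = spec.oral.genus_namespace()
    faecal_names = spec.faecal.genus_namespace()
    for gO, gF, sign in spec.cross_correlation:
        if gO not in oral_names:
            raise ValueError(f"correlated oral genus {gO!r} absent")
        if gF not in faecal_names:
            raise ValueError(f"correlated faecal genus {gF!r} absent")

    def base_means(n: int, name: str) -> np.ndarray:
        rng = substream(spec.seed, name)
        b = rng.gamma(2.0, 1.0, size=n)
        return b / b.sum()

    mO = base_means(nO, "oral-base")
    mF = base_means(nF, "faecal-base")
    oral_idx = {g: i for i, g in enumerate(oral_names)}
    faecal_idx = {g: i for i, g in enumerate(faecal_names)}

    def planted(m: np.ndarray, cohort: CohortSpec, idx: dict[str, int], group: str) -> np.ndarray:
        out = m.copy()
        if group == cohort.group_names[1]:
            for genus, direction, fold in cohort.planted_genera:
                j = idx[genus]
                out[j] = out[j] * fold if direction == "up" else out[j] / fold
        return out / out.sum()

    rng_counts = substream(spec.seed, "paired-counts")
    rng_latent = substream(spec.seed, "coupling")
    groups = spec.oral.group_names
    n = spec.oral.n_per_group
    oral_rows, faecal_rows, ids_o, ids_f = [], [], [], []
    sample_groups: dict[str, str] = {}
    for group in groups:
        c_g = min(shared_counts.get(group, c_max), c_max)
        for i in range(n):
            subj = f"{group}_p{i:02d}"
            u = rng_latent.normal()
            mo = planted(mO, spec.oral, oral_idx, group)
            mf = planted(mF, spec.faecal, faecal_idx, group)
            # group-level compartmentalization: beyond c_g, faecal mass of
            # shared names is suppressed so the genus is not co-present
            mf = mf.copy()
            for j in range(c_g, c_max):
                mf[faecal_idx[shared_names[j]]] = 0.0
            for gO, gF, sign in spec.cross_correlation:
                mo[oral_idx[gO]] *= np.exp(0.8 * u)
                mf[faecal_idx[gF]] *= np.exp(0.8 * u * np.sign(sign))
            mo, mf = mo / mo.sum(), mf / mf.sum()
            co = _sample_counts(mo, 1, spec.oral, rng_counts)[0]
            cf = _sample_counts(mf, 1, spec.faecal, rng_counts)[0]
            oral_rows.append(co)
            faecal_rows.append(cf)
            ids_o.append(f"{subj}_oral")
            ids_f.append(f"{subj}_faecal")
            sample_groups[f"{subj}_oral"] = group
            sample_groups[f"{subj}_faecal"] = group
    oral = AbundanceTable(pd.DataFrame(oral_rows, index=ids_o, columns=oral_names))
    faecal = AbundanceTable(pd.DataFrame(faecal_rows, index=ids_f, columns=faecal_names))
    truth = SyntheticTruth(
        planted_genera=list(spec.oral.planted_genera),
        sample_groups=sample_groups,
        shared_genus_fraction=dict(fractions),
        cross_correlation=list(spec.cross_correlation),
    )
    return oral, faecal, truth


def paired_metadata(truth: SyntheticTruth, seed: int, cohort: str = "training") -> pd.DataFrame:
    """Metadata frame for generated samples (ages/sex are nuisance draws)."""
    rng = substream(seed, "metadata")
    rows = []
    for sample, group in truth.sample_groups.items():
        if sample.endswith("_oral") or sample.endswith("_faecal"):
            subject, compartment = sample.rsplit("_", 1)
        else:
            subject, compartment = sample, "oral"
        rows.append(
            {
                "sample_id": sample,
                "subject_id": subject,
                "group": group,
                "compartment": compartment,
                "age": float(rng.integers(20, 71)),
                "sex": rng.choice(["F", "M"]),
                "cohort": cohort,
            }
        )
    md = pd.DataFrame(rows).set_index("sample_id")
    # subjects keep one age/sex across compartments
    for subj, sub in md.groupby("subject_id"):
        md.loc[sub.index, "age"] = sub["age"].iloc[0]
        md.loc[sub.index, "sex"] = sub["sex"].iloc[0]
    return md[METADATA_COLUMNS]


# ---------------------------------------------------------------------------
# toy model libraries


def _toy_model(taxon: str, signature: tuple[str, str] | None) -> MetabolicReconstruction:
    mets = {"substrate": "extracellular", "A": "internal"}
    rxns = [
        Reaction("EX_substrate", {"substrate": -1.0}, -10.0, 1000.0, exchange=True),
        Reaction("uptake", {"substrate": -1.0, "A": 1.0}, 0.0, 1000.0),
    ]
    if signature is None:
        rxns.append(Reaction("growth", {"A": -1.0}, 0.0, 1000.0, objective=1.0))
    else:
        met, mode = signature
        mets[met] = "extracellular"
        rxns.append(Reaction(f"EX_{met}", {met: -1.0}, -10.0, 1000.0, exchange=True))
        if mode == "secrete":
            # signature metabolite is an obligate growth byproduct
            rxns.append(
                Reaction("growth", {"A": -1.0, met: 0.5}, 0.0, 1000.0, objective=1.0)
            )
        else:
            rxns.append(Reaction("assimilate", {met: -1.0, "A": 1.0}, 0.0, 1000.0))
            rxns.append(Reaction("growth", {"A": -1.0}, 0.0, 1000.0, objective=1.0))
    return MetabolicReconstruction(taxon_id=taxon, metabolites=mets, reactions=rxns)


def generate_model_library(spec: ModelLibrarySpec) -> list[MetabolicReconstruction]:
    """Toy reconstructions, each verified feasible with its signature active.

    Raises ``RuntimeError`` rather than emitting an infeasible model or one
    whose signature exchange flux has the wrong sign at the optimum.
    """
    taxa = [f"t{i:02d}" for i in range(spec.n_taxa)]
    unknown = [t for t in spec.signature_map if t not in taxa]
    if unknown:
        raise ValueError(f"signature_map names unknown taxa: {unknown}")
    library = []
    for taxon in taxa:
        model = _toy_model(taxon, spec.signature_map.get(taxon))
        sol = fba(model, direction="max")
        if sol.status != "optimal" or sol.objective_value is None or sol.objective_value <= 0:
            raise RuntimeError(f"generated model {taxon!r} is not viably feasible")
        if taxon in spec.signature_map:
            met, mode = spec.signature_map[taxon]
            flux = sol.fluxes[f"EX_{met}"]
            if mode == "secrete" and flux <= 0:
                raise RuntimeError(f"{taxon!r} fails to secrete {met!r}")
            if mode == "consume" and flux >= 0:
                raise RuntimeError(f"{taxon!r} fails to consume {met!r}")
        library.append(model)
    return library


def expected_flux_directions(
    planted_genera: list[tuple[str, str, float]],
    signature_map: dict[str, tuple[str, str]],
) -> dict[str, str]:
    """Expected case-vs-control direction of each signature metabolite's flux.

    An enriched secretor raises net secretion of its metabolite ("up"); an
    enriched consumer deepens net consumption ("down"); depleted taxa act in
    reverse.
    """
    directions: dict[str, str] = {}
    planted = {g: d for g, d, _ in planted_genera}
    for taxon, (met, mode) in signature_map.items():
        if taxon not in planted:
            continue
        up = planted[taxon] == "up"
        secretes = mode == "secrete"
        directions[met] = "up" if up == secretes else "down"
    return directions
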