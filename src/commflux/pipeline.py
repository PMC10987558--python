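"""End-to-end orchestration: ecology → community FBA → classification.

A :class:`PipelineConfig` names the inputs, thresholds, permutation counts
and seeds; :func:`run_pipeline` executes the stages in order, writes every
stage output as TSV/JSON next to a provenance record, and fails fast with
the stage name on any error.  Rerunning with the same config and seeds
reproduces all deterministic outputs bit-identically (the provenance file
carries wall-clock timings and is the only output excluded from that
guarantee).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import to_relative
from .bioavailability import bioavailability
from .classify import batch_correct, stepwise_aic, tsne_embed, validate_external
from .community import cohort_fluxes
from .ecology import bray_curtis, diff_abundance, pcoa, permanova, shannon
from .io import read_abundance, read_metadata, read_model_library


@dataclass
class PipelineConfig:
    abundance: str
    metadata: str
    models: str
    out_dir: str
    seed: int
    validation_abundance: str | None = None
    validation_metadata: str | None = None
    case_group: str = "MS"
    control_group: str = "HV"
    taxon_threshold: float = 0.01
    p_threshold: float = 0.05
    fdr_threshold: float = 0.1
    coverage_floor: float = 0.5
    n_perm: int = 1000
    n_perm_permanova: int = 1000
    median_summary: bool = False
    cailliez: bool = False
    batch_correction: bool = True
    tsne_perplexity: float = 10.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required")
        for name in ("taxon_threshold", "p_threshold", "fdr_threshold", "coverage_floor"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_perm < 1 or self.n_perm_permanova < 1:
            raise ValueError("permutation counts must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        return cls(**raw)


def load_config(path: str | Path) -> PipelineConfig:
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return PipelineConfig.from_dict(raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


@dataclass
class RunProvenance:
    config: dict
    version: str
    stage_seconds: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    complete: bool = False
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> RunProvenance:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = RunProvenance(config=config.to_dict(), version=__version__)
    stage = "setup"

    def emit(name: str) -> Path:
        prov.outputs.append(name)
        return out / name

    try:
        t0 = time.perf_counter()
        table = read_abundance(config.abundance)
        metadata = read_metadata(config.metadata)
        library = read_model_library(config.models)
        rel = to_relative(table)
        groups = metadata.loc[rel.sample_ids, "group"]
        labels = groups.to_numpy()
        prov.stage_seconds["setup"] = time.perf_counter() - t0

        stage = "ecology"
        t0 = time.perf_counter()
        div = shannon(rel)
        _write_tsv(div, emit("diversity.tsv"), "sample_id")
        dm = bray_curtis(rel)
        perm = permanova(dm, labels, config.n_perm_permanova, seed=config.seed)
        emit("permanova.json").write_text(
            json.dumps(
                {
                    "pseudo_F": perm.pseudo_F,
                    "p_value": perm.p_value,
                    "n_permutations": perm.n_permutations,
                    "seed": perm.seed,
                },
                indent=2,
                sort_keys=True,
            )
        )
        ord_res = pcoa(dm, k=2, cailliez=config.cailliez)
        _write_tsv(ord_res.coordinates, emit("pcoa.tsv"), "sample_id")
        da = diff_abundance(rel, labels, n_perm=config.n_perm, seed=config.seed)
        _write_tsv(da, emit("diffabund.tsv"), "genus")
        prov.stage_seconds["ecology"] = time.perf_counter() - t0

        stage = "community_fba"
        t0 = time.perf_counter()
        fluxes = cohort_fluxes(
            table,
            library,
            min_coverage=config.coverage_floor,
            selection_threshold=config.taxon_threshold,
        )
        _write_tsv(fluxes.profiles, emit("fluxes.tsv"), "sample_id")
        emit("coverage.json").write_text(
            json.dumps(
                {
                    "per_sample": fluxes.coverage.round(10).to_dict(),
                    "low_coverage_samples": fluxes.low_coverage,
                    "floor": config.coverage_floor,
                },
                indent=2,
                sort_keys=True,
            )
        )
        for s in fluxes.low_coverage:
            prov.warnings.append(f"coverage below floor for sample {s}")
        bio = bioavailability(
            fluxes.profiles,
            groups,
            config.case_group,
            config.control_group,
            n_perm=config.n_perm,
            seed=config.seed,
            summary="median" if config.median_summary else "mean",
        )
        _write_tsv(bio, emit("bioavailability.tsv"), "metabolite")
        prov.stage_seconds["community_fba"] = time.perf_counter() - t0

        stage = "discriminate"
        t0 = time.perf_counter()
        train_X = fluxes.profiles
        y = (groups.loc[train_X.index] == config.case_group).astype(int).to_numpy()
        keep = groups.loc[train_X.index].isin([config.case_group, config.control_group])
        train_X = train_X.loc[keep.to_numpy()]
        y = y[keep.to_numpy()]
        if len(train_X) > 3 * config.tsne_perplexity:
            emb = tsne_embed(
                train_X, perplexity=config.tsne_perplexity, seed=config.seed
            )
            _write_tsv(emb.coordinates, emit("tsne.tsv"), "sample_id")
        else:
            prov.warnings.append("cohort too small for t-SNE at configured perplexity")

        val_X = None
        if config.validation_abundance and config.validation_metadata:
            val_table = read_abundance(config.validation_abundance)
            val_md = read_metadata(config.validation_metadata)
            val_fluxes = cohort_fluxes(
                val_table,
                library,
                min_coverage=config.coverage_floor,
                selection_threshold=config.taxon_threshold,
            )
            val_groups = val_md.loc[val_fluxes.profiles.index, "group"]
            vkeep = val_groups.isin([config.case_group, config.control_group])
            val_X = val_fluxes.profiles.loc[vkeep.to_numpy()]
            y_val = (val_groups[vkeep] == config.case_group).astype(int).to_numpy()
            if config.batch_correction:
                train_X, val_X = batch_correct(train_X, val_X)

        model = stepwise_aic(train_X, y)
        if model.separated:
            prov.warnings.append("complete separation in training fit")
        model_record = {
            "features": model.feature_ids,
            "intercept": model.intercept,
            "coefficients": dict(zip(model.feature_ids, model.coefficients.tolist())),
            "wald_p": model.wald_p,
            "aic": model.aic,
            "log_likelihood": model.log_likelihood,
            "standardization": {
                f: list(v) for f, v in model.standardization.items()
            },
            "operating_threshold": model.operating_threshold,
            "train_auc": model.train_auc,
            "step_trace": model.step_trace,
        }
        emit("classifier.json").write_text(
            json.dumps(model_record, indent=2, sort_keys=True)
        )
        if val_X is not None:
            val = validate_external(model, val_X, y_val)
            emit("validation.json").write_text(
                json.dumps(
                    {
                        "auc": val.auc,
                        "sensitivity": val.sensitivity,
                        "specificity": val.specificity,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            _write_tsv(
                pd.DataFrame({"fpr": val.roc.fpr, "tpr": val.roc.tpr}),
                emit("validation_roc.tsv"),
                "point",
            )
        prov.stage_seconds["discriminate"] = time.perf_counter() - t0
        prov.complete = True
    except Exception as exc:
        prov.failed_stage = stage
        prov.warnings.append(f"stage {stage} failed: {exc}")
        prov.write(out / "provenance.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    prov.write(out / "provenance.json")
    return prov
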