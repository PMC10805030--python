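"""End-to-end orchestration: simulate or ingest -> preprocess -> split ->
select -> refit -> score -> evaluate -> report.

Every run writes a JSON manifest with the config snapshot, seed, per-stage
bookkeeping, and a content hash for each output file, so that a rerun with
the same seed can be checked for bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import CombinedModelError
from .omics_io import (
    CohortMetadata,
    Layer,
    OmicLayerTable,
    align,
    read_feature_table,
    read_metadata,
    write_feature_table,
    write_metadata,
)
from .penalized_glmm import (
    MixedModelSpec,
    build_model_data,
    lambda_grid,
    lasso_path,
    refit_glmm,
    select_lambda_elbow,
)
from .preprocess import (
    LayerConfig,
    apply_preprocess,
    default_layer_config,
    run_preprocess,
)
from .reporting import selection_percent
from .risk_scores import (
    ScoreModel,
    average_by_participant,
    build_score_model,
    compute_scores,
    fit_baseline,
    make_split,
    standardize,
)
from .evaluation import evaluate_layer, fit_combined, leave_one_omic_out, roc_auc
from .synthetic_cohort import SimulationDesign, hmp2_like_design, simulate_cohort

logger = logging.getLogger(__name__)

# named RNG substreams fanned out from the master seed
_SUBSTREAMS = {"simulate": 0, "collinearity": 1, "solver": 2, "split": 3}


def substream_seed(master_seed: int, name: str) -> int:
    h = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class AnalysisConfig:
    """Run-level configuration with the documented defaults."""

    seed: int = 0
    n_validation: int = 30
    lambda_points: int = 15
    lambda_min_ratio: float = 0.01
    filter_scope: str = "train"  # filters fit on train only, or "all"
    standardize_scope: str = "train"  # score constants from train, or "pooled"
    adjusted_evaluation: bool = True  # diagnosis ~ score + age + sex
    layer_configs: dict[str, LayerConfig] = field(default_factory=dict)
    covariates: tuple = ("age", "sex", "race", "antibiotic_use")
    random_factors: tuple = ("site", "participant_id")

    def layer_config(self, layer: Layer) -> LayerConfig:
        return self.layer_configs.get(layer.value, default_layer_config(layer))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        layer_cfgs = {
            k: LayerConfig(**v) for k, v in raw.pop("layer_configs", {}).items()
        }
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.layer_configs = layer_cfgs
        return cfg

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_validation": self.n_validation,
            "lambda_points": self.lambda_points,
            "lambda_min_ratio": self.lambda_min_ratio,
            "filter_scope": self.filter_scope,
            "standardize_scope": self.standardize_scope,
            "adjusted_evaluation": self.adjusted_evaluation,
            "covariates": list(self.covariates),
            "random_factors": list(self.random_factors),
        }


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)
    files: dict[str, str] = field(default_factory=dict)

    def add_stage(self, name: str, seconds: float, **info) -> None:
        self.stages.append({"name": name, "wall_seconds": round(seconds, 3), **info})

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
            "files": self.files,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _participant_covariates(meta: CohortMetadata) -> pd.DataFrame:
    """Participant-level age and numeric sex (male=1) for evaluation models."""
    per = meta.data.groupby("participant_id").first()
    return pd.DataFrame(
        {"age": per["age"].astype(float), "sex": (per["sex"] == "male").astype(float)}
    )


@dataclass
class LayerRunResult:
    layer: Layer
    filter_report: dict
    n_selected: int
    selected: list[str]
    selection_percent: Optional[float]
    lam: float
    score_model: Optional[ScoreModel]
    validation_scores: Optional[pd.DataFrame]  # participant-level
    evaluation: Optional[dict]


def _degenerate_score_model(layer: Layer, transform: str) -> ScoreModel:
    # zero selected features: the score is identically 0 and discriminates
    # nothing; keep the pipeline total with an affine-identity model
    return ScoreModel(
        layer=layer, feature_ids=[], weights=np.zeros(0), mean=0.0, sd=1.0,
        transform=transform, provenance={"degenerate": True},
    )


def run_layer(
    layer: Layer,
    table: OmicLayerTable,
    meta: CohortMetadata,
    train_participants: list[str],
    config: AnalysisConfig,
) -> LayerRunResult:
    """Preprocess, select, refit and score one omic layer."""
    lcfg = config.layer_config(layer)
    mdf = meta.data
    train_samples = set(
        mdf.loc[mdf["participant_id"].isin(train_participants), "sample_id"]
    )
    coll_seed = substream_seed(config.seed, f"collinearity:{layer.value}")

    present = table.sample_ids
    tr_ids = [s for s in present if s in train_samples]
    va_ids = [s for s in present if s not in train_samples]
    if config.filter_scope == "train":
        train_proc, report = run_preprocess(
            table.subset_samples(tr_ids), lcfg, seed=coll_seed
        )
        kept = train_proc.feature_ids
        val_proc = (
            apply_preprocess(table.subset_samples(va_ids), lcfg, kept)
            if va_ids
            else None
        )
    else:
        all_proc, report = run_preprocess(table, lcfg, seed=coll_seed)
        kept = all_proc.feature_ids
        train_proc = all_proc.subset_samples(tr_ids)
        val_proc = all_proc.subset_samples(va_ids) if va_ids else None

    spec = MixedModelSpec(
        feature_ids=kept,
        covariates=config.covariates,
        random_factors=config.random_factors,
    )
    meta_train = meta.subset_samples(tr_ids)
    data = build_model_data(train_proc, meta_train, spec)
    grid = lambda_grid(
        spec, data, n_points=config.lambda_points,
        min_ratio=config.lambda_min_ratio,
    )
    path = lasso_path(spec, data, grid)
    lam = select_lambda_elbow(path)
    entry = path.entries[int(np.argmin(np.abs(path.grid - lam)))]
    selected = entry.selected
    logger.info(
        "%s: %d features in, %d pass QC, %d selected at lambda=%.4g",
        layer.value, report.features_in, report.features_out,
        len(selected), lam,
    )

    refit = refit_glmm(spec, data, selected)
    provenance = {
        "lambda": lam, "seed": config.seed,
        "filter_features_out": report.features_out,
    }
    if selected:
        model = build_score_model(refit, train_proc, provenance=provenance)
        if config.standardize_scope == "pooled" and val_proc is not None:
            pooled_raw = pd.concat(
                [
                    pd.Series(
                        t.data[model.feature_ids].to_numpy() @ model.weights,
                        index=t.data.index,
                    )
                    for t in (train_proc, val_proc)
                ]
            )
            (model.mean, model.sd), _ = standardize(pooled_raw)
    else:
        model = _degenerate_score_model(layer, train_proc.transform)

    val_scores = None
    evaluation = None
    if val_proc is not None and val_proc.n_samples:
        sample_scores = compute_scores(val_proc, model)
        val_scores = average_by_participant(sample_scores, meta)
        labels = meta.participant_labels().reindex(val_scores.index)
        if labels.nunique() == 2:
            covs = _participant_covariates(meta).reindex(val_scores.index)
            evaluation = evaluate_layer(
                val_scores["score"], labels, covs,
                adjusted=config.adjusted_evaluation, label=layer.value,
            ).to_dict()

    sel_pct = (
        selection_percent(len(selected), report.features_out)
        if report.features_out
        else None
    )
    return LayerRunResult(
        layer=layer,
        filter_report=report.to_dict(),
        n_selected=len(selected),
        selected=selected,
        selection_percent=sel_pct,
        lam=lam,
        score_model=model,
        validation_scores=val_scores,
        evaluation=evaluation,
    )


def run_all(
    config: AnalysisConfig,
    out_dir: str | Path,
    design: Optional[SimulationDesign] = None,
    tables: Optional[Mapping[Layer, OmicLayerTable]] = None,
    meta: Optional[CohortMetadata] = None,
) -> RunManifest:
    """Execute the full analysis and write all outputs under ``out_dir``.

    Either a simulation design or pre-loaded tables + metadata must be
    given.  Single-layer evaluations run for every layer; the combined
    multi-omic model runs only when all four layers are present, over
    validation samples carrying all four.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(), seed=config.seed, version=__version__
    )

    t0 = time.perf_counter()
    if tables is None or meta is None:
        if design is None:
            design = hmp2_like_design(seed=substream_seed(config.seed, "simulate"))
        tables, meta, truth = simulate_cohort(design)
        (out / "truth.json").write_text(
            json.dumps(truth.to_dict(), indent=2, sort_keys=True)
        )
        manifest.add_stage(
            "simulate", time.perf_counter() - t0,
            n_participants=design.n_participants,
            layers=[l.value for l in tables],
        )
    tables = {Layer(k): v for k, v in tables.items()}
    write_metadata(meta, out / "metadata.tsv")

    t0 = time.perf_counter()
    tables = {layer: align(t, meta) for layer, t in tables.items()}
    inventories = {layer.value: t.sample_ids for layer, t in tables.items()}
    split = make_split(meta, inventories, config.n_validation)
    split.assignment.rename("assignment").to_csv(
        out / "split.tsv", sep="\t", index_label="participant_id"
    )
    manifest.add_stage(
        "split", time.perf_counter() - t0,
        n_validation=len(split.validation_participants),
        validation_percent=split.validation_fraction_percent(),
    )

    train_participants = split.train_participants
    layer_results: dict[Layer, LayerRunResult] = {}
    for layer, table in sorted(tables.items(), key=lambda kv: kv[0].value):
        t0 = time.perf_counter()
        res = run_layer(layer, table, meta, train_participants, config)
        layer_results[layer] = res
        ldir = out / layer.value
        ldir.mkdir(exist_ok=True)
        (ldir / "filter_report.json").write_text(
            json.dumps(res.filter_report, indent=2, sort_keys=True)
        )
        if res.score_model is not None:
            res.score_model.to_json(ldir / "score_model.json")
        if res.validation_scores is not None:
            res.validation_scores.to_csv(
                ldir / "validation_scores.tsv", sep="\t",
                index_label="participant_id",
            )
        payload = {
            "selected": res.selected,
            "n_selected": res.n_selected,
            "selection_percent": res.selection_percent,
            "lambda": res.lam,
            "evaluation": res.evaluation,
        }
        (ldir / "selection.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True)
        )
        manifest.add_stage(
            f"layer:{layer.value}", time.perf_counter() - t0,
            features_in=res.filter_report["stages"][0]["features_in"],
            features_out=res.filter_report["stages"][-1]["features_out"],
            n_selected=res.n_selected,
        )

    # metadata-only baseline, evaluated on validation participants
    t0 = time.perf_counter()
    meta_train = meta.subset_participants(train_participants)
    meta_val = meta.subset_participants(split.validation_participants)
    baseline = fit_baseline(
        meta_train, covariates=config.covariates,
        random_factors=config.random_factors,
    )
    base_pred = baseline.predict_participants(meta_val)
    base_labels = meta.participant_labels().reindex(base_pred.index)
    baseline_eval = None
    if base_labels.nunique() == 2:
        auc, ci = roc_auc(base_pred.to_numpy(), base_labels.to_numpy())
        baseline_eval = {"auc": auc, "auc_ci": list(ci)}
    (out / "baseline.json").write_text(
        json.dumps(baseline_eval, indent=2, sort_keys=True)
    )
    manifest.add_stage("baseline", time.perf_counter() - t0)

    # combined multi-omic model over complete-4-omic validation samples
    t0 = time.perf_counter()
    combined_payload = None
    if len(tables) == 4:
        combined_payload = _run_combined(
            tables, meta, split.validation_participants, layer_results, config
        )
    else:
        warnings.warn("combined stage skipped: fewer than four layers")
    (out / "combined.json").write_text(
        json.dumps(combined_payload, indent=2, sort_keys=True)
    )
    manifest.add_stage("combined", time.perf_counter() - t0,
                       skipped=combined_payload is None)

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.files[str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True)
    )
    return manifest


def _run_combined(
    tables: Mapping[Layer, OmicLayerTable],
    meta: CohortMetadata,
    validation_participants: list[str],
    layer_results: Mapping[Layer, LayerRunResult],
    config: AnalysisConfig,
) -> Optional[dict]:
    """Average each layer's standardized scores over the validation samples
    that carry all four layers, then fit the combined logistic model."""
    mdf = meta.data
    val_samples = mdf.loc[
        mdf["participant_id"].isin(validation_participants), "sample_id"
    ]
    complete = [
        s for s in val_samples
        if all(s in set(t.sample_ids) for t in tables.values())
    ]
    if not complete:
        warnings.warn("no complete-4-omic validation samples; combined skipped")
        return None
    per_layer = {}
    for layer, table in tables.items():
        res = layer_results[layer]
        model = res.score_model
        if model is None:
            return None
        lcfg = config.layer_config(layer)
        proc = apply_preprocess(
            table.subset_samples(complete), lcfg, model.feature_ids
        )
        ss = compute_scores(proc, model)
        per_layer[layer.value] = average_by_participant(ss, meta)["score"]
    scores = pd.DataFrame(per_layer)
    labels = meta.participant_labels().reindex(scores.index)
    if labels.nunique() < 2:
        warnings.warn("combined skipped: single class among complete samples")
        return None
    covs = _participant_covariates(meta).reindex(scores.index)
    try:
        combined = fit_combined(scores, covs, labels)
        loo = leave_one_omic_out(scores, covs, labels)
    except CombinedModelError:
        return None
    return {
        "combined": combined.to_dict(),
        "score_correlations": combined.score_correlations.round(6).to_dict(),
        "leave_one_out": {
            k: {"r2_full": v.r2_full, "loglik": v.loglik_full}
            for k, v in loo.items()
        },
        "n_participants": int(len(scores)),
        "n_complete_samples": len(complete),
    }
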