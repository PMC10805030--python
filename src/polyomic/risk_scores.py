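"""Weighted-sum risk scores, score standardization, participant averaging,
the participant-level train/validation split, and metadata-only baselines.

A layer's risk score for sample i is the polygenic-score-style weighted sum

    score_i = beta_1 * feature_1,i + ... + beta_n * feature_n,i

over the selected features only; demographic covariates never contribute to
the score.  Raw scores are standardized (mean 0, SD 1) against the training
samples and averaged across each participant's longitudinal samples before
evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ScoringError, StandardizationError
from .omics_io import CohortMetadata, Layer, OmicLayerTable
from .penalized_glmm import (
    CovariateEncoder,
    GlmmFit,
    MixedModelSpec,
    ModelData,
    build_model_data,
    predict_linear,
    refit_glmm,
)


@dataclass
class ScoreModel:
    """A fitted per-layer score: selected features, refit weights, and the
    standardization constants of the training-set raw scores."""

    layer: Layer
    feature_ids: list[str]
    weights: np.ndarray
    mean: float
    sd: float
    transform: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.layer = Layer(self.layer)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.feature_ids):
            raise ValueError("weights length must match feature ids")
        if self.sd <= 0:
            raise StandardizationError("score SD constant must be > 0")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "layer": self.layer.value,
            "feature_ids": self.feature_ids,
            "weights": self.weights.tolist(),
            "mean": self.mean,
            "sd": self.sd,
            "transform": self.transform,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoreModel":
        d = json.loads(Path(path).read_text())
        return cls(
            layer=Layer(d["layer"]),
            feature_ids=d["feature_ids"],
            weights=np.array(d["weights"]),
            mean=d["mean"],
            sd=d["sd"],
            transform=d["transform"],
            provenance=d.get("provenance", {}),
        )


@dataclass
class SampleScores:
    layer: Layer
    scores: pd.DataFrame  # index sample_id; columns raw, standardized


@dataclass
class SplitAssignment:
    """Participant-level train/validation partition."""

    assignment: pd.Series  # participant_id -> "train" | "validation"
    complete_counts: pd.Series  # samples with all layers present
    incomplete_counts: pd.Series  # samples missing >= 1 layer

    @property
    def validation_participants(self) -> list[str]:
        return sorted(self.assignment[self.assignment == "validation"].index)

    @property
    def train_participants(self) -> list[str]:
        return sorted(self.assignment[self.assignment == "train"].index)

    def validation_fraction_percent(self, decimals: int = 0) -> float:
        n_val = int((self.assignment == "validation").sum())
        return round(100.0 * n_val / len(self.assignment), decimals)


def make_split(
    meta: CohortMetadata,
    layer_samples: Mapping[str, Iterable[str]],
    n_validation: int,
) -> SplitAssignment:
    """Choose the validation participants.

    Participants are ranked by (most samples with every omic layer present,
    fewest samples missing at least one layer, then participant id) and the
    top ``n_validation`` become the validation set; all of a participant's
    samples share its assignment, so no validation sample can enter
    training.
    """
    if n_validation <= 0:
        raise ValueError("n_validation must be positive")
    participants = meta.participants
    if n_validation >= len(participants):
        raise ValueError("n_validation must be smaller than the cohort")
    sets = {k: set(v) for k, v in layer_samples.items()}
    records = []
    for pid, grp in meta.data.groupby("participant_id"):
        sids = grp["sample_id"]
        complete = int(sids.map(lambda s: all(s in ss for ss in sets.values())).sum())
        records.append((pid, complete, len(sids) - complete))
    df = pd.DataFrame(records, columns=["participant_id", "complete", "incomplete"])
    df = df.sort_values(
        by=["complete", "incomplete", "participant_id"],
        ascending=[False, True, True],
    ).reset_index(drop=True)
    validation = set(df["participant_id"].iloc[:n_validation])
    assignment = pd.Series(
        {p: ("validation" if p in validation else "train") for p in participants}
    )
    return SplitAssignment(
        assignment=assignment,
        complete_counts=df.set_index("participant_id")["complete"],
        incomplete_counts=df.set_index("participant_id")["incomplete"],
    )


def standardize(
    raw: pd.Series, reference: Optional[pd.Series] = None
) -> tuple[tuple[float, float], pd.Series]:
    """z = (x - mean_ref) / sd_ref with the sample (n-1) SD of the reference."""
    ref = raw if reference is None else reference
    mean = float(ref.mean())
    sd = float(ref.std(ddof=1))
    if not np.isfinite(sd) or sd <= 0:
        raise StandardizationError("reference scores have zero variance")
    return (mean, sd), (raw - mean) / sd


def build_score_model(
    fit: GlmmFit,
    train_table: OmicLayerTable,
    provenance: Optional[dict] = None,
) -> ScoreModel:
    """Turn a refit into a ScoreModel, standardized against the training
    samples' raw scores."""
    weights = fit.feature_coefs.to_numpy()
    raw = pd.Series(
        train_table.data[fit.feature_ids].to_numpy() @ weights,
        index=train_table.data.index,
    )
    (mean, sd), _ = standardize(raw)
    return ScoreModel(
        layer=train_table.layer,
        feature_ids=list(fit.feature_ids),
        weights=weights,
        mean=mean,
        sd=sd,
        transform=train_table.transform,
        provenance=provenance or {},
    )


def compute_scores(table: OmicLayerTable, model: ScoreModel) -> SampleScores:
    """Weighted-sum raw scores plus the model-standardized scores.

    The table must be in the transform state the model was trained on and
    contain every model feature.  Covariates never contribute.
    """
    if table.transform != model.transform:
        raise ScoringError(
            f"table transform {table.transform!r} does not match model "
            f"transform {model.transform!r}"
        )
    missing = [f for f in model.feature_ids if f not in set(table.feature_ids)]
    if missing:
        raise ScoringError(f"table lacks model features: {missing}")
    raw = table.data[model.feature_ids].to_numpy() @ model.weights
    std = (raw - model.mean) / model.sd
    return SampleScores(
        layer=model.layer,
        scores=pd.DataFrame(
            {"raw": raw, "standardized": std}, index=table.data.index
        ),
    )


def average_by_participant(
    scores: SampleScores, meta: CohortMetadata
) -> pd.DataFrame:
    """Mean standardized score per participant across their scored samples.

    Returns a frame indexed by participant_id with columns ``score`` and
    ``n_samples``.
    """
    sample_to_part = meta.data.set_index("sample_id")["participant_id"]
    df = scores.scores.copy()
    df["participant_id"] = sample_to_part.reindex(df.index)
    if df["participant_id"].isna().any():
        missing = df.index[df["participant_id"].isna()].tolist()
        raise ScoringError(f"scored samples missing from metadata: {missing[:5]}")
    g = df.groupby("participant_id")["standardized"]
    return pd.DataFrame({"score": g.mean(), "n_samples": g.size()})


@dataclass
class BaselineModel:
    """Metadata-only mixed logistic model (no omic features)."""

    fit: GlmmFit
    encoder: CovariateEncoder

    def predict(self, meta: CohortMetadata) -> pd.Series:
        """Per-sample linear predictor from covariates + known site effects;
        no omic columns are ever consulted."""
        return predict_linear(self.fit, None, meta, self.encoder)

    def predict_participants(self, meta: CohortMetadata) -> pd.Series:
        eta = self.predict(meta)
        part = meta.data.set_index("sample_id")["participant_id"]
        return eta.groupby(part.reindex(eta.index)).mean()


def fit_baseline(
    meta_train: CohortMetadata,
    covariates: Sequence[str] = ("age", "sex", "race", "antibiotic_use"),
    random_factors: Sequence[str] = ("site", "participant_id"),
) -> BaselineModel:
    """Fit the covariate-only mixed logistic baseline on training metadata."""
    spec = MixedModelSpec(
        feature_ids=[], covariates=covariates, random_factors=random_factors
    )
    # a dummy zero-feature table over the training samples
    dummy = OmicLayerTable(
        Layer.MGN,
        pd.DataFrame(index=meta_train.sample_ids),
        transform="clr",
    )
    data = build_model_data(dummy, meta_train, spec)
    fit = refit_glmm(spec, data, selected=[])
    return BaselineModel(fit=fit, encoder=data.encoder)
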