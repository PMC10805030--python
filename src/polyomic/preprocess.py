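"""Per-layer normalization and feature filtering.

The compositional count layers (MGN, MTS, VRM) are centered log-ratio
transformed; metabolomic intensities are log10-transformed.  Features are
then filtered by presence (computed on the raw, pre-transform values),
pairwise collinearity, and post-transform standard deviation.  Each layer
has its own recipe:

  MGN: clr -> sd(1.0)
  MTS: clr -> collinearity(0.95) -> sd(1.0)
  VRM: clr -> presence(keep >= 5% of samples, on raw) -> sd(0.1)
  MBL: log10 -> presence(keep > 99% of samples, on raw)
       -> collinearity(0.95) -> sd(0.1)

The ``FilterReport`` records the bookkeeping of every stage (features in,
features out, removed ids) so the pipeline can emit statements like
"filtered MGN from 578 to 237 features" for any dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError, TransformStateError
from .omics_io import CLR, LOG10, RAW, Layer, OmicLayerTable


@dataclass
class FilterStage:
    name: str
    features_in: int
    features_out: int
    removed: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.features_in - self.features_out != len(self.removed):
            raise ValueError("stage counts do not match removed-id list")


@dataclass
class FilterReport:
    layer: Layer
    stages: list[FilterStage] = field(default_factory=list)
    seed: Optional[int] = None

    def add(self, stage: FilterStage) -> None:
        if self.stages and stage.features_in != self.stages[-1].features_out:
            raise ValueError(
                f"stage {stage.name} features_in={stage.features_in} does not chain "
                f"from previous features_out={self.stages[-1].features_out}"
            )
        self.stages.append(stage)

    @property
    def features_in(self) -> int:
        return self.stages[0].features_in if self.stages else 0

    @property
    def features_out(self) -> int:
        return self.stages[-1].features_out if self.stages else 0

    def to_dict(self) -> dict:
        return {
            "layer": self.layer.value,
            "seed": self.seed,
            "stages": [
                {
                    "name": s.name,
                    "features_in": s.features_in,
                    "features_out": s.features_out,
                    "removed": s.removed,
                    "params": s.params,
                }
                for s in self.stages
            ],
        }


def clr_transform(table: OmicLayerTable, pseudocount: float = 0.5) -> OmicLayerTable:
    """Centered log-ratio transform: ln((x + pc) / geometric_mean(x + pc)) per row.

    Maps compositional count rows to a space where every row sums to zero.
    """
    if table.transform != RAW:
        raise TransformStateError("clr_transform requires a raw table")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = table.values + pseudocount
    logx = np.log(x)
    out = logx - logx.mean(axis=1, keepdims=True)
    return table.with_data(
        pd.DataFrame(out, index=table.data.index, columns=table.data.columns),
        transform=CLR,
    )


def log10_transform(table: OmicLayerTable, pseudocount: float = 0.0) -> OmicLayerTable:
    """log10(x + pseudocount) element-wise for intensity tables."""
    if table.transform != RAW:
        raise TransformStateError("log10_transform requires a raw table")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    x = table.values + pseudocount
    if (x <= 0).any():
        raise DomainError(
            "zero intensity with zero pseudocount: log10 undefined"
        )
    out = np.log10(x)
    return table.with_data(
        pd.DataFrame(out, index=table.data.index, columns=table.data.columns),
        transform=LOG10,
    )


def presence_filter(
    table: OmicLayerTable,
    min_presence_fraction: float,
    mode: str = "keep_ge",
    raw_values: Optional[pd.DataFrame] = None,
) -> tuple[OmicLayerTable, list[str]]:
    """Remove sparse (or not-near-ubiquitous) features by presence fraction.

    Presence is the fraction of samples in which the feature is nonzero in
    the RAW values, regardless of the table's current transform state; pass
    ``raw_values`` when the table has already been transformed.

    ``mode="keep_ge"`` keeps features with presence >= threshold (removing
    those found in strictly fewer than the threshold fraction of samples,
    the sparse-virus rule); ``mode="keep_gt"`` keeps features with presence
    strictly > threshold (the near-ubiquitous-compound rule).
    """
    if not (0.0 <= min_presence_fraction <= 1.0):
        raise ValueError("presence fraction must be in [0, 1]")
    if mode not in ("keep_ge", "keep_gt"):
        raise ValueError(f"unknown presence mode {mode!r}")
    if raw_values is None:
        if table.transform != RAW:
            raise TransformStateError(
                "presence on a transformed table requires raw_values"
            )
        raw = table.data
    else:
        raw = raw_values.loc[table.data.index, table.data.columns]
    presence = (raw.to_numpy() != 0).mean(axis=0)
    if mode == "keep_ge":
        keep = presence >= min_presence_fraction
    else:
        keep = presence > min_presence_fraction
    removed = [f for f, k in zip(table.feature_ids, keep) if not k]
    kept = [f for f, k in zip(table.feature_ids, keep) if k]
    return table.subset_features(kept), removed


def collinearity_filter(
    table: OmicLayerTable,
    rho_threshold: float = 0.95,
    seed: int = 0,
) -> tuple[OmicLayerTable, list[str]]:
    """Remove one member of every highly collinear pair (|Pearson r| > threshold).

    While any pair exceeds the threshold, the first such pair (in column
    order) is found and one member is removed, chosen by the seeded RNG.
    Zero-variance features have their correlations treated as 0 and are
    never removed by this filter.  Deterministic given the seed.
    """
    if table.n_samples < 2:
        raise TransformStateError("collinearity filter needs >= 2 samples")
    rng = np.random.default_rng(seed)
    x = table.values
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[~np.isfinite(corr)] = 0.0
    zero_var = sd == 0
    corr[zero_var, :] = 0.0
    corr[:, zero_var] = 0.0
    np.fill_diagonal(corr, 0.0)

    alive = list(range(table.n_features))
    removed_idx: list[int] = []
    while True:
        sub = np.abs(corr[np.ix_(alive, alive)])
        hits = np.argwhere(sub > rho_threshold)
        hits = hits[hits[:, 0] < hits[:, 1]]
        if len(hits) == 0:
            break
        i, j = hits[0]
        victim = alive[i] if rng.random() < 0.5 else alive[j]
        removed_idx.append(victim)
        alive.remove(victim)
    feature_ids = table.feature_ids
    removed = [feature_ids[i] for i in removed_idx]
    kept = [feature_ids[i] for i in alive]
    return table.subset_features(kept), removed


def sd_filter(
    table: OmicLayerTable, min_sd: float
) -> tuple[OmicLayerTable, list[str]]:
    """Remove features whose post-transform sample SD (ddof=1) is < min_sd."""
    if table.transform == RAW:
        raise TransformStateError("sd_filter applies to transformed tables")
    if table.n_samples < 2:
        raise TransformStateError("sd undefined with a single sample")
    sd = table.values.std(axis=0, ddof=1)
    keep = sd >= min_sd
    removed = [f for f, k in zip(table.feature_ids, keep) if not k]
    kept = [f for f, k in zip(table.feature_ids, keep) if k]
    return table.subset_features(kept), removed


@dataclass
class LayerConfig:
    """Normalization and filter recipe for one layer."""

    transform: str  # "clr" or "log10"
    pseudocount: float = 0.5
    presence_threshold: Optional[float] = None
    presence_mode: str = "keep_ge"
    collinearity_threshold: Optional[float] = None
    sd_threshold: float = 0.0


def default_layer_config(layer: Layer) -> LayerConfig:
    """The per-layer recipe used throughout the pipeline."""
    layer = Layer(layer)
    if layer is Layer.MGN:
        return LayerConfig(transform=CLR, pseudocount=0.5, sd_threshold=1.0)
    if layer is Layer.MTS:
        return LayerConfig(
            transform=CLR, pseudocount=0.5, collinearity_threshold=0.95,
            sd_threshold=1.0,
        )
    if layer is Layer.VRM:
        return LayerConfig(
            transform=CLR, pseudocount=0.5, presence_threshold=0.05,
            presence_mode="keep_ge", sd_threshold=0.1,
        )
    return LayerConfig(
        transform=LOG10, pseudocount=1.0, presence_threshold=0.99,
        presence_mode="keep_gt", collinearity_threshold=0.95, sd_threshold=0.1,
    )


def run_preprocess(
    table: OmicLayerTable,
    config: Optional[LayerConfig] = None,
    seed: int = 0,
) -> tuple[OmicLayerTable, FilterReport]:
    """Normalize then filter a raw table per its layer recipe.

    Stage order: transform -> presence (on raw values) -> collinearity -> SD.
    Returns the surviving table and the chained FilterReport.
    """
    if table.transform != RAW:
        raise TransformStateError("run_preprocess expects a raw table")
    if config is None:
        config = default_layer_config(table.layer)
    report = FilterReport(layer=table.layer, seed=seed)
    raw_data = table.data

    if config.transform == CLR:
        out = clr_transform(table, config.pseudocount)
    elif config.transform == LOG10:
        out = log10_transform(table, config.pseudocount)
    else:
        raise ValueError(f"unknown transform {config.transform!r}")
    report.add(
        FilterStage(
            name=config.transform,
            features_in=table.n_features,
            features_out=table.n_features,
            removed=[],
            params={"pseudocount": config.pseudocount},
        )
    )

    if config.presence_threshold is not None:
        n_in = out.n_features
        out, removed = presence_filter(
            out, config.presence_threshold, mode=config.presence_mode,
            raw_values=raw_data,
        )
        report.add(
            FilterStage(
                name="presence",
                features_in=n_in,
                features_out=out.n_features,
                removed=removed,
                params={
                    "threshold": config.presence_threshold,
                    "mode": config.presence_mode,
                },
            )
        )

    if config.collinearity_threshold is not None:
        n_in = out.n_features
        out, removed = collinearity_filter(
            out, config.collinearity_threshold, seed=seed
        )
        report.add(
            FilterStage(
                name="collinearity",
                features_in=n_in,
                features_out=out.n_features,
                removed=removed,
                params={"threshold": config.collinearity_threshold},
            )
        )

    if config.sd_threshold > 0:
        n_in = out.n_features
        out, removed = sd_filter(out, config.sd_threshold)
        report.add(
            FilterStage(
                name="sd",
                features_in=n_in,
                features_out=out.n_features,
                removed=removed,
                params={"min_sd": config.sd_threshold},
            )
        )

    return out, report


def apply_preprocess(
    table: OmicLayerTable,
    config: LayerConfig,
    kept_features: list[str],
) -> OmicLayerTable:
    """Apply a fitted recipe to new samples: transform, then keep the frozen
    feature list (filters are fit on the reference/training samples only)."""
    if table.transform != RAW:
        raise TransformStateError("apply_preprocess expects a raw table")
    if config.transform == CLR:
        out = clr_transform(table, config.pseudocount)
    else:
        out = log10_transform(table, config.pseudocount)
    return out.subset_features(kept_features)
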