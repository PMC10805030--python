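"""Synthetic multi-omic longitudinal cohort generator with known ground truth.

Emulates the structure of a multi-site IBD cohort: ~130 participants across
5 clinical sites, several stool samples per participant over a year, and
four omic layers (metagenomic species counts, metatranscriptomic pathway
counts, viromic virus counts, metabolomic compound intensities) with
layer-specific sparsity and per-sample layer missingness.

Generation is case-control conditional: diagnosis is assigned first and
causal features receive a mean log-abundance shift delta between cases and
controls, so the planted support is exactly the discriminative set a sparse
selector should recover.  Participant- and site-level random intercepts plus
a per-sample scalar shift induce the within-participant correlation the
mixed models downstream are meant to absorb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DesignError
from .omics_io import CohortMetadata, Layer, OmicLayerTable, RAW

# fixed stream index per layer so adding/removing a layer never perturbs
# another layer's draws
_LAYER_STREAM = {Layer.MGN: 1, Layer.MTS: 2, Layer.VRM: 3, Layer.MBL: 4}
_META_STREAM = 0

SITES = ("CedarsSinai", "Cincinnati", "MGH", "MGHPediatrics", "Emory")
RACES = (
    "White",
    "BlackOrAfricanAmerican",
    "MoreThanOneRace",
    "Other",
    "AmericanIndianOrAlaskaNative",
)
# marginal frequencies of the emulated cohort
_SITE_PROBS = np.array([33, 33, 37, 16, 11], dtype=float) / 130.0
_RACE_PROBS = np.array([110, 10, 5, 4, 1], dtype=float) / 130.0


@dataclass
class LayerDesign:
    """Generative settings for one omic layer.

    ``effect_size`` is the mean log-abundance shift (delta) of the causal
    features in cases relative to controls.  ``zero_inflation`` is the mean
    per-feature dropout probability applied after the multinomial draw; the
    per-feature rates are Beta-distributed around this mean so that sparse
    layers contain both rare and common features.  ``missing_layer_prob`` is
    the probability that a sample simply lacks this layer.
    """

    n_features: int
    n_causal: int
    effect_size: float
    base_log_mean: float = 0.0
    base_log_sd: float = 1.0
    library_size: int = 100_000
    zero_inflation: float = 0.0
    zero_inflation_concentration: float = 2.0
    missing_layer_prob: float = 0.0
    sample_noise_sd: float = 1.0
    intensity_scale: float = 1.0e6  # intensity layers only

    def __post_init__(self) -> None:
        if self.n_causal > self.n_features:
            raise DesignError("n_causal exceeds n_features")
        if not (0.0 <= self.zero_inflation < 1.0):
            raise DesignError("zero_inflation must be in [0, 1)")
        if not (0.0 <= self.missing_layer_prob < 1.0):
            raise DesignError("missing_layer_prob must be in [0, 1)")
        if self.library_size <= 0:
            raise DesignError("library_size must be positive")


@dataclass
class SimulationDesign:
    """Full design of a synthetic cohort."""

    n_participants: int
    n_cases: int
    n_sites: int = 5
    samples_per_participant: tuple[int, int] = (4, 8)
    study_weeks: int = 52
    layers: Mapping[Layer, LayerDesign] = field(default_factory=dict)
    participant_re_sd: float = 0.5
    site_re_sd: float = 0.25
    age_mean: float = 28.0
    age_sd: float = 17.0
    age_range: tuple[float, float] = (6.0, 76.0)
    case_cd_fraction: float = 65.0 / 103.0  # CD vs UC split among cases
    antibiotic_prob_case: float = 19.0 / 103.0
    antibiotic_prob_control: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases > self.n_participants:
            raise DesignError("n_cases exceeds n_participants")
        if self.n_sites < 1:
            raise DesignError("need at least one site")
        lo, hi = self.samples_per_participant
        if lo < 1 or hi < lo:
            raise DesignError("invalid samples_per_participant range")


@dataclass
class SimulatedTruth:
    """Ground truth stored alongside a generated cohort."""

    diagnosis: pd.Series  # participant_id -> nonIBD/CD/UC
    participant_intercepts: pd.Series  # participant_id -> random intercept
    site_intercepts: pd.Series  # site -> random intercept
    causal_features: dict[Layer, list[str]]
    causal_shifts: dict[Layer, pd.Series]  # feature_id -> delta
    sample_intercepts: dict[Layer, pd.Series]  # sample_id -> latent scalar

    def to_dict(self) -> dict:
        return {
            "diagnosis": self.diagnosis.to_dict(),
            "participant_intercepts": self.participant_intercepts.to_dict(),
            "site_intercepts": self.site_intercepts.to_dict(),
            "causal_features": {k.value: v for k, v in self.causal_features.items()},
            "causal_shifts": {
                k.value: v.to_dict() for k, v in self.causal_shifts.items()
            },
        }


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(
    design: SimulationDesign,
) -> tuple[dict[Layer, OmicLayerTable], CohortMetadata, SimulatedTruth]:
    """Generate the per-layer tables, metadata and ground truth for a design.

    Deterministic given ``design.seed``; each layer consumes its own RNG
    stream derived from the master seed.
    """
    if not design.layers:
        raise DesignError("design has no omic layers")
    rng = np.random.default_rng([design.seed, _META_STREAM])
    n = design.n_participants
    participants = [f"P{i:03d}" for i in range(1, n + 1)]

    # diagnosis: n_cases participants are cases, split CD/UC
    is_case = np.zeros(n, dtype=bool)
    case_idx = rng.choice(n, size=design.n_cases, replace=False)
    is_case[case_idx] = True
    dx = np.where(is_case, "CD", "nonIBD").astype(object)
    for i in case_idx:
        if rng.random() >= design.case_cd_fraction:
            dx[i] = "UC"

    sites = np.array(SITES[: design.n_sites])
    site_probs = _SITE_PROBS[: design.n_sites]
    site_probs = site_probs / site_probs.sum()
    part_site = rng.choice(sites, size=n, p=site_probs)
    age = _truncated_normal(
        rng, design.age_mean, design.age_sd, *design.age_range, size=n
    )
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    race = rng.choice(RACES, size=n, p=_RACE_PROBS)
    abx_p = np.where(is_case, design.antibiotic_prob_case, design.antibiotic_prob_control)
    antibiotic = rng.random(n) < abx_p

    b_part = rng.normal(0.0, design.participant_re_sd, size=n)
    c_site = rng.normal(0.0, design.site_re_sd, size=len(sites))
    site_lookup = dict(zip(sites, c_site))

    lo, hi = design.samples_per_participant
    rows = []
    for i, pid in enumerate(participants):
        k = int(rng.integers(lo, hi + 1))
        weeks = np.sort(rng.choice(design.study_weeks, size=k, replace=False))
        for j, w in enumerate(weeks):
            rows.append(
                {
                    "sample_id": f"{pid}_S{j + 1:02d}",
                    "participant_id": pid,
                    "diagnosis": dx[i],
                    "age": round(float(age[i]), 1),
                    "sex": sex[i],
                    "race": race[i],
                    "antibiotic_use": bool(antibiotic[i]),
                    "site": part_site[i],
                    "week": int(w),
                }
            )
    meta = CohortMetadata(pd.DataFrame(rows))
    mdf = meta.data
    part_index = {p: i for i, p in enumerate(participants)}

    tables: dict[Layer, OmicLayerTable] = {}
    causal_features: dict[Layer, list[str]] = {}
    causal_shifts: dict[Layer, pd.Series] = {}
    sample_intercepts: dict[Layer, pd.Series] = {}

    for layer in sorted(design.layers, key=lambda l: _LAYER_STREAM[Layer(l)]):
        layer = Layer(layer)
        ld = design.layers[layer]
        lrng = np.random.default_rng([design.seed, _LAYER_STREAM[layer]])
        p = ld.n_features
        feat_ids = [f"{layer.value}_F{j:04d}" for j in range(1, p + 1)]
        base = lrng.normal(ld.base_log_mean, ld.base_log_sd, size=p)
        causal_idx = lrng.choice(p, size=ld.n_causal, replace=False)
        delta = np.zeros(p)
        signs = np.where(lrng.random(ld.n_causal) < 0.5, -1.0, 1.0)
        delta[causal_idx] = ld.effect_size * signs

        # per-sample latent scalar: participant + site intercepts + sample shift
        pi = mdf["participant_id"].map(part_index).to_numpy()
        y_part = (mdf["diagnosis"] != "nonIBD").astype(float).to_numpy()
        scalar = (
            b_part[pi]
            + mdf["site"].map(site_lookup).to_numpy()
            + lrng.normal(0.0, ld.sample_noise_sd * 0.5, size=len(mdf))
        )
        latent = (
            base[None, :]
            + np.outer(y_part, delta)
            + scalar[:, None]
            + lrng.normal(0.0, ld.sample_noise_sd, size=(len(mdf), p))
        )

        if layer is Layer.MBL:
            values = ld.intensity_scale * np.exp(latent)
        else:
            w = np.exp(latent - latent.max(axis=1, keepdims=True))
            probs = w / w.sum(axis=1, keepdims=True)
            values = np.empty_like(probs)
            for r in range(probs.shape[0]):
                values[r] = lrng.multinomial(ld.library_size, probs[r])

        if ld.zero_inflation > 0:
            kappa = ld.zero_inflation_concentration
            z_rates = lrng.beta(
                ld.zero_inflation * kappa, (1.0 - ld.zero_inflation) * kappa, size=p
            )
            mask = lrng.random(values.shape) < z_rates[None, :]
            values = np.where(mask, 0.0, values)

        df = pd.DataFrame(values, index=mdf["sample_id"].tolist(), columns=feat_ids)
        if ld.missing_layer_prob > 0:
            keep = lrng.random(len(df)) >= ld.missing_layer_prob
            df = df.loc[keep]

        tables[layer] = OmicLayerTable(layer, df, RAW)
        causal_features[layer] = [feat_ids[j] for j in sorted(causal_idx)]
        causal_shifts[layer] = pd.Series(
            {feat_ids[j]: delta[j] for j in sorted(causal_idx)}
        )
        sample_intercepts[layer] = pd.Series(scalar, index=mdf["sample_id"].tolist())

    truth = SimulatedTruth(
        diagnosis=pd.Series(dx, index=participants),
        participant_intercepts=pd.Series(b_part, index=participants),
        site_intercepts=pd.Series(c_site, index=list(sites)),
        causal_features=causal_features,
        causal_shifts=causal_shifts,
        sample_intercepts=sample_intercepts,
    )
    return tables, meta, truth


def hmp2_like_design(seed: int = 0) -> SimulationDesign:
    """A design approximating the emulated study's shape.

    130 participants (103 IBD cases, 27 controls) across 5 sites, ages
    centered on 28 +/- 17 years within 6-76, and pre-filter feature counts
    of 578 / 421 / 239 / 596 for the MGN / MTS / VRM / MBL layers.  Planted
    effect sizes are strongest in the metabolomic and viromic layers and
    weakest in the metagenomic layer, mirroring the predictive ordering the
    framework is designed to expose; sparsity and per-sample layer
    missingness differ by layer as in real multi-omic stool profiling.
    """
    layers = {
        Layer.MGN: LayerDesign(
            n_features=578, n_causal=14, effect_size=0.6,
            zero_inflation=0.35, missing_layer_prob=0.10,
        ),
        Layer.MTS: LayerDesign(
            n_features=421, n_causal=22, effect_size=0.9,
            zero_inflation=0.25, missing_layer_prob=0.35,
        ),
        Layer.VRM: LayerDesign(
            n_features=239, n_causal=6, effect_size=1.8,
            zero_inflation=0.90, missing_layer_prob=0.30, library_size=20_000,
        ),
        Layer.MBL: LayerDesign(
            n_features=596, n_causal=14, effect_size=1.4,
            zero_inflation=0.002, zero_inflation_concentration=50.0,
            missing_layer_prob=0.25,
        ),
    }
    return SimulationDesign(
        n_participants=130,
        n_cases=103,
        n_sites=5,
        layers=layers,
        seed=seed,
    )
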