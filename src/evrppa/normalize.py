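"""Spot-level to sample-level normalization of RPPA intensities.

The correction chain converts raw per-spot fluorescence into normalized
intensities in arbitrary units (A.U.), in this order:

1. local background subtraction (per spot, floored at 0),
2. negative-control subtraction (secondary-antibody-only slide, matched per
   spot or per sample mean, floored at 0),
3. replicate averaging (mean of finite technical replicates),
4. total-protein normalization (division by the sample's relative Sypro
   loading).

Each step can be disabled; the applied steps and parameters are recorded in
the result's provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import (
    CHANNEL_ANTIBODY,
    CHANNEL_NEGATIVE_CONTROL,
    CHANNEL_TOTAL_PROTEIN,
)

logger = logging.getLogger(__name__)

_SPOT_KEY = ["sample_id", "print_conc_mg_ml", "replicate_idx"]


@dataclass(frozen=True)
class SpotRecord:
    """One printed spot's raw measurement with its assay coordinates."""

    slide_id: str
    channel: str
    antibody_id: str
    sample_id: str
    print_conc_mg_ml: float
    replicate_idx: int
    raw_intensity: float
    local_background: float

    def __post_init__(self):
        if self.raw_intensity < 0 or self.local_background < 0:
            raise ValueError("intensities must be non-negative")
        if self.replicate_idx < 1:
            raise ValueError("replicate_idx must be >= 1")


@dataclass
class NormalizeConfig:
    """Parameters of the normalization chain."""

    print_conc: float | None = None  # None -> highest available concentration
    subtract_local_background: bool = True
    subtract_negative_control: bool = True
    negctrl_mode: str = "per_spot"  # or "per_sample_mean"
    total_protein_normalize: bool = True
    sypro_rescale: str = "median"  # "median" (cohort-median units) or "none"

    def __post_init__(self):
        if self.negctrl_mode not in ("per_spot", "per_sample_mean"):
            raise ValueError("negctrl_mode must be 'per_spot' or 'per_sample_mean'")
        if self.sypro_rescale not in ("median", "none"):
            raise ValueError("sypro_rescale must be 'median' or 'none'")


@dataclass
class NormalizedMatrix:
    """Samples x endpoints table of normalized RPPA intensities (A.U.)."""

    values: pd.DataFrame  # index: sample_id, columns: endpoint ids; NaN = missing
    provenance: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def endpoint_ids(self) -> list[str]:
        return list(self.values.columns)


def subtract_background(raw_intensity: float, local_background: float) -> float:
    """Local background subtraction, floored at 0."""
    if raw_intensity < 0 or local_background < 0:
        raise ValueError("intensities must be non-negative")
    return max(raw_intensity - local_background, 0.0)


def subtract_negative_control(value: float, negctrl_value: float) -> float:
    """Subtract the matched negative-control intensity, floored at 0."""
    return max(value - negctrl_value, 0.0)


def average_replicates(values) -> tuple[float, int]:
    """Mean of finite replicates; returns (mean or NaN, replicate count used)."""
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        return float("nan"), 0
    return float(finite.mean()), int(finite.size)


def normalize_total_protein(value: float, sypro_value: float, sypro_reference: float = 1.0) -> float:
    """Divide by the sample's relative total-protein loading.

    ``sypro_reference`` is the cohort reference (median Sypro); the result is
    ``value / (sypro_value / sypro_reference)``.  Non-positive Sypro yields NaN.
    """
    if sypro_value <= 0 or not np.isfinite(sypro_value):
        logger.warning("non-positive Sypro value; normalized value set to missing")
        return float("nan")
    return value / (sypro_value / sypro_reference)


def _matched_negctrl(ab: pd.DataFrame, neg: pd.DataFrame, mode: str) -> pd.Series:
    """Negative-control value aligned to each antibody-channel spot row."""
    if mode == "per_spot":
        lut = neg.set_index(_SPOT_KEY)["corrected"]
        if lut.index.has_duplicates:
            lut = lut.groupby(level=list(range(3))).mean()
        idx = pd.MultiIndex.from_frame(ab[_SPOT_KEY])
        matched = lut.reindex(idx)
        if matched.isna().any():
            missing = ab.loc[matched.isna().to_numpy(), _SPOT_KEY].iloc[0]
            raise ValueError(
                "negative-control slide lacks a spot for "
                f"sample={missing['sample_id']!r} conc={missing['print_conc_mg_ml']} "
                f"replicate={missing['replicate_idx']}"
            )
    else:  # per_sample_mean
        lut = neg.groupby("sample_id")["corrected"].mean()
        matched = lut.reindex(ab["sample_id"])
        if matched.isna().any():
            orphan = ab.loc[matched.isna().to_numpy(), "sample_id"].iloc[0]
            raise ValueError(f"negative-control slide lacks sample {orphan!r}")
    return pd.Series(matched.to_numpy(), index=ab.index)


def run_normalization(spots: pd.DataFrame, config: NormalizeConfig | None = None) -> NormalizedMatrix:
    """Apply the full correction chain to a spot table and pivot to samples x endpoints.

    Steps run per (sample, endpoint, print concentration) in the fixed order
    background -> negative control -> replicate mean -> total protein, after
    which the configured print concentration is selected (default: highest).
    """
    config = config or NormalizeConfig()
    spots = spots.copy()
    required = {"channel", "antibody_id", "sample_id", "print_conc_mg_ml",
                "replicate_idx", "raw_intensity", "local_background"}
    missing_cols = required - set(spots.columns)
    if missing_cols:
        raise ValueError(f"spot table missing columns: {sorted(missing_cols)}")

    ab = spots[spots["channel"] == CHANNEL_ANTIBODY].copy()
    if ab.empty:
        raise ValueError("spot table contains no antibody-channel rows")

    concs = sorted(ab["print_conc_mg_ml"].unique())
    conc = config.print_conc if config.print_conc is not None else max(concs)
    if conc not in concs:
        raise ValueError(
            f"requested print concentration {conc} absent; available: {concs}"
        )

    steps = []

    # 1. local background
    if config.subtract_local_background:
        ab["corrected"] = (ab["raw_intensity"] - ab["local_background"]).clip(lower=0)
        steps.append("local_background_subtraction")
    else:
        ab["corrected"] = ab["raw_intensity"]

    # 2. negative control
    if config.subtract_negative_control:
        neg = spots[spots["channel"] == CHANNEL_NEGATIVE_CONTROL].copy()
        if neg.empty:
            raise ValueError("negative-control subtraction enabled but channel absent")
        if config.subtract_local_background:
            neg["corrected"] = (neg["raw_intensity"] - neg["local_background"]).clip(lower=0)
        else:
            neg["corrected"] = neg["raw_intensity"]
        matched = _matched_negctrl(ab, neg, config.negctrl_mode)
        ab["corrected"] = (ab["corrected"] - matched).clip(lower=0)
        steps.append(f"negative_control_subtraction[{config.negctrl_mode}]")

    # 3. replicate averaging
    grouped = (
        ab.groupby(["sample_id", "antibody_id", "print_conc_mg_ml"], sort=False)["corrected"]
        .agg(["mean", "count"])
        .reset_index()
    )
    steps.append("replicate_averaging")

    # 4. total protein normalization
    if config.total_protein_normalize:
        tp = spots[spots["channel"] == CHANNEL_TOTAL_PROTEIN].copy()
        if tp.empty:
            raise ValueError("total-protein normalization enabled but channel absent")
        if config.subtract_local_background:
            tp["corrected"] = (tp["raw_intensity"] - tp["local_background"]).clip(lower=0)
        else:
            tp["corrected"] = tp["raw_intensity"]
        sypro = (
            tp.groupby(["sample_id", "print_conc_mg_ml"], sort=False)["corrected"]
            .mean()
            .rename("sypro")
            .reset_index()
        )
        grouped = grouped.merge(sypro, on=["sample_id", "print_conc_mg_ml"], how="left")
        if grouped["sypro"].isna().any():
            orphan = grouped.loc[grouped["sypro"].isna(), "sample_id"].iloc[0]
            raise ValueError(f"total-protein channel lacks sample {orphan!r}")
        bad = grouped["sypro"] <= 0
        if bad.any():
            logger.warning("%d cells with non-positive Sypro set to missing", int(bad.sum()))
        if config.sypro_rescale == "median":
            ref = grouped.groupby("print_conc_mg_ml")["sypro"].transform("median")
        else:
            ref = 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            grouped["value"] = np.where(
                grouped["sypro"] > 0, grouped["mean"] / (grouped["sypro"] / ref), np.nan
            )
        steps.append(f"total_protein_normalization[{config.sypro_rescale}]")
    else:
        grouped["value"] = grouped["mean"]

    sel = grouped[grouped["print_conc_mg_ml"] == conc]
    matrix = sel.pivot(index="sample_id", columns="antibody_id", values="value")
    matrix = matrix.reindex(
        index=pd.unique(ab["sample_id"]), columns=pd.unique(ab["antibody_id"])
    )
    matrix.index.name = "sample_id"
    matrix.columns.name = "endpoint"

    provenance = {
        "steps": steps,
        "print_conc_mg_ml": float(conc),
        "available_concentrations": [float(c) for c in concs],
        "n_samples": int(matrix.shape[0]),
        "n_endpoints": int(matrix.shape[1]),
        "config": {
            "subtract_local_background": config.subtract_local_background,
            "subtract_negative_control": config.subtract_negative_control,
            "negctrl_mode": config.negctrl_mode,
            "total_protein_normalize": config.total_protein_normalize,
            "sypro_rescale": config.sypro_rescale,
        },
    }
    return NormalizedMatrix(values=matrix, provenance=provenance)
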