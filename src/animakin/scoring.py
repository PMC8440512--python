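"""Accuracy scores, observer-animator similarity, and predictor preprocessing.

Accuracy on a rating trial is the rating given to the target word minus the
mean rating of the four non-target words, so it lies in [-9, 9] for 1-10
scales and is positive when the observer discriminated the depicted word
from the alternatives.

Observer-animator similarity for any kinematic feature is the absolute
difference between the stimulus animation's mean feature value and the mean
feature value of the observer's own production of the same word; lower
difference means higher similarity.

Predictor preprocessing follows the order: optional variance-stabilizing
transform (log or sqrt), winsorization at median +/- 3 scaled MADs
(MAD * 1.4826, the normal-consistent scaling), then z-scoring.  Every step
is recorded per column so the transformation is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory_model import RatingTrial

__all__ = [
    "MAD_SCALE",
    "ColumnProvenance",
    "FeatureTable",
    "accuracy_score",
    "similarity_difference",
    "winsorize_mad",
    "suggest_transforms",
    "preprocess_predictors",
    "build_trial_table",
]

#: Consistency constant making the MAD estimate the normal sd.
MAD_SCALE = 1.4826


def accuracy_score(trial: RatingTrial) -> float:
    """Target-word rating minus the mean of the four non-target ratings."""
    target = trial.ratings[trial.target_word]
    others = [r for w, r in trial.ratings.items() if w != trial.target_word]
    return float(target - np.mean(others))


def similarity_difference(stimulus_value: float, observer_value: float) -> float:
    """Absolute observer-animator difference; lower = more similar."""
    return abs(float(observer_value) - float(stimulus_value))


@dataclass(frozen=True)
class ColumnProvenance:
    transform: str = "none"  # none | log | sqrt
    winsor_lower: float | None = None
    winsor_upper: float | None = None
    z_mean: float | None = None
    z_sd: float | None = None


@dataclass
class FeatureTable:
    """Trial- or item-level feature table with per-column provenance."""

    data: pd.DataFrame
    provenance: dict[str, ColumnProvenance] = field(default_factory=dict)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), dict(self.provenance))


def winsorize_mad(
    values: np.ndarray, n_mads: float = 3.0, scale: float = MAD_SCALE
) -> tuple[np.ndarray, float, float]:
    """Clip values at median +/- n_mads * scaled MAD.

    Returns (clipped values, lower bound, upper bound).  Idempotent: the
    clipped output has the same median and a MAD no larger than the input's,
    so re-winsorizing changes nothing.
    """
    x = np.asarray(values, dtype=float)
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med))) * scale
    lo, hi = med - n_mads * mad, med + n_mads * mad
    return np.clip(x, lo, hi), lo, hi


def suggest_transforms(
    df: pd.DataFrame, columns, skew_threshold: float = 1.0
) -> dict[str, str]:
    """Heuristic transform map: log for skewed strictly positive columns,
    sqrt for skewed non-negative ones, none otherwise."""
    out: dict[str, str] = {}
    for col in columns:
        x = df[col].to_numpy(dtype=float)
        skew = float(pd.Series(x).skew())
        if skew > skew_threshold and np.all(x > 0):
            out[col] = "log"
        elif skew > skew_threshold and np.all(x >= 0):
            out[col] = "sqrt"
        else:
            out[col] = "none"
    return out


def preprocess_predictors(
    table: FeatureTable,
    transform_map: dict[str, str],
    n_mads: float = 3.0,
    mad_scale: float = MAD_SCALE,
) -> FeatureTable:
    """Transform -> winsorize -> z-score each listed predictor column.

    Z-scoring uses the pooled analysis sample (no stratification).  Raises
    on a log transform of a non-positive value, naming the column and row.
    """
    out = table.copy()
    for col, transform in transform_map.items():
        x = out.data[col].to_numpy(dtype=float)
        if transform == "log":
            bad = np.nonzero(x <= 0)[0]
            if bad.size:
                raise ValueError(
                    f"log transform of non-positive value in column {col!r} "
                    f"at row {bad[0]}"
                )
            x = np.log(x)
        elif transform == "sqrt":
            bad = np.nonzero(x < 0)[0]
            if bad.size:
                raise ValueError(
                    f"sqrt transform of negative value in column {col!r} "
                    f"at row {bad[0]}"
                )
            x = np.sqrt(x)
        elif transform != "none":
            raise ValueError(f"unknown transform {transform!r} for column {col!r}")
        x, lo, hi = winsorize_mad(x, n_mads=n_mads, scale=mad_scale)
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=0))
        if sd == 0:
            raise ValueError(f"column {col!r} is constant after winsorization")
        out.data[col] = (x - mean) / sd
        out.provenance[col] = ColumnProvenance(
            transform=transform,
            winsor_lower=lo,
            winsor_upper=hi,
            z_mean=mean,
            z_sd=sd,
        )
    return out


def build_trial_table(
    trials,
    animation_features: pd.DataFrame,
    production_features: pd.DataFrame | None = None,
) -> FeatureTable:
    """Join rating trials with animation features and similarity scores.

    Parameters
    ----------
    trials:
        iterable of RatingTrial.
    animation_features:
        one row per animation_id (index), columns = kinematic/spatial
        features (mean_jerk, mean_acceleration, mean_speed, mean_rotation,
        simultaneous_movement, relative_distance, bin_1..bin_9, word).
    production_features:
        one row per (observer_id, word) multi-index with the same kinematic
        columns, from the observers' own productions; enables the
        jerk/acceleration/rotation difference scores.  Trials without a
        matching production raise.
    """
    rows = []
    for tr in trials:
        if tr.animation_id not in animation_features.index:
            raise KeyError(f"no features for animation {tr.animation_id!r}")
        feat = animation_features.loc[tr.animation_id]
        row = {
            "observer_id": tr.observer_id,
            "animation_id": tr.animation_id,
            "word": tr.target_word.value,
            "is_mental": tr.target_word.is_mental,
            "accuracy": accuracy_score(tr),
        }
        for col in animation_features.columns:
            if col != "word":
                row[col] = feat[col]
        if production_features is not None:
            key = (tr.observer_id, tr.target_word.value)
            if key not in production_features.index:
                raise KeyError(
                    f"observer {tr.observer_id!r} has no production for "
                    f"word {tr.target_word.value!r}"
                )
            prod = production_features.loc[key]
            for feat_col, diff_col in (
                ("mean_jerk", "jerk_diff"),
                ("mean_acceleration", "acceleration_diff"),
                ("mean_rotation", "rotation_diff"),
            ):
                row[diff_col] = similarity_difference(feat[feat_col], prod[feat_col])
        rows.append(row)
    return FeatureTable(pd.DataFrame(rows))
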