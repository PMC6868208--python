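"""CSV readers and writers for the standard long-format tables.

All files are UTF-8 CSVs with mandatory headers. Schemas:

* positions: ``group_id, condition, frame_index, time_s, fish_id, x_cm, y_cm[, z_cm]``
* body lengths: ``group_id, fish_id, standard_length_mm``
* behaviours (long): ``group_id, condition, clip_index, behaviour, present``
* cortisol: ``group_id, condition, fish_id, cortisol_ng_per_g``
* metric table: one FrameMetricRow per line
* results: ``response, family, transform, chi_sq, df, p_raw, p_bonferroni,
  coef, n_obs, n_groups, converged, note``
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from .geometry import FRAME_METRIC_COLUMNS
from .inference import LRTResult

POSITION_COLUMNS = ["group_id", "condition", "frame_index", "time_s",
                    "fish_id", "x_cm", "y_cm"]
BODY_LENGTH_COLUMNS = ["group_id", "fish_id", "standard_length_mm"]
BEHAVIOUR_COLUMNS = ["group_id", "condition", "clip_index", "behaviour", "present"]
CORTISOL_COLUMNS = ["group_id", "condition", "fish_id", "cortisol_ng_per_g"]
RESULT_COLUMNS = ["response", "family", "transform", "chi_sq", "df", "p_raw",
                  "p_bonferroni", "coef", "n_obs", "n_groups", "converged", "note"]


class SchemaError(ValueError):
    """A CSV is missing required columns."""


def _check_schema(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; found {list(df.columns)}")


def read_positions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, POSITION_COLUMNS, path)
    return df


def read_body_lengths(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, BODY_LENGTH_COLUMNS, path)
    if (df["standard_length_mm"] <= 0).any():
        raise ValueError(f"{path}: non-positive standard_length_mm")
    return df


def read_behaviours(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, BEHAVIOUR_COLUMNS, path)
    if not df["present"].isin((0, 1)).all():
        raise ValueError(f"{path}: 'present' must be 0/1")
    return df


def read_cortisol(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, CORTISOL_COLUMNS, path)
    return df


def read_metric_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, FRAME_METRIC_COLUMNS, path)
    return df


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def results_to_frame(results: list[LRTResult]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in results]
    df = pd.DataFrame(rows)
    return df[[c for c in RESULT_COLUMNS if c in df.columns]]
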