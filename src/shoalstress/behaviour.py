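"""Clip-level behaviour coding utilities.

Observation sessions are cut into fixed-length clips (10 s by default) and
each clip is scored for the presence/absence of each behaviour: a behaviour
is present when at least one fish in the shoal performs it at any point in
the clip. This module manages clip segmentation, the rare-behaviour filter,
and intra-observer reliability statistics (percent agreement and Cohen's
kappa). Scoring itself is an input — by a human observer for video, or by
the simulator for synthetic trajectories.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: canonical behaviour names
ERRATIC = "erratic_movement"
TOP_HALF = "top_half"


def segment_clips(session_duration_s: float, clip_duration_s: float = 10.0) -> int:
    """Number of clips a session divides into; errors on a partial clip."""
    if clip_duration_s <= 0:
        raise ValueError("clip duration must be positive")
    n, rem = divmod(session_duration_s, clip_duration_s)
    if rem != 0:
        raise ValueError(
            f"partial clip: {session_duration_s} s is not divisible by "
            f"{clip_duration_s} s"
        )
    return int(n)


def reliability_subsample(
    tables: pd.DataFrame, fraction: float = 0.10, seed: int | None = None
) -> pd.DataFrame:
    """Random clip subsample for second-pass (intra-observer) coding.

    ``tables`` is a long-format behaviour table with columns
    ``group_id, condition, clip_index`` (a ``behaviour`` column is ignored:
    the unit of rescoring is the clip). Selects ``round(fraction * total)``
    distinct clips uniformly at random, reproducibly for a given seed.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    clips = tables[["group_id", "condition", "clip_index"]].drop_duplicates()
    if clips.empty:
        raise ValueError("empty behaviour table set")
    n_select = int(round(fraction * len(clips)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(clips), size=n_select, replace=False)
    return clips.iloc[np.sort(idx)].reset_index(drop=True)


def percent_agreement(coder1, coder2) -> float:
    """Percentage of clips on which two coding passes agree."""
    a = np.asarray(coder1)
    b = np.asarray(coder2)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("coder vectors must be equal-length, non-empty 1-D")
    return float(100.0 * np.mean(a == b))


def cohens_kappa(coder1, coder2) -> float:
    """Chance-corrected agreement between two binary coding passes.

    kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e from the
    product of the coders' marginal rates. Degenerate cases: when both
    coders are constant and identical (p_e = 1) agreement is perfect by
    construction and 1 is returned; constant but different coders return 0
    with a warning.
    """
    a = np.asarray(coder1)
    b = np.asarray(coder2)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("coder vectors must be equal-length, non-empty 1-D")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("coder vectors must be binary (0/1)")
    p_o = np.mean(a == b)
    if np.ptp(a) == 0 and np.ptp(b) == 0:  # both coders constant
        if a[0] == b[0]:
            return 1.0
        warnings.warn("constant coders with disagreement: kappa undefined, returning 0")
        return 0.0
    pa, pb = a.mean(), b.mean()
    p_e = pa * pb + (1 - pa) * (1 - pb)
    return float((p_o - p_e) / (1 - p_e))


def rare_behaviour_filter(
    tables: pd.DataFrame, min_presence: float = 0.10
) -> list[str]:
    """Behaviours present often enough, pooled over both conditions.

    ``tables`` is long-format (``behaviour``, ``present`` columns) spanning
    all groups and both conditions. A behaviour is retained iff its pooled
    presence proportion is >= ``min_presence`` (boundary inclusive:
    behaviours strictly below the cutoff are removed). Returns retained
    behaviour names in their order of first appearance.
    """
    if not {"behaviour", "present"}.issubset(tables.columns):
        raise ValueError("expected long-format table with behaviour/present columns")
    prop = tables.groupby("behaviour", sort=False)["present"].mean()
    return [name for name, p in prop.items() if p >= min_presence]


def behaviour_wide(tables: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long behaviour table to clip x behaviour 0/1 cells."""
    wide = tables.pivot_table(
        index=["group_id", "condition", "clip_index"],
        columns="behaviour",
        values="present",
        aggfunc="first",
    )
    wide.columns.name = None
    return wide.reset_index()
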