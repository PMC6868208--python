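"""End-to-end analysis: metrics -> selection -> mixed-model tests.

The canonical flow mirrors the study design the package targets: per-frame
group metrics are computed from positions, pooled with clip-level
behaviours into a metric catalogue aligned on 10 s intervals, pruned to a
weakly-correlated subset covering every metric category, and each retained
metric is tested for a condition difference with a mixed-effects
likelihood-ratio test (Gaussian for continuous metrics, binomial for
behaviours), Bonferroni-corrected as one family. Cortisol is analysed
log-transformed as its own a-priori test.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd

from . import association, behaviour, geometry, inference, selection
from .geometry import TankGeometry

#: metric -> category map for the standard catalogue
METRIC_CATEGORY = {
    "mean_nnd_cm": "proximity",
    "cv_nnd": "proximity",
    "mean_interindividual_distance_cm": "proximity",
    "expanse_cm": "proximity",
    "convex_hull_area_cm2": "proximity",
    "distance_to_wall_cm": "spatial",
    "density": "social",
    "n_subgroups": "social",
    "largest_subgroup_size": "social",
    "erratic_movement": "behavioural",
    "top_half": "behavioural",
}

#: assay detection limit for whole-body cortisol ELISA (ng/ml); samples below
#: it are recorded as 0 and need an offset before a log transform.
CORTISOL_DETECTION_LIMIT = 0.0567


@dataclass
class AnalysisConfig:
    tank: TankGeometry = field(default_factory=TankGeometry)
    association_multiplier: float = 2.0
    selection_threshold: float = 0.2
    rare_behaviour_min_presence: float = 0.10
    transforms: dict = field(default_factory=lambda: {"cv_nnd": "log"})
    priority: list | None = None
    bonferroni_m: int | None = None      # default: number of retained responses
    include_cortisol_in_family: bool = False
    cortisol_log_offset: float = CORTISOL_DETECTION_LIMIT / 2
    #: explicit response list; bypasses selection-driven choice (selection is
    #: then skipped) and tests exactly these metrics as the Bonferroni family
    responses: list | None = None


@dataclass
class AnalysisResult:
    metric_table: pd.DataFrame
    catalogue: selection.MetricCatalogue
    correlation: selection.CorrelationMatrix
    selected: selection.SelectionResult
    tests: list
    cortisol_test: inference.LRTResult | None
    reliability: pd.DataFrame | None = None


def compute_metric_table(
    positions: pd.DataFrame,
    body_lengths: pd.DataFrame,
    tank: TankGeometry | None = None,
    association_multiplier: float = 2.0,
) -> pd.DataFrame:
    """Per-frame FrameMetricRow table for every group/condition/frame.

    The association threshold is ``multiplier`` x the group's mean standard
    body length (mm -> cm), computed per group. When every frame holds the
    same number of fish (the regular case) the whole table is computed on
    stacked arrays; otherwise each frame goes through
    :func:`shoalstress.geometry.compute_frame_metrics` individually. Both
    paths produce identical values.
    """
    tank = tank or TankGeometry()
    thresholds = {
        gid: association.association_threshold(
            sub["standard_length_mm"].to_numpy(), association_multiplier
        )
        for gid, sub in body_lengths.groupby("group_id")
    }
    missing = set(positions["group_id"].unique()) - set(thresholds)
    if missing:
        raise ValueError(f"groups without body lengths: {sorted(missing)}")

    df = positions.sort_values(
        ["group_id", "condition", "frame_index", "fish_id"], kind="mergesort"
    )
    counts = df.groupby(["group_id", "condition", "frame_index"], sort=False).size()
    if counts.nunique() == 1 and counts.iloc[0] >= 2:
        return _bulk_metric_table(df, int(counts.iloc[0]), tank, thresholds)

    rows = []
    for (gid, condition, fidx), sub in df.groupby(
        ["group_id", "condition", "frame_index"], sort=True
    ):
        xy = sub[["x_cm", "y_cm"]].to_numpy(float)
        rows.append(
            geometry.compute_frame_metrics(
                xy, tank, thresholds[gid],
                group_id=gid, condition=condition, frame_index=fidx,
            )
        )
    return pd.DataFrame(rows, columns=geometry.FRAME_METRIC_COLUMNS)


def _bulk_metric_table(
    df: pd.DataFrame, n_fish: int, tank: TankGeometry, thresholds: dict
) -> pd.DataFrame:
    """Vectorised metric table for frames with a uniform fish count."""
    from scipy.spatial import ConvexHull, QhullError

    keys = df[["group_id", "condition", "frame_index"]].drop_duplicates()
    xy = df[["x_cm", "y_cm"]].to_numpy(float).reshape(-1, n_fish, 2)
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-finite coordinate in frame")
    n_frames = xy.shape[0]

    diff = xy[:, :, None, :] - xy[:, None, :, :]
    dmat = np.sqrt((diff**2).sum(axis=3))                       # (N, n, n)
    eye = np.eye(n_fish, dtype=bool)
    dmat_inf = np.where(eye[None], np.inf, dmat)
    nnd = dmat_inf.min(axis=2)                                  # (N, n)
    mean_nnd = nnd.mean(axis=1)
    if np.any(mean_nnd <= 0):
        bad = int(np.argmax(mean_nnd <= 0))
        raise geometry.DegenerateFrameError(
            f"degenerate frame: mean NND is zero at row {bad}"
        )
    cv_nnd = nnd.std(axis=1, ddof=1) / mean_nnd
    iu = np.triu_indices(n_fish, k=1)
    mean_iid = dmat[:, iu[0], iu[1]].mean(axis=1)
    cen = xy.mean(axis=1)                                       # (N, 2)
    expanse = np.linalg.norm(xy - cen[:, None, :], axis=2).mean(axis=1)
    if not tank.contains(cen):
        raise geometry.OutsideTankError("position outside tank: shoal centroid")
    wall = np.minimum.reduce(
        [cen[:, 0], tank.length_cm - cen[:, 0], cen[:, 1], tank.width_cm - cen[:, 1]]
    )

    thr = keys["group_id"].map(thresholds).to_numpy(float)      # (N,)
    adj = (dmat <= thr[:, None, None]) & ~eye[None]
    density = adj[:, iu[0], iu[1]].sum(axis=1) / (n_fish * (n_fish - 1) / 2)
    n_sub, largest = _components_counts(adj)

    hull = np.empty(n_frames)
    for f in range(n_frames):
        pts = xy[f]
        if len(np.unique(pts, axis=0)) < 3:
            hull[f] = 0.0
            continue
        try:
            hull[f] = ConvexHull(pts).volume
        except QhullError:
            hull[f] = 0.0

    out = keys.reset_index(drop=True).copy()
    out["mean_nnd_cm"] = mean_nnd
    out["cv_nnd"] = cv_nnd
    out["mean_interindividual_distance_cm"] = mean_iid
    out["expanse_cm"] = expanse
    out["convex_hull_area_cm2"] = hull
    out["centroid_x_cm"] = cen[:, 0]
    out["centroid_y_cm"] = cen[:, 1]
    out["distance_to_wall_cm"] = wall
    out["density"] = density
    out["n_subgroups"] = n_sub
    out["largest_subgroup_size"] = largest
    return out[geometry.FRAME_METRIC_COLUMNS]


@numba.njit(cache=False)
def _components_counts(adj):  # pragma: no cover - jitted
    """Connected-component count and largest size per frame (stacked BFS)."""
    n_frames, n = adj.shape[0], adj.shape[1]
    out_count = np.empty(n_frames, np.int64)
    out_largest = np.empty(n_frames, np.int64)
    label = np.empty(n, np.int64)
    stack = np.empty(n, np.int64)
    for f in range(n_frames):
        for i in range(n):
            label[i] = -1
        ncomp = 0
        largest = 0
        for i in range(n):
            if label[i] >= 0:
                continue
            size = 0
            stack[0] = i
            label[i] = ncomp
            top = 1
            while top > 0:
                top -= 1
                v = stack[top]
                size += 1
                for j in range(n):
                    if adj[f, v, j] and label[j] < 0:
                        label[j] = ncomp
                        stack[top] = j
                        top += 1
            if size > largest:
                largest = size
            ncomp += 1
        out_count[f] = ncomp
        out_largest[f] = largest
    return out_count, out_largest


def build_catalogue(
    metric_table: pd.DataFrame,
    behaviours: pd.DataFrame,
    min_presence: float = 0.10,
) -> tuple[selection.MetricCatalogue, pd.DataFrame]:
    """Align per-frame metrics and per-clip behaviours into one catalogue.

    Frames and clips are both 10 s units indexed 0..n-1 within a session,
    so rows align on (group, condition, index). Rare behaviours are
    filtered out before inclusion. Returns the catalogue plus the merged
    long table (with group/condition keys) used to build it.
    """
    kept = behaviour.rare_behaviour_filter(behaviours, min_presence)
    wide = behaviour.behaviour_wide(
        behaviours[behaviours["behaviour"].isin(kept)]
    ).rename(columns={"clip_index": "frame_index"})
    merged = metric_table.merge(
        wide, on=["group_id", "condition", "frame_index"], how="inner"
    )
    continuous = [
        "mean_nnd_cm", "cv_nnd", "mean_interindividual_distance_cm",
        "expanse_cm", "convex_hull_area_cm2", "distance_to_wall_cm",
        "density", "n_subgroups", "largest_subgroup_size",
    ]
    metrics = continuous + kept
    values = merged[metrics].reset_index(drop=True)
    category = {m: METRIC_CATEGORY[m] for m in metrics}
    kind = {m: ("binary" if m in kept else "continuous") for m in metrics}
    return selection.MetricCatalogue(values=values, category=category, data_kind=kind), merged


def _check_group_consistency(tables: dict[str, pd.DataFrame]) -> None:
    sets = {name: set(df["group_id"].unique()) for name, df in tables.items()}
    union = set.union(*sets.values())
    offenders = {
        name: sorted(union - s) for name, s in sets.items() if union - s
    }
    if offenders:
        raise ValueError(f"mismatched group sets across inputs: {offenders}")


def analyse_cortisol(
    cortisol: pd.DataFrame, log_offset: float = CORTISOL_DETECTION_LIMIT / 2
) -> inference.LRTResult:
    """Condition test of log whole-body cortisol (group random intercept).

    Concentrations at 0 (below the assay detection limit) break the log
    transform; they are shifted by ``log_offset`` (default: half the
    detection limit) with a warning.
    """
    df = cortisol.rename(columns={"cortisol_ng_per_g": "value"}).copy()
    n_zero = int((df["value"] <= 0).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} cortisol value(s) at/below 0 shifted by +{log_offset} "
            "before log transform"
        )
        df.loc[df["value"] <= 0, "value"] = log_offset
    res = inference.fit_lmm_lrt(df, response="value", transform="log")
    return dataclasses.replace(res, response="cortisol_ng_per_g")


def run_full_analysis(
    positions: pd.DataFrame,
    body_lengths: pd.DataFrame,
    behaviours: pd.DataFrame,
    cortisol: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
    behaviours_recoded: pd.DataFrame | None = None,
) -> AnalysisResult:
    """Execute the full pipeline on long-format input tables."""
    config = config or AnalysisConfig()
    tables = {"positions": positions, "body_lengths": body_lengths,
              "behaviours": behaviours}
    if cortisol is not None:
        tables["cortisol"] = cortisol
    _check_group_consistency(tables)

    metric_table = compute_metric_table(
        positions, body_lengths, config.tank, config.association_multiplier
    )
    catalogue, merged = build_catalogue(
        metric_table, behaviours, config.rare_behaviour_min_presence
    )
    if config.responses is None:
        corr = selection.correlation_matrix(catalogue)
        selected = selection.select_metrics(
            corr, catalogue, config.selection_threshold, config.priority
        )
        responses = selected.retained
    else:
        missing = [r for r in config.responses if r not in catalogue.metrics]
        if missing:
            raise ValueError(f"unknown responses requested: {missing}")
        corr = None
        selected = selection.SelectionResult(
            retained=list(config.responses),
            threshold=config.selection_threshold,
            audit=[{"metric": r, "action": "retained",
                    "reason": "explicitly requested"} for r in config.responses],
        )
        responses = list(config.responses)

    tests = []
    for name in responses:
        obs = merged[["group_id", "condition", name]].rename(columns={name: "value"})
        if catalogue.data_kind[name] == "binary":
            res = inference.fit_glmm_binomial_lrt(obs, response="value")
        else:
            res = inference.fit_lmm_lrt(
                obs, response="value",
                transform=config.transforms.get(name, "none"),
            )
        tests.append(dataclasses.replace(res, response=name))

    cortisol_res = None
    if cortisol is not None:
        cortisol_res = analyse_cortisol(cortisol, config.cortisol_log_offset)

    if config.include_cortisol_in_family and cortisol_res is not None:
        family = inference.adjust_family(
            tests + [cortisol_res], m=config.bonferroni_m
        )
        tests, cortisol_res = family[:-1], family[-1]
    else:
        tests = inference.adjust_family(tests, m=config.bonferroni_m)
        if cortisol_res is not None:
            [cortisol_res] = inference.adjust_family([cortisol_res], m=1)

    reliability = None
    if behaviours_recoded is not None:
        reliability = reliability_report(behaviours, behaviours_recoded)

    return AnalysisResult(
        metric_table=metric_table,
        catalogue=catalogue,
        correlation=corr,
        selected=selected,
        tests=tests,
        cortisol_test=cortisol_res,
        reliability=reliability,
    )


def reliability_report(
    coded: pd.DataFrame, recoded: pd.DataFrame
) -> pd.DataFrame:
    """Per-behaviour intra-observer agreement on the re-scored clips.

    ``recoded`` holds a second coding pass of a clip subset (same long
    schema); agreement and Cohen's kappa are computed per behaviour over
    the clips present in both tables.
    """
    keys = ["group_id", "condition", "clip_index", "behaviour"]
    merged = coded.merge(recoded, on=keys, suffixes=("_1", "_2"))
    rows = []
    for name, sub in merged.groupby("behaviour"):
        a = sub["present_1"].to_numpy()
        b = sub["present_2"].to_numpy()
        rows.append(
            {
                "behaviour": name,
                "percent_agreement": behaviour.percent_agreement(a, b),
                "kappa": behaviour.cohens_kappa(a, b),
                "n_clips_rescored": len(sub),
            }
        )
    return pd.DataFrame(rows)


def render_results_frame(df: pd.DataFrame) -> str:
    """Plain-text summary: per response, direction, chi-squared, adjusted p."""
    lines = [
        "Condition differences (immediate vs after_24h), LRT on 1 df",
        "-" * 64,
        f"{'response':<34}{'dir':>4}{'chi_sq':>11}{'p_adj':>12}",
    ]
    for _, r in df.iterrows():
        direction = "+" if r["coef"] > 0 else "-" if r["coef"] < 0 else "0"
        p = r["p_bonferroni"] if pd.notna(r.get("p_bonferroni")) else r["p_raw"]
        p_str = f"{p:.3g}" if p >= 1e-12 else "<1e-12"
        lines.append(
            f"{r['response']:<34}{direction:>4}{r['chi_sq']:>11.1f}{p_str:>12}"
        )
    lines.append("-" * 64)
    return "\n".join(lines)


def render_report(result: AnalysisResult) -> str:
    """Summary of a full analysis, including the retained metric set."""
    from . import io

    all_tests = list(result.tests)
    if result.cortisol_test is not None:
        all_tests.append(result.cortisol_test)
    text = render_results_frame(io.results_to_frame(all_tests))
    return text + (
        f"\nretained metrics: {', '.join(result.selected.retained)} "
        f"(|r| < {result.selected.threshold})"
    )
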