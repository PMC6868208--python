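"""Correlation-based metric pruning.

Candidate metrics — behavioural, social, proximity and spatial — are highly
collinear in shoal data because most of them describe the same underlying
cohesion. This module computes a mixed-type correlation matrix (Spearman
for non-normal continuous pairs, Pearson otherwise; binary metrics always
use Pearson, i.e. point-biserial/phi) and greedily prunes to a subset whose
pairwise |r| stays below a threshold (0.2 by default), while guaranteeing
that every metric category keeps at least one representative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("behavioural", "social", "proximity", "spatial")

#: priority head: the canonical low-collinearity quintet, one per category
#: plus the second behavioural measure; remaining metrics follow alphabetically.
DEFAULT_PRIORITY_HEAD = [
    "density",
    "cv_nnd",
    "distance_to_wall_cm",
    "erratic_movement",
    "top_half",
]


@dataclass
class MetricCatalogue:
    """Aligned per-observation values plus per-metric typing.

    ``values``: observations x metrics DataFrame (rows aligned across
    metrics, one row per 10 s interval). ``category`` and ``data_kind``
    map metric name -> category / {"continuous", "binary"}.
    """

    values: pd.DataFrame
    category: dict[str, str]
    data_kind: dict[str, str]

    def __post_init__(self) -> None:
        missing = [m for m in self.values.columns if m not in self.category]
        if missing:
            raise ValueError(f"metrics without category: {missing}")
        bad = set(self.category.values()) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")

    @property
    def metrics(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CorrelationMatrix:
    metrics: list[str]
    r: pd.DataFrame          # symmetric, unit diagonal
    method: pd.DataFrame     # per-pair label: "pearson" | "spearman"
    n_obs: pd.DataFrame      # pairwise-complete observation counts


@dataclass
class SelectionResult:
    retained: list[str]
    threshold: float
    audit: list[dict] = field(default_factory=list)


def is_normalish(x: np.ndarray, alpha: float = 0.05, max_n: int = 5000,
                 seed: int = 0) -> bool:
    """Shapiro-Wilk normality screen (subsampled to ``max_n`` values)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3 or np.ptp(x) == 0:
        return False
    if x.size > max_n:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=max_n, replace=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(x).pvalue >= alpha


def choose_correlation_method(
    catalogue: MetricCatalogue, metric_a: str, metric_b: str
) -> str:
    """Spearman for continuous pairs where either member fails normality;
    Pearson for everything else (including any pair involving a binary
    metric, where Pearson r reduces to point-biserial/phi)."""
    kinds = (catalogue.data_kind[metric_a], catalogue.data_kind[metric_b])
    if kinds != ("continuous", "continuous"):
        return "pearson"
    a = catalogue.values[metric_a].to_numpy(float)
    b = catalogue.values[metric_b].to_numpy(float)
    if not (is_normalish(a) and is_normalish(b)):
        return "spearman"
    return "pearson"


def _pair_correlation(a: np.ndarray, b: np.ndarray, method: str) -> tuple[float, int]:
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    n = a.size
    if n < 3:
        raise ValueError("need >=3 pairwise-complete observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("zero-variance metric in correlation pair; r set to 0")
        return 0.0, n
    if method == "spearman":
        r = stats.spearmanr(a, b).statistic
    else:
        r = stats.pearsonr(a, b).statistic
    return float(r), n


def correlation_matrix(catalogue: MetricCatalogue) -> CorrelationMatrix:
    """All-pairs correlation matrix with per-pair method choice."""
    names = catalogue.metrics
    if len(names) < 2:
        raise ValueError("need at least 2 metrics")
    if len(catalogue.values) < 3:
        raise ValueError("need at least 3 observations")
    k = len(names)
    r = np.eye(k)
    meth = np.full((k, k), "pearson", dtype=object)
    nobs = np.full((k, k), len(catalogue.values), dtype=int)
    for i, j in combinations(range(k), 2):
        m = choose_correlation_method(catalogue, names[i], names[j])
        rij, n = _pair_correlation(
            catalogue.values[names[i]].to_numpy(float),
            catalogue.values[names[j]].to_numpy(float),
            m,
        )
        r[i, j] = r[j, i] = rij
        meth[i, j] = meth[j, i] = m
        nobs[i, j] = nobs[j, i] = n
    idx = pd.Index(names)
    return CorrelationMatrix(
        metrics=names,
        r=pd.DataFrame(r, index=idx, columns=idx),
        method=pd.DataFrame(meth, index=idx, columns=idx),
        n_obs=pd.DataFrame(nobs, index=idx, columns=idx),
    )


def default_priority(metrics: list[str]) -> list[str]:
    head = [m for m in DEFAULT_PRIORITY_HEAD if m in metrics]
    tail = sorted(m for m in metrics if m not in head)
    return head + tail


def select_metrics(
    corr: CorrelationMatrix,
    catalogue: MetricCatalogue,
    threshold: float = 0.2,
    priority: list[str] | None = None,
) -> SelectionResult:
    """Greedy pruning to a mutually weakly-correlated metric subset.

    Metrics are visited in priority order; one is accepted iff its |r|
    against every already-accepted metric is strictly below ``threshold``
    (|r| exactly at the threshold counts as correlated). Afterwards, any
    category left empty is repaired by admitting its member with the
    smallest maximum |r| against the accepted set (ties broken by
    priority), logged as constraint-forced.
    """
    metrics = corr.metrics
    if not metrics:
        raise ValueError("empty catalogue")
    order = list(priority) if priority is not None else default_priority(metrics)
    unknown = set(order) - set(metrics)
    if unknown:
        raise ValueError(f"priority names not in catalogue: {sorted(unknown)}")
    order += [m for m in metrics if m not in order]

    absr = corr.r.abs()
    retained: list[str] = []
    audit: list[dict] = []
    for m in order:
        conflicts = [a for a in retained if absr.loc[m, a] >= threshold]
        if conflicts:
            worst = max(conflicts, key=lambda a: absr.loc[m, a])
            audit.append(
                {
                    "metric": m,
                    "action": "excluded",
                    "against": worst,
                    "abs_r": float(absr.loc[m, worst]),
                    "reason": f"|r|={absr.loc[m, worst]:.3f} >= {threshold} vs {worst}",
                }
            )
        else:
            retained.append(m)
            audit.append({"metric": m, "action": "retained", "reason": "passed threshold"})

    covered = {catalogue.category[m] for m in retained}
    for cat in CATEGORIES:
        members = [m for m in order if catalogue.category.get(m) == cat]
        if not members or cat in covered:
            continue
        best = min(
            members,
            key=lambda m: (max((absr.loc[m, a] for a in retained), default=0.0),
                           order.index(m)),
        )
        retained.append(best)
        covered.add(cat)
        audit.append(
            {
                "metric": best,
                "action": "retained",
                "reason": f"constraint-forced: category '{cat}' would be empty",
            }
        )
    # keep retained in priority order for downstream reporting
    retained = [m for m in order if m in retained]
    return SelectionResult(retained=retained, threshold=threshold, audit=audit)


def select_metrics_exact(
    corr: CorrelationMatrix,
    catalogue: MetricCatalogue,
    threshold: float = 0.2,
    priority: list[str] | None = None,
) -> list[str]:
    """Exhaustive-search reference: the largest subset with all pairwise
    |r| < threshold, preferring higher-priority members among ties.

    Exponential in the metric count; intended for <=15 metrics as a
    verification mode for the greedy selector.
    """
    metrics = corr.metrics
    if len(metrics) > 15:
        raise ValueError("exact mode supports at most 15 metrics")
    order = list(priority) if priority is not None else default_priority(metrics)
    order += [m for m in metrics if m not in order]
    rank = {m: i for i, m in enumerate(order)}
    absr = corr.r.abs()
    best: tuple | None = None
    for size in range(len(metrics), 0, -1):
        for subset in combinations(sorted(metrics, key=rank.get), size):
            if all(absr.loc[a, b] < threshold for a, b in combinations(subset, 2)):
                key = (-size, tuple(rank[m] for m in subset))
                if best is None or key < best[0]:
                    best = (key, list(subset))
        if best is not None:
            break
    return best[1] if best else []
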