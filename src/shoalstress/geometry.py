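"""Proximity and spatial metrics of a fish shoal within a rectangular tank.

A *frame* is one time-stamped snapshot of all fish coordinates in a group.
Metrics are computed on 2D top-down coordinates (x, y) in centimetres with
the origin at one tank corner and axes along the walls. Frames with all
fish at an identical position are rejected with :class:`DegenerateFrameError`
rather than producing NaNs, because silent NaN propagation corrupts the
downstream mixed-model fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform


class InsufficientFishError(ValueError):
    """Raised when a frame holds fewer fish than the metric requires."""


class DegenerateFrameError(ValueError):
    """Raised when all fish coincide and a scale-free metric is undefined."""


class OutsideTankError(ValueError):
    """Raised when a position or centroid lies outside the tank walls."""


@dataclass(frozen=True)
class TankGeometry:
    """Rectangular test tank, dimensions in cm.

    Defaults are a 45 x 25 cm footprint filled to 20 cm water depth.
    """

    length_cm: float = 45.0
    width_cm: float = 25.0
    water_depth_cm: float = 20.0

    def __post_init__(self) -> None:
        if not (self.length_cm > 0 and self.width_cm > 0 and self.water_depth_cm > 0):
            raise ValueError("tank dimensions must be strictly positive")

    def contains(self, xy: np.ndarray, atol: float = 1e-9) -> bool:
        xy = np.asarray(xy, dtype=float)
        x, y = xy[..., 0], xy[..., 1]
        return bool(
            np.all(x >= -atol)
            and np.all(x <= self.length_cm + atol)
            and np.all(y >= -atol)
            and np.all(y <= self.width_cm + atol)
        )


def _as_xy(positions) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] < 2:
        raise ValueError("positions must be an (n_fish, >=2) array")
    xy = pos[:, :2]
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-finite coordinate in frame")
    return xy


def pairwise_distances(positions) -> np.ndarray:
    """Symmetric matrix of Euclidean distances (cm) between all fish.

    Distances are computed on the 2D (x, y) coordinates only.
    """
    xy = _as_xy(positions)
    if xy.shape[0] < 2:
        raise InsufficientFishError("insufficient fish: need at least 2")
    return squareform(pdist(xy))


def nearest_neighbour_distances(positions) -> np.ndarray:
    """Per-fish distance to its closest group-mate (cm)."""
    dmat = pairwise_distances(positions)
    np.fill_diagonal(dmat, np.inf)
    return dmat.min(axis=1)


def cv_nearest_neighbour(positions, ddof: int = 1) -> float:
    """Coefficient of variation of the within-frame nearest-neighbour distances.

    Dimensionless (scale-free). Uses the sample standard deviation
    (``ddof=1``) by default. Raises :class:`DegenerateFrameError` when the
    mean NND is zero (all fish coincident).
    """
    nnd = nearest_neighbour_distances(positions)
    mean = nnd.mean()
    if mean <= 0:
        raise DegenerateFrameError("degenerate frame: mean NND is zero")
    return float(nnd.std(ddof=ddof) / mean)


def mean_interindividual_distance(positions) -> float:
    """Mean of all pairwise fish-fish distances (cm)."""
    xy = _as_xy(positions)
    if xy.shape[0] < 2:
        raise InsufficientFishError("insufficient fish: need at least 2")
    return float(pdist(xy).mean())


def centroid(positions) -> np.ndarray:
    """Centre of mass of the shoal: coordinate-wise mean of (x, y)."""
    return _as_xy(positions).mean(axis=0)


def expanse(positions) -> float:
    """Mean Euclidean distance of all fish to the shoal centre of mass (cm)."""
    xy = _as_xy(positions)
    c = xy.mean(axis=0)
    return float(np.linalg.norm(xy - c, axis=1).mean())


def convex_hull_area(positions) -> float:
    """Area (cm^2) of the 2D convex hull of fish positions.

    Collinear or fewer than three distinct points give area 0.
    """
    xy = _as_xy(positions)
    if len(np.unique(xy, axis=0)) < 3:
        return 0.0
    try:
        hull = ConvexHull(xy)
    except QhullError:
        # Qhull rejects degenerate (collinear) input: zero-area hull.
        return 0.0
    return float(hull.volume)  # in 2D "volume" is the polygon area


def distance_to_nearest_wall(positions, tank: TankGeometry) -> float:
    """Distance (cm) of the shoal centre of mass to the nearest tank wall.

    A thigmotaxis measure: the smaller the value, the closer the shoal
    sits to a wall. The centroid must lie inside the tank.
    """
    cx, cy = centroid(positions)
    if not tank.contains(np.array([[cx, cy]])):
        raise OutsideTankError(
            f"position outside tank: centroid ({cx:.3f}, {cy:.3f})"
        )
    return float(min(cx, tank.length_cm - cx, cy, tank.width_cm - cy))


#: FrameMetricRow column order used by metric tables throughout the package.
FRAME_METRIC_COLUMNS = [
    "group_id",
    "condition",
    "frame_index",
    "mean_nnd_cm",
    "cv_nnd",
    "mean_interindividual_distance_cm",
    "expanse_cm",
    "convex_hull_area_cm2",
    "centroid_x_cm",
    "centroid_y_cm",
    "distance_to_wall_cm",
    "density",
    "n_subgroups",
    "largest_subgroup_size",
]


def compute_frame_metrics(
    positions,
    tank: TankGeometry,
    threshold_cm: float,
    group_id=None,
    condition=None,
    frame_index=None,
) -> dict:
    """All per-frame metrics for one frame, as a FrameMetricRow dict.

    ``threshold_cm`` is the association distance (two mean body lengths by
    default upstream); the social fields (density, subgroups) are delegated
    to :mod:`shoalstress.association`.
    """
    from . import association  # local import to avoid cycle

    xy = _as_xy(positions)
    dmat = pairwise_distances(xy)
    nnd = nearest_neighbour_distances(xy)
    mean_nnd = float(nnd.mean())
    if mean_nnd <= 0:
        raise DegenerateFrameError("degenerate frame: mean NND is zero")
    cx, cy = xy.mean(axis=0)
    adj = association.build_association_matrix(xy, threshold_cm, distances=dmat)
    n_sub, sizes = association.subgroups(adj)
    return {
        "group_id": group_id,
        "condition": condition,
        "frame_index": frame_index,
        "mean_nnd_cm": mean_nnd,
        "cv_nnd": float(nnd.std(ddof=1) / mean_nnd),
        "mean_interindividual_distance_cm": float(
            dmat[np.triu_indices_from(dmat, k=1)].mean()
        ),
        "expanse_cm": expanse(xy),
        "convex_hull_area_cm2": convex_hull_area(xy),
        "centroid_x_cm": float(cx),
        "centroid_y_cm": float(cy),
        "distance_to_wall_cm": distance_to_nearest_wall(xy, tank),
        "density": association.network_density(adj),
        "n_subgroups": int(n_sub),
        "largest_subgroup_size": int(sizes[0]),
    }
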