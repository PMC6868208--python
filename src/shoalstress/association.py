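"""Proximity-based association networks and social metrics.

Two fish are taken to be associating when they are within a proximity
threshold of each other — by default twice the mean standard body length
of all fish in the group. Each frame yields a binary, symmetric,
zero-diagonal association matrix from which network density and subgroup
(connected-component) structure are computed.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import InsufficientFishError, pairwise_distances


def association_threshold(body_lengths_mm, multiplier: float = 2.0) -> float:
    """Association distance in cm from per-fish standard lengths in mm.

    ``multiplier`` x mean standard length, converted mm -> cm. The default
    multiplier of 2 gives the conventional "two body lengths" criterion.
    """
    lengths = np.asarray(body_lengths_mm, dtype=float)
    if lengths.size == 0:
        raise ValueError("empty body-length table")
    if np.any(lengths <= 0):
        raise ValueError("body lengths must be strictly positive")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    return float(multiplier * lengths.mean() / 10.0)


def build_association_matrix(
    positions, threshold_cm: float, *, distances: np.ndarray | None = None
) -> np.ndarray:
    """Binary symmetric adjacency: 1 iff pairwise distance <= threshold.

    The boundary is inclusive: a pair exactly at the threshold counts as
    associating. Pass a precomputed ``distances`` matrix to skip the
    distance computation in per-frame loops.
    """
    if threshold_cm <= 0:
        raise ValueError("threshold_cm must be positive")
    dmat = pairwise_distances(positions) if distances is None else distances
    adj = (dmat <= threshold_cm).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return adj


def network_density(adj: np.ndarray) -> float:
    """Fraction of realised associations out of all n(n-1)/2 possible pairs."""
    n = adj.shape[0]
    if n < 2:
        raise InsufficientFishError("insufficient fish: need at least 2")
    edges = int(np.triu(adj, k=1).sum())
    return edges / (n * (n - 1) / 2)


def associating_individual_fraction(adj: np.ndarray) -> float:
    """Alternative numerator: fraction of individuals with >=1 association.

    Kept as a secondary reading of "number of individuals associating";
    the canonical density above is the pairwise graph density.
    """
    n = adj.shape[0]
    if n < 2:
        raise InsufficientFishError("insufficient fish: need at least 2")
    return float((adj.sum(axis=1) > 0).sum() / n)


def subgroups(adj: np.ndarray) -> tuple[int, list[int]]:
    """Connected components of the association graph.

    Returns ``(n_components, sizes)`` with sizes sorted descending. An
    isolated fish is its own subgroup of size 1.
    """
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    sizes = sorted(np.bincount(labels).tolist(), reverse=True)
    return int(n_comp), sizes


def edge_list(adj: np.ndarray) -> list[tuple[int, int]]:
    """Upper-triangle (i, j) pairs with an association, i < j."""
    ii, jj = np.nonzero(np.triu(adj, k=1))
    return list(zip(ii.tolist(), jj.tolist()))
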