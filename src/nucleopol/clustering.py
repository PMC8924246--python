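"""Density-based cluster detection on localisation tables.

DBSCAN with the parameterisation used for nuclear SMLM data: a localisation
is a core point when at least ``min_pts`` *other* localisations lie within
``epsilon`` of it (the neighbour count excludes the point itself, so the
default ``min_pts = 3`` means "a minimum of three molecules within the
search area"); ``epsilon`` defaults to the mean localisation precision of
the dye; density-connected groups below ``min_cluster_size`` (default 10
localisations) revert to noise. Border points join the first core cluster
that reaches them when points are scanned in index order, which makes the
labelling deterministic for a given row order.

Cluster area is the area of the iso-density contour of a Gaussian
kernel-density surface (bandwidth ``smoothing_sigma``, default 7 nm) at the
level that encloses every member, evaluated on a 5 nm grid; groups of fewer
than 5 members fall back to the convex hull.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClusterMixin

from .ripley import _as_xy

__all__ = [
    "ClusterParams",
    "ClusterSummary",
    "DensityClusterer",
    "dbscan_labels",
    "detect_clusters",
    "summarize_clusters",
    "cluster_area",
]

NOISE = -1


@dataclass
class ClusterParams:
    """DBSCAN + cluster-filter parameters (lengths in nm)."""

    epsilon: float = 20.0
    min_pts: int = 3
    min_cluster_size: int = 10
    smoothing_sigma: float = 7.0

    def validate(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")
        if self.min_cluster_size < self.min_pts:
            raise ValueError("min_cluster_size must be >= min_pts")


@dataclass
class ClusterSummary:
    """Per-ROI clustering summary."""

    n_clusters: int
    mean_molecules_per_cluster: float
    mean_area: float
    percent_clustered: float


def dbscan_labels(points, epsilon: float, min_pts: int) -> np.ndarray:
    """Per-point cluster labels (0, 1, …) with −1 for noise.

    Core point: ≥ ``min_pts`` neighbours within ``epsilon``, the point
    itself excluded. Clusters are maximal density-connected sets; border
    points take the label of the first core cluster that reaches them in
    the deterministic index-order scan.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    xy = _as_xy(points)
    n = len(xy)
    labels = np.full(n, NOISE, dtype=int)
    if n == 0:
        return labels
    tree = cKDTree(xy)
    neighbors = tree.query_ball_point(xy, epsilon)
    n_others = np.array([len(nb) - 1 for nb in neighbors])
    core = n_others >= min_pts

    cluster_id = 0
    for i in range(n):
        if labels[i] != NOISE or not core[i]:
            continue
        labels[i] = cluster_id
        queue = deque(sorted(neighbors[i]))
        while queue:
            j = queue.popleft()
            if labels[j] == NOISE:
                labels[j] = cluster_id
                if core[j]:
                    queue.extend(sorted(neighbors[j]))
        cluster_id += 1
    return labels


def cluster_area(members, smoothing_sigma: float = 7.0, grid_step: float = 5.0):
    """Area (nm²) occupied by a cluster's member localisations.

    ≥ 5 members: area of the Gaussian-KDE iso-density contour (bandwidth
    ``smoothing_sigma``) at the level enclosing all members, on a
    ``grid_step`` nm grid. 3–4 members: convex-hull area. Collinear or
    < 3 members: degenerate (area 0, flagged).

    Returns
    -------
    (area, degenerate_flag)
    """
    xy = np.asarray(members, float).reshape(-1, 2)
    if len(xy) < 3:
        return 0.0, True
    span = xy.max(axis=0) - xy.min(axis=0)
    # collinearity via the smaller singular value of the centred coordinates
    s = np.linalg.svd(xy - xy.mean(axis=0), compute_uv=False)
    if s[-1] < 1e-9 * max(s[0], 1.0):
        return 0.0, True
    if len(xy) < 5:
        from scipy.spatial import ConvexHull

        return float(ConvexHull(xy).volume), False

    pad = 3.0 * smoothing_sigma
    x = np.arange(xy[:, 0].min() - pad, xy[:, 0].max() + pad + grid_step, grid_step)
    y = np.arange(xy[:, 1].min() - pad, xy[:, 1].max() + pad + grid_step, grid_step)
    gx, gy = np.meshgrid(x, y)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    inv2s2 = 1.0 / (2.0 * smoothing_sigma**2)

    def density(at):
        d2 = (
            (at[:, None, 0] - xy[None, :, 0]) ** 2
            + (at[:, None, 1] - xy[None, :, 1]) ** 2
        )
        return np.exp(-d2 * inv2s2).sum(axis=1)

    level = density(xy).min()
    dens = density(grid)
    return float((dens >= level).sum() * grid_step**2), False


class DensityClusterer(BaseEstimator, ClusterMixin):
    """Detect localisation clusters by DBSCAN with a minimum-size filter.

    Parameters mirror :class:`ClusterParams`; ``epsilon=None`` uses the mean
    ``precision_nm`` of the fitted table (the dye's localisation precision),
    or the supplied ``epsilon_override`` at fit time (e.g. a Ripley peak
    radius when following the r_max policy).

    Attributes (after ``fit``)
    --------------------------
    labels_ : (n,) int array, −1 for noise
    clusters_ : DataFrame
        One row per retained cluster: ``cluster_id, n_molecules,
        centroid_x_nm, centroid_y_nm, area_nm2, degenerate_area``.
    summary_ : ClusterSummary
    epsilon_ : float — the epsilon actually used
    """

    def __init__(
        self,
        epsilon: float | None = None,
        min_pts: int = 3,
        min_cluster_size: int = 10,
        smoothing_sigma: float = 7.0,
    ):
        self.epsilon = epsilon
        self.min_pts = min_pts
        self.min_cluster_size = min_cluster_size
        self.smoothing_sigma = smoothing_sigma

    def fit(self, X, y=None, epsilon_override: float | None = None):
        xy = _as_xy(X)
        if epsilon_override is not None:
            eps = float(epsilon_override)
        elif self.epsilon is not None:
            eps = float(self.epsilon)
        elif hasattr(X, "columns") and "precision_nm" in X.columns:
            eps = float(np.asarray(X["precision_nm"], float).mean())
        else:
            raise ValueError(
                "epsilon not set and input has no precision_nm column to derive it"
            )
        params = ClusterParams(
            epsilon=eps,
            min_pts=self.min_pts,
            min_cluster_size=self.min_cluster_size,
            smoothing_sigma=self.smoothing_sigma,
        )
        params.validate()
        self.epsilon_ = eps

        labels = dbscan_labels(xy, eps, self.min_pts)
        # groups below the minimum size revert to noise; survivors renumbered
        rows = []
        new_labels = np.full(len(xy), NOISE, dtype=int)
        next_id = 0
        for cid in range(labels.max() + 1 if len(labels) else 0):
            members = np.flatnonzero(labels == cid)
            if len(members) < self.min_cluster_size:
                continue
            area, degenerate = cluster_area(xy[members], self.smoothing_sigma)
            centroid = xy[members].mean(axis=0)
            rows.append(
                {
                    "cluster_id": next_id,
                    "n_molecules": len(members),
                    "centroid_x_nm": centroid[0],
                    "centroid_y_nm": centroid[1],
                    "area_nm2": area,
                    "degenerate_area": degenerate,
                }
            )
            new_labels[members] = next_id
            next_id += 1
        self.labels_ = new_labels
        self.clusters_ = pd.DataFrame(
            rows,
            columns=[
                "cluster_id",
                "n_molecules",
                "centroid_x_nm",
                "centroid_y_nm",
                "area_nm2",
                "degenerate_area",
            ],
        )
        self.summary_ = _summarize(self.clusters_, self.labels_)
        return self

    def fit_predict(self, X, y=None, **kw):
        return self.fit(X, **kw).labels_


def _summarize(clusters: pd.DataFrame, labels: np.ndarray) -> ClusterSummary:
    n_clusters = len(clusters)
    n_total = len(labels)
    n_in = int((labels != NOISE).sum())
    return ClusterSummary(
        n_clusters=n_clusters,
        mean_molecules_per_cluster=(
            float(clusters["n_molecules"].mean()) if n_clusters else float("nan")
        ),
        mean_area=float(clusters["area_nm2"].mean()) if n_clusters else float("nan"),
        percent_clustered=100.0 * n_in / n_total if n_total else 0.0,
    )


def detect_clusters(points, params: ClusterParams | None = None) -> DensityClusterer:
    """Functional wrapper: fit a :class:`DensityClusterer` and return it
    (``labels_``, ``clusters_`` and ``summary_`` carry the ClusterSet)."""
    params = params or ClusterParams()
    params.validate()
    est = DensityClusterer(
        epsilon=params.epsilon,
        min_pts=params.min_pts,
        min_cluster_size=params.min_cluster_size,
        smoothing_sigma=params.smoothing_sigma,
    )
    return est.fit(points)


def summarize_clusters(clusterer: DensityClusterer) -> ClusterSummary:
    """Per-ROI summary of a fitted clusterer."""
    return clusterer.summary_
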