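"""Coordinate-based colocalisation: per-molecule degree-of-colocalisation.

For each localisation *i* of channel A (and symmetrically for B), density
gradients are accumulated over radii r ∈ {r_step, 2·r_step, …, r_max}:

    D_A,i(r) = (N_A,i(r) / N_A,i(r_max)) · (r_max² / r²)
    D_B,i(r) = (N_B,i(r) / N_B,i(r_max)) · (r_max² / r²)

where N_A,i(r) counts same-channel neighbours (excluding *i* itself) and
N_B,i(r) counts other-channel neighbours at strictly positive distance —
exactly-coincident molecules are excluded from both counts, mirroring the
self-exclusion. For continuous coordinates this is a measure-zero
convention; it makes the perfect-copy identity exact (a channel duplicated
onto itself has identical gradient vectors, hence score 1 everywhere the
vector is defined). The degree of colocalisation is
the Spearman rank correlation of the two gradient vectors (average-rank tie
handling), damped by the distance d_i to the nearest other-channel molecule:

    DoC_i = ρ_S(D_A,i, D_B,i) · exp(−d_i / r_max)

Scores lie in [−1, 1]: +1 for perfectly colocalised molecules, −1 for
segregated ones. A molecule whose gradient vector is degenerate (no
neighbours at r_max, or zero variance) scores 0 and is flagged undefined.
Molecules with score above the threshold (default 0.4) are classified
colocalised; clusters containing at least ``min_coloc_in_cluster`` such
members are colocalised clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .clustering import NOISE, DensityClusterer
from .ripley import _as_xy

__all__ = [
    "DoCParams",
    "DoCResult",
    "DegreeOfColocalization",
    "doc_scores",
    "coloc_cluster_breakdown",
]


class InsufficientDataError(ValueError):
    """A channel has fewer than 2 points."""


@dataclass
class DoCParams:
    """DoC scoring parameters (lengths in nm)."""

    r_max: float = 500.0
    r_step: float = 20.0
    threshold: float = 0.4
    min_coloc_in_cluster: int = 5

    def validate(self) -> None:
        if not 0 < self.r_step < self.r_max:
            raise ValueError("need 0 < r_step < r_max")
        if not -1 < self.threshold < 1:
            raise ValueError("threshold must be in (-1, 1)")


@dataclass
class DoCResult:
    """Per-localisation DoC scores and threshold classification."""

    scores_A: np.ndarray
    scores_B: np.ndarray
    flags_A: np.ndarray
    flags_B: np.ndarray
    defined_A: np.ndarray
    defined_B: np.ndarray
    percent_A: float
    percent_B: float
    threshold: float


def _spearman_rows(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rank correlation with average-rank ties.

    Returns nan for rows where either vector has zero variance.
    """
    ru = np.apply_along_axis(rankdata, 1, u)
    rv = np.apply_along_axis(rankdata, 1, v)
    ru = ru - ru.mean(axis=1, keepdims=True)
    rv = rv - rv.mean(axis=1, keepdims=True)
    su = np.sqrt((ru**2).sum(axis=1))
    sv = np.sqrt((rv**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ru * rv).sum(axis=1) / (su * sv)
    rho[(su == 0) | (sv == 0)] = np.nan
    return rho


def _channel_scores(xy_self, xy_other, radii, r_max):
    """DoC scores for every point of one channel against the other."""
    tree_self = cKDTree(xy_self)
    tree_other = cKDTree(xy_other)
    n = len(xy_self)
    m = len(radii)
    N_self = np.empty((n, m))
    N_other = np.empty((n, m))
    # zero-radius query counts exactly-coincident molecules, excluded below
    n_coincident = tree_other.query_ball_point(xy_self, 0.0, return_length=True)
    for k, r in enumerate(radii):
        N_self[:, k] = tree_self.query_ball_point(xy_self, r, return_length=True) - 1
        N_other[:, k] = (
            tree_other.query_ball_point(xy_self, r, return_length=True) - n_coincident
        )
    scale = (r_max / radii) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        D_self = N_self / N_self[:, -1][:, None] * scale[None, :]
        D_other = N_other / N_other[:, -1][:, None] * scale[None, :]
    undefined = (N_self[:, -1] == 0) | (N_other[:, -1] == 0)
    D_self[undefined] = 0.0
    D_other[undefined] = 0.0

    rho = _spearman_rows(D_self, D_other)
    d_nn, _ = tree_other.query(xy_self, k=1)
    scores = rho * np.exp(-np.asarray(d_nn) / r_max)
    defined = ~undefined & ~np.isnan(rho)
    scores = np.where(defined, scores, 0.0)
    return scores, defined


class DegreeOfColocalization(BaseEstimator):
    """Two-channel coordinate-based colocalisation scorer.

    Parameters mirror :class:`DoCParams`. ``fit(X_a, X_b)`` computes scores
    for both channels; swapping the channels swaps the score arrays exactly.

    Attributes (after ``fit``)
    --------------------------
    result_ : DoCResult
    radii_ : ndarray — the gradient radii grid actually used
    """

    def __init__(
        self,
        r_max: float = 500.0,
        r_step: float = 20.0,
        threshold: float = 0.4,
        min_coloc_in_cluster: int = 5,
    ):
        self.r_max = r_max
        self.r_step = r_step
        self.threshold = threshold
        self.min_coloc_in_cluster = min_coloc_in_cluster

    def fit(self, X_a, X_b, y=None):
        params = DoCParams(
            r_max=self.r_max,
            r_step=self.r_step,
            threshold=self.threshold,
            min_coloc_in_cluster=self.min_coloc_in_cluster,
        )
        params.validate()
        xy_a = _as_xy(X_a)
        xy_b = _as_xy(X_b)
        if len(xy_a) < 2 or len(xy_b) < 2:
            raise InsufficientDataError("each channel needs at least 2 points")
        radii = np.arange(self.r_step, self.r_max + 0.5 * self.r_step, self.r_step)
        self.radii_ = radii
        scores_a, defined_a = _channel_scores(xy_a, xy_b, radii, self.r_max)
        scores_b, defined_b = _channel_scores(xy_b, xy_a, radii, self.r_max)
        flags_a = scores_a > self.threshold
        flags_b = scores_b > self.threshold
        self.result_ = DoCResult(
            scores_A=scores_a,
            scores_B=scores_b,
            flags_A=flags_a,
            flags_B=flags_b,
            defined_A=defined_a,
            defined_B=defined_b,
            percent_A=100.0 * flags_a.mean() if len(flags_a) else 0.0,
            percent_B=100.0 * flags_b.mean() if len(flags_b) else 0.0,
            threshold=self.threshold,
        )
        return self


def doc_scores(table_A, table_B, params: DoCParams | None = None) -> DoCResult:
    """Functional wrapper over :class:`DegreeOfColocalization`."""
    params = params or DoCParams()
    est = DegreeOfColocalization(
        r_max=params.r_max,
        r_step=params.r_step,
        threshold=params.threshold,
        min_coloc_in_cluster=params.min_coloc_in_cluster,
    )
    est.fit(table_A, table_B)
    return est.result_


def _breakdown_one(clusterer: DensityClusterer, flags: np.ndarray, min_members: int):
    labels = clusterer.labels_
    if len(labels) != len(flags):
        raise ValueError("cluster labels and DoC flags have mismatched lengths")
    rows = []
    for _, cl in clusterer.clusters_.iterrows():
        cid = int(cl["cluster_id"])
        members = labels == cid
        n_flagged = int(flags[members].sum())
        rows.append(
            {
                "cluster_id": cid,
                "n_molecules": int(cl["n_molecules"]),
                "area_nm2": float(cl["area_nm2"]),
                "n_colocalized_molecules": n_flagged,
                "colocalized": n_flagged >= min_members,
            }
        )
    per_cluster = pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "n_molecules",
            "area_nm2",
            "n_colocalized_molecules",
            "colocalized",
        ],
    )
    summary = []
    for coloc in (True, False):
        sub = per_cluster[per_cluster["colocalized"] == coloc]
        summary.append(
            {
                "subpopulation": "colocalized" if coloc else "non_colocalized",
                "n_clusters": len(sub),
                "mean_area_nm2": float(sub["area_nm2"].mean()) if len(sub) else float("nan"),
                "mean_molecules": float(sub["n_molecules"].mean()) if len(sub) else float("nan"),
            }
        )
    return per_cluster, pd.DataFrame(summary)


def coloc_cluster_breakdown(
    clusterer_A: DensityClusterer,
    clusterer_B: DensityClusterer,
    doc: DoCResult,
    params: DoCParams | None = None,
) -> dict:
    """Colocalised vs non-colocalised cluster breakdown for both channels.

    A cluster is colocalised when it holds at least ``min_coloc_in_cluster``
    members whose DoC score exceeds the threshold.

    Returns a dict with per-cluster and summary DataFrames per channel.
    """
    params = params or DoCParams()
    per_a, sum_a = _breakdown_one(clusterer_A, doc.flags_A, params.min_coloc_in_cluster)
    per_b, sum_b = _breakdown_one(clusterer_B, doc.flags_B, params.min_coloc_in_cluster)
    return {
        "clusters_A": per_a,
        "summary_A": sum_a,
        "clusters_B": per_b,
        "summary_B": sum_b,
    }
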