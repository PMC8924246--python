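"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a statistic by exhaustive enumeration over a
pairwise distance matrix (no spatial index), so it shares no code path
with the implementations it checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.stats import spearmanr


def pairwise_distances(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    b = a if b is None else b
    return np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))


def dbscan_bruteforce(xy: np.ndarray, epsilon: float, min_pts: int) -> np.ndarray:
    """Textbook DBSCAN via an exhaustive region query.

    Core point: >= min_pts neighbours within epsilon excluding itself.
    Points scanned in index order; border points take the label of the
    first cluster whose expansion reaches them.
    """
    n = len(xy)
    d = pairwise_distances(xy)
    neighbors = [list(np.flatnonzero(d[i] <= epsilon)) for i in range(n)]
    core = np.array([len(nb) - 1 >= min_pts for nb in neighbors])
    labels = np.full(n, -1, dtype=int)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        queue = deque(sorted(neighbors[i]))
        while queue:
            j = queue.popleft()
            if labels[j] == -1:
                labels[j] = cid
                if core[j]:
                    queue.extend(sorted(neighbors[j]))
        cid += 1
    return labels


def ripley_k_bruteforce(xy: np.ndarray, area: float, radii: np.ndarray) -> np.ndarray:
    """Uncorrected Ripley K by the naive double loop."""
    n = len(xy)
    d = pairwise_distances(xy)
    K = np.empty(len(radii))
    for k, r in enumerate(radii):
        count = 0
        for i in range(n):
            for j in range(n):
                if i != j and d[i, j] <= r:
                    count += 1
        K[k] = area / (n * (n - 1)) * count
    return K


def doc_scores_bruteforce(
    xy_a: np.ndarray, xy_b: np.ndarray, r_max: float, r_step: float
) -> tuple[np.ndarray, np.ndarray]:
    """Naive all-pairs DoC scores for channel A against channel B.

    Same conventions as the implementation: self excluded from the
    same-channel counts, exactly-coincident points excluded from the
    cross-channel counts; Spearman via scipy.stats.spearmanr.
    """
    radii = np.arange(r_step, r_max + 0.5 * r_step, r_step)
    d_aa = pairwise_distances(xy_a)
    d_ab = pairwise_distances(xy_a, xy_b)
    scores = np.zeros(len(xy_a))
    defined = np.zeros(len(xy_a), dtype=bool)
    for i in range(len(xy_a)):
        n_self = np.array([(d_aa[i] <= r).sum() - 1 for r in radii], float)
        n_other = np.array(
            [((d_ab[i] <= r) & (d_ab[i] > 0)).sum() for r in radii], float
        )
        if n_self[-1] == 0 or n_other[-1] == 0:
            continue
        scale = (r_max / radii) ** 2
        u = n_self / n_self[-1] * scale
        v = n_other / n_other[-1] * scale
        if np.all(u == u[0]) or np.all(v == v[0]):
            continue
        rho = spearmanr(u, v).statistic
        if np.isnan(rho):
            continue
        scores[i] = rho * np.exp(-d_ab[i].min() / r_max)
        defined[i] = True
    return scores, defined


def msd_bruteforce(xyz: np.ndarray, frames: np.ndarray, dt: float):
    """Time-averaged MSD by enumerating every frame pair."""
    max_lag = int(frames.max() - frames.min())
    lags, msds, counts = [], [], []
    for k in range(1, max_lag + 1):
        sq = []
        for i in range(len(frames)):
            for j in range(len(frames)):
                if frames[j] - frames[i] == k:
                    sq.append(((xyz[j] - xyz[i]) ** 2).sum())
        if sq:
            lags.append(k * dt)
            msds.append(np.mean(sq))
            counts.append(len(sq))
    return np.array(lags), np.array(msds), np.array(counts)
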