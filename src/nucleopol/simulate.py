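"""Synthetic data with the statistical structure the analyses assume.

Four generators, all deterministic given a single integer seed:

* complete spatial randomness (CSR) point patterns;
* Thomas-process clustered patterns (Poisson per-cluster counts, Gaussian
  offsets) emulating nuclear SMLM data — defaults target the measured regime
  of nuclear myosin VI (≈500 clusters of ≈64 molecules per ~10 µm nucleus,
  ~19% non-clustered background);
* two-channel patterns with a controllable colocalised fraction of cluster
  centres, for colocalisation benchmarks;
* 3D (or 2D) anomalous-diffusion trajectories sampled from fractional
  Brownian motion so the ensemble MSD obeys MSD(τ) = 2·d·D·τ^α;
* actin-activated ATPase titrations from the Michaelis–Menten-with-offset
  rate law Rate = V0 + kcat·[A]/(K_actin + [A]).

Ground-truth labels always travel alongside the simulated tables on separate
outputs; analysis code never consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream
from .io import ROI, rectangle_roi

__all__ = [
    "PatternSpec",
    "TwoChannelSpec",
    "TrackSimSpec",
    "KineticsSimSpec",
    "simulate_csr",
    "simulate_clustered",
    "simulate_two_channel",
    "simulate_tracks",
    "simulate_atpase",
    "default_roi",
]


class ParameterError(ValueError):
    """A simulation spec violates its invariants."""


def default_roi() -> ROI:
    """10 × 10 µm square ROI — the scale of a HeLa nucleus mid-section."""
    return rectangle_roi(10_000.0, 10_000.0)


def _points_in_roi(n: int, roi: ROI, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside an arbitrary simple polygon by rejection."""
    minx, miny, maxx, maxy = roi.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(16, int(1.5 * (n - len(out)) * (maxx - minx) * (maxy - miny) / max(roi.area, 1e-12)))
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        keep = roi.contains_points(cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[keep]])
    return out[:n]


def _as_table(xy: np.ndarray, channel: str, precision: float, rng) -> pd.DataFrame:
    n = len(xy)
    return pd.DataFrame(
        {
            "x_nm": xy[:, 0],
            "y_nm": xy[:, 1],
            "frame": np.arange(n, dtype=int),
            "precision_nm": np.full(n, float(precision)),
            "channel": channel,
        }
    )


def simulate_csr(n: int, roi: ROI | None = None, seed: int = 0, channel: str = "A",
                 precision_nm: float = 20.0) -> pd.DataFrame:
    """*n* uniform points over the ROI (complete spatial randomness)."""
    if n < 0:
        raise ParameterError("n must be >= 0")
    roi = roi or default_roi()
    rng = stream(seed, "csr")
    xy = _points_in_roi(n, roi, rng)
    return _as_table(xy, channel, precision_nm, rng)


@dataclass
class PatternSpec:
    """Thomas-process pattern parameters.

    Defaults reproduce the measured nuclear myosin VI regime: 504 clusters
    of on average 64 molecules with ~20 nm cluster spread in a 10 µm square
    ROI, 19% of localisations as non-clustered background, and 20 nm
    localisation precision (Alexa-647-class dye).
    """

    roi: ROI = field(default_factory=default_roi)
    n_clusters: int = 504
    molecules_per_cluster: float = 64.0
    cluster_sigma: float = 20.0
    background_fraction: float = 0.19
    precision_sigma: float = 20.0
    seed: int = 0
    channel: str = "A"

    def validate(self) -> None:
        if self.n_clusters < 0:
            raise ParameterError("n_clusters must be >= 0")
        if self.molecules_per_cluster < 1:
            raise ParameterError("molecules_per_cluster must be >= 1")
        if self.cluster_sigma <= 0:
            raise ParameterError("cluster_sigma must be > 0")
        if not 0 <= self.background_fraction < 1:
            raise ParameterError("background_fraction must be in [0, 1)")


def simulate_clustered(spec: PatternSpec, centers: np.ndarray | None = None):
    """Thomas-process clustered pattern plus uniform background.

    Cluster centres are uniform in the ROI (or supplied via *centers*),
    per-cluster counts are Poisson(molecules_per_cluster), member offsets are
    isotropic Gaussian with sd ``cluster_sigma``, localisation jitter with sd
    ``precision_sigma`` is added to every point, and uniform background
    points are appended so they form ``background_fraction`` of the total.

    Returns
    -------
    (DataFrame, DataFrame)
        The localisation table and a ground-truth sidecar with one row per
        localisation: ``true_cluster`` (-1 for background) and the generating
        centre coordinates.
    """
    spec.validate()
    rng = stream(spec.seed, f"clustered/{spec.channel}")
    if centers is None:
        centers = _points_in_roi(spec.n_clusters, spec.roi, rng)
    centers = np.asarray(centers, float)
    counts = rng.poisson(spec.molecules_per_cluster, size=len(centers))
    labels = np.repeat(np.arange(len(centers)), counts)
    base = centers[labels] + rng.normal(0.0, spec.cluster_sigma, size=(counts.sum(), 2))

    n_clustered = len(base)
    if spec.background_fraction > 0 and n_clustered > 0:
        n_bg = rng.poisson(
            n_clustered * spec.background_fraction / (1 - spec.background_fraction)
        )
    elif n_clustered == 0:
        n_bg = 0
    else:
        n_bg = 0
    bg = _points_in_roi(n_bg, spec.roi, rng)

    xy = np.vstack([base, bg])
    xy = xy + rng.normal(0.0, spec.precision_sigma, size=xy.shape)
    all_labels = np.concatenate([labels, np.full(n_bg, -1, dtype=int)])
    table = _as_table(xy, spec.channel, spec.precision_sigma if spec.precision_sigma > 0 else 20.0, rng)
    truth = pd.DataFrame(
        {
            "true_cluster": all_labels,
            "center_x_nm": np.concatenate(
                [centers[labels][:, 0] if n_clustered else np.empty(0), np.full(n_bg, np.nan)]
            ),
            "center_y_nm": np.concatenate(
                [centers[labels][:, 1] if n_clustered else np.empty(0), np.full(n_bg, np.nan)]
            ),
        }
    )
    return table, truth


@dataclass
class TwoChannelSpec:
    """Two-channel pattern with a controllable colocalised fraction.

    A ``coloc_fraction`` share of channel-B cluster centres is placed at
    channel-A centres displaced by Gaussian noise (sd ``displacement_sigma``);
    the remaining B centres are independent.
    """

    spec_A: PatternSpec = field(default_factory=lambda: PatternSpec(channel="A"))
    spec_B: PatternSpec = field(default_factory=lambda: PatternSpec(channel="B"))
    coloc_fraction: float = 0.2
    displacement_sigma: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        self.spec_A.validate()
        self.spec_B.validate()
        if not 0 <= self.coloc_fraction <= 1:
            raise ParameterError("coloc_fraction must be in [0, 1]")


def simulate_two_channel(spec: TwoChannelSpec):
    """Simulate both channels; returns (table_A, table_B, truth dict)."""
    spec.validate()
    rng = stream(spec.seed, "two_channel")
    spec.spec_A.seed = spec.seed
    spec.spec_B.seed = spec.seed

    centers_A = _points_in_roi(spec.spec_A.n_clusters, spec.spec_A.roi, rng)
    n_B = spec.spec_B.n_clusters
    n_shared = int(round(spec.coloc_fraction * n_B))
    n_shared = min(n_shared, len(centers_A))
    if n_shared > 0:
        chosen = rng.choice(len(centers_A), size=n_shared, replace=False)
        shared = centers_A[chosen] + rng.normal(
            0.0, spec.displacement_sigma, size=(n_shared, 2)
        )
    else:
        shared = np.empty((0, 2))
    indep = _points_in_roi(n_B - n_shared, spec.spec_B.roi, rng)
    centers_B = np.vstack([shared, indep])

    table_A, truth_A = simulate_clustered(spec.spec_A, centers=centers_A)
    table_B, truth_B = simulate_clustered(spec.spec_B, centers=centers_B)
    truth = {
        "truth_A": truth_A,
        "truth_B": truth_B,
        "coloc_fraction": (n_shared / n_B) if n_B else 0.0,
        "n_shared_centers": n_shared,
        "shared_center_ids_B": np.arange(n_shared),
    }
    return table_A, table_B, truth


@dataclass
class TrackSimSpec:
    """Fractional-Brownian-motion trajectory simulation.

    The ensemble MSD obeys MSD(τ) = 2·dims·D·τ^α (α = 1 reduces to ordinary
    Brownian motion with independent Gaussian steps). ``mixture`` overrides
    (D, alpha) with a list of (weight, D, alpha) components sampled per
    track. Localisation error is iid Gaussian per frame per axis.
    """

    n_tracks: int = 200
    frames: int = 100
    dt: float = 0.032
    D: float = 0.4
    alpha: float = 1.0
    dims: int = 3
    loc_error_sigma: float = 0.02
    mixture: list | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.D < 0:
            raise ParameterError("D must be >= 0")
        if self.alpha <= 0:
            raise ParameterError("alpha must be > 0")
        if self.dims not in (2, 3):
            raise ParameterError("dims must be 2 or 3")
        if self.frames < 2:
            raise ParameterError("frames must be >= 2")
        if self.mixture is not None:
            w = sum(m[0] for m in self.mixture)
            if abs(w - 1.0) > 1e-9:
                raise ParameterError("mixture weights must sum to 1")
            for _, D, alpha in self.mixture:
                if D < 0 or alpha <= 0:
                    raise ParameterError("mixture D >= 0 and alpha > 0 required")


def _fgn_cholesky(n_steps: int, alpha: float, dt: float) -> np.ndarray:
    """Cholesky factor of the unit-D fractional-Gaussian-noise covariance.

    cov(Δi, Δj) = (dt^α / 2)(|k+1|^α + |k−1|^α − 2|k|^α), k = |i−j|; the
    resulting increments integrate to a path with Var[x(t)] = t^α per axis
    (multiply by sqrt(2D) for diffusion constant D).
    """
    k = np.abs(np.subtract.outer(np.arange(n_steps), np.arange(n_steps))).astype(float)
    cov = 0.5 * dt**alpha * (
        np.abs(k + 1) ** alpha + np.abs(k - 1) ** alpha - 2 * k**alpha
    )
    # jitter guards against numerically semi-definite covariances at alpha ~ 2
    return np.linalg.cholesky(cov + 1e-12 * np.eye(n_steps))


def simulate_tracks(spec: TrackSimSpec):
    """Simulate trajectories; returns (trajectory DataFrame, truth DataFrame).

    Truth columns: ``track_id, D, alpha, mobility_class`` (class from the
    static/diffusive/hypermobile D thresholds used by the tracking analysis).
    """
    spec.validate()
    rng = stream(spec.seed, "tracks")
    n_steps = spec.frames - 1

    if spec.mixture is not None:
        weights = np.array([m[0] for m in spec.mixture])
        comp = rng.choice(len(spec.mixture), size=spec.n_tracks, p=weights)
        Ds = np.array([spec.mixture[c][1] for c in comp])
        alphas = np.array([spec.mixture[c][2] for c in comp])
    else:
        Ds = np.full(spec.n_tracks, spec.D)
        alphas = np.full(spec.n_tracks, spec.alpha)

    chol_cache: dict[float, np.ndarray] = {}
    rows = []
    truth_rows = []
    t = np.arange(spec.frames) * spec.dt
    for tid in range(spec.n_tracks):
        D, alpha = float(Ds[tid]), float(alphas[tid])
        if D == 0:
            pos = np.zeros((spec.frames, spec.dims))
        else:
            L = chol_cache.get(alpha)
            if L is None:
                L = _fgn_cholesky(n_steps, alpha, spec.dt)
                chol_cache[alpha] = L
            z = rng.standard_normal((n_steps, spec.dims))
            steps = np.sqrt(2.0 * D) * (L @ z)
            pos = np.vstack([np.zeros(spec.dims), np.cumsum(steps, axis=0)])
        # random origin inside a 10 µm nucleus-scale box
        pos = pos + rng.uniform(0.0, 10.0, size=spec.dims)
        if spec.loc_error_sigma > 0:
            pos = pos + rng.normal(0.0, spec.loc_error_sigma, size=pos.shape)
        rec = {
            "track_id": tid,
            "frame": np.arange(spec.frames),
            "t_s": t,
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
        }
        if spec.dims == 3:
            rec["z_um"] = pos[:, 2]
        rows.append(pd.DataFrame(rec))
        if D < 0.1:
            cls = "static"
        elif D <= 5:
            cls = "diffusive"
        else:
            cls = "hypermobile"
        truth_rows.append({"track_id": tid, "D": D, "alpha": alpha, "mobility_class": cls})

    traj = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return traj, truth


@dataclass
class KineticsSimSpec:
    """Actin-activated ATPase titration simulation.

    Rate([A]) = V0 + kcat·[A]/(K_actin + [A]) + N(0, noise_sd). Default kcat
    5.5 s⁻¹ matches wild-type full-length myosin VI; K_actin defaults to
    10 µM (within the physiological range for actin-activated myosins) since
    no fitted value is reported for these constructs.
    """

    actin_concs: tuple = (0.0, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0)
    V0: float = 0.04
    kcat: float = 5.5
    K_actin: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if any(c < 0 for c in self.actin_concs):
            raise ParameterError("actin concentrations must be >= 0")
        if self.kcat <= 0 or self.K_actin <= 0:
            raise ParameterError("kcat and K_actin must be > 0")
        if self.V0 < 0:
            raise ParameterError("V0 must be >= 0")


def atpase_rate(conc, V0: float, kcat: float, K_actin: float):
    """Michaelis–Menten rate law with a basal offset."""
    conc = np.asarray(conc, float)
    return V0 + kcat * conc / (K_actin + conc)


def simulate_atpase(spec: KineticsSimSpec) -> pd.DataFrame:
    """Simulate a titration; columns ``actin_uM, rate_per_s``."""
    spec.validate()
    rng = stream(spec.seed, "atpase")
    conc = np.asarray(spec.actin_concs, float)
    rate = atpase_rate(conc, spec.V0, spec.kcat, spec.K_actin)
    if spec.noise_sd > 0:
        rate = rate + rng.normal(0.0, spec.noise_sd, size=rate.shape)
    return pd.DataFrame({"actin_uM": conc, "rate_per_s": rate})
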