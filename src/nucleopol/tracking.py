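"""Single-particle-track MSD analysis and anomalous-diffusion fitting.

The time-averaged mean squared displacement of a track r(t) sampled at a
uniform frame interval is

    msd(τ_k) = ⟨ ‖r(t + τ_k) − r(t)‖² ⟩  over all overlapping pairs,

with pairs spanning missing frames excluded. The anomalous diffusion model
msd(τ) = 2·d·D·τ^α is fitted as a straight line in log-log space over the
short-lag portion of the curve (first 25% of available lags, clamped to
[3, 10] — the usual bias/variance compromise for time-averaged MSD): the
slope is α and the intercept log(2·d·D) gives D.

Tracks are classified by D alone: static D < 0.1 µm² s⁻¹, diffusive
0.1 ≤ D ≤ 5 (boundaries closed on the right), hypermobile D > 5
(excluded from mean-D summaries, reported but not quantified further).

A greedy nearest-neighbour frame-to-frame linker is provided for per-frame
detection tables, honouring a maximum displacement per link (default
400 nm = 0.4 µm) and a minimum track length (default 10 frames).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "MSDCurve",
    "MSDFit",
    "MobilitySummary",
    "AnomalousDiffusionMSD",
    "link_tracks",
    "compute_msd",
    "fit_anomalous",
    "summarize_mobility",
    "STATIC_D_THRESHOLD",
    "HYPERMOBILE_D_THRESHOLD",
]

STATIC_D_THRESHOLD = 0.1  # µm² s⁻¹
HYPERMOBILE_D_THRESHOLD = 5.0  # µm² s⁻¹


@dataclass
class MSDCurve:
    """Time-averaged MSD of one track."""

    lags: np.ndarray  # s
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray
    dims: int


@dataclass
class MSDFit:
    """Fitted anomalous-diffusion parameters of one track."""

    D: float  # µm² s⁻¹
    alpha: float
    dims: int
    fit_lags: int
    rss: float
    mobility_class: str
    ok: bool


@dataclass
class MobilitySummary:
    """Per-cell aggregate over track fits."""

    mean_D: float  # static + diffusive tracks only
    static_fraction: float
    mobile_fraction: float
    n_tracks: int


def _track_coords(track: pd.DataFrame):
    cols = [c for c in ("x_um", "y_um", "z_um") if c in track.columns]
    return track[cols].to_numpy(float), track["frame"].to_numpy(int), len(cols)


def compute_msd(track: pd.DataFrame, dt: float | None = None) -> MSDCurve:
    """Time-averaged MSD over all overlapping pairs of one track.

    *track* needs ``frame`` plus coordinate columns (``x_um, y_um[, z_um]``).
    The lag times come from ``t_s`` when present, else ``frame * dt``.
    Gaps (missing frames) simply contribute no pairs at the spanned lags.
    """
    xyz, frames, dims = _track_coords(track)
    if "t_s" in track.columns:
        t = track["t_s"].to_numpy(float)
        dt = (np.diff(t) / np.diff(frames)).mean() if len(frames) > 1 else (dt or 1.0)
    elif dt is None:
        raise ValueError("dt required when the track has no t_s column")
    max_lag = frames.max() - frames.min()
    msd = np.zeros(max_lag)
    n_pairs = np.zeros(max_lag, dtype=int)
    index = {f: i for i, f in enumerate(frames)}
    for k in range(1, max_lag + 1):
        sq = [
            float(((xyz[index[f + k]] - xyz[index[f]]) ** 2).sum())
            for f in frames
            if (f + k) in index
        ]
        if sq:
            msd[k - 1] = np.mean(sq)
            n_pairs[k - 1] = len(sq)
    lags = np.arange(1, max_lag + 1) * dt
    keep = n_pairs > 0
    return MSDCurve(lags=lags[keep], msd=msd[keep], n_pairs=n_pairs[keep], dims=dims)


def _n_fit_lags(n_lags: int, fit_fraction: float, lo: int = 3, hi: int = 10) -> int:
    return int(np.clip(round(fit_fraction * n_lags), lo, min(hi, n_lags)))


def fit_anomalous(
    curve: MSDCurve,
    dims: int | None = None,
    fit_lags: int | None = None,
    fit_fraction: float = 0.25,
    loc_error_offset: bool = False,
) -> MSDFit:
    """Fit the anomalous diffusion model to an MSD curve.

    Default: log-log linear fit of msd = 2·d·D·τ^α (deterministic, exact in
    the noiseless limit). With ``loc_error_offset`` the model gains a
    constant localisation-error term, msd = 2·d·D·τ^α + c (c ≥ 0), fitted
    by bounded nonlinear least squares seeded from the log-log solution —
    appropriate when static-error variance rivals the short-lag MSD.

    Returns D in µm² s⁻¹ and the anomalous exponent α; the mobility class
    is a pure function of D. An all-zero curve yields D = 0, α flagged
    undefined (nan) and class static; fewer than 3 positive lags flags a
    fit failure.
    """
    dims = dims or curve.dims
    pos = curve.msd > 0
    if not np.any(pos):
        return MSDFit(D=0.0, alpha=float("nan"), dims=dims, fit_lags=0,
                      rss=0.0, mobility_class="static", ok=True)
    lags = curve.lags[pos]
    msd = curve.msd[pos]
    n = fit_lags if fit_lags is not None else _n_fit_lags(len(lags), fit_fraction)
    if len(lags) < 3:
        return MSDFit(D=float("nan"), alpha=float("nan"), dims=dims, fit_lags=len(lags),
                      rss=float("nan"), mobility_class="unclassified", ok=False)
    n = min(n, len(lags))
    x = np.log(lags[:n])
    y = np.log(msd[:n])
    slope, intercept = np.polyfit(x, y, 1)
    rss = float(((y - (slope * x + intercept)) ** 2).sum())
    D = float(np.exp(intercept) / (2.0 * dims))
    if loc_error_offset:
        from scipy.optimize import curve_fit

        def model(tau, D_, alpha_, c_):
            return 2.0 * dims * D_ * tau**alpha_ + c_

        import warnings

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # singular covariance on exact data
                popt, _ = curve_fit(
                    model, lags[:n], msd[:n],
                    p0=[max(D, 1e-12), np.clip(slope, 0.05, 2.0), 0.0],
                    bounds=([0.0, 1e-3, 0.0], [np.inf, 3.0, np.inf]),
                    maxfev=10000,
                )
            D, slope = float(popt[0]), float(popt[1])
            rss = float(((msd[:n] - model(lags[:n], *popt)) ** 2).sum())
        except RuntimeError:
            return MSDFit(D=float("nan"), alpha=float("nan"), dims=dims,
                          fit_lags=n, rss=float("nan"),
                          mobility_class="unclassified", ok=False)
    return MSDFit(
        D=D,
        alpha=float(slope),
        dims=dims,
        fit_lags=n,
        rss=rss,
        mobility_class=classify_mobility(D),
        ok=True,
    )


def classify_mobility(D: float) -> str:
    """Mobility class from D alone (boundaries closed on the right)."""
    if D < STATIC_D_THRESHOLD:
        return "static"
    if D <= HYPERMOBILE_D_THRESHOLD:
        return "diffusive"
    return "hypermobile"


def summarize_mobility(fits, include_hypermobile: bool = False) -> MobilitySummary:
    """Aggregate track fits: static fraction and mean D.

    Hypermobile tracks count toward the fractions but are excluded from
    mean D by default (set ``include_hypermobile`` to average over them
    too).
    """
    ok = [f for f in fits if f.ok]
    if not ok:
        raise ValueError("no successful fits to summarise")
    classes = np.array([f.mobility_class for f in ok])
    n = len(ok)
    static = int((classes == "static").sum())
    keep = ("static", "diffusive", "hypermobile") if include_hypermobile else (
        "static", "diffusive")
    quant = [f.D for f in ok if f.mobility_class in keep]
    return MobilitySummary(
        mean_D=float(np.mean(quant)) if quant else float("nan"),
        static_fraction=static / n,
        mobile_fraction=1.0 - static / n,
        n_tracks=n,
    )


class AnomalousDiffusionMSD(BaseEstimator):
    """Per-track MSD + anomalous-diffusion fitting over a trajectory table.

    Parameters
    ----------
    fit_fraction : float
        Fraction of available lags used in the log-log fit (clamped to
        [3, 10] lags).
    min_frames : int
        Tracks shorter than this are skipped (default 10).
    dt : float or None
        Frame interval (s) when the table carries no ``t_s`` column.

    Attributes (after ``fit``)
    --------------------------
    fits_ : DataFrame — track_id, D, alpha, mobility_class, fit_lags, rss, ok
    curves_ : dict[int, MSDCurve]
    summary_ : MobilitySummary
    """

    def __init__(self, fit_fraction: float = 0.25, min_frames: int = 10,
                 dt: float | None = None):
        self.fit_fraction = fit_fraction
        self.min_frames = min_frames
        self.dt = dt

    def fit(self, X: pd.DataFrame, y=None):
        rows = []
        curves = {}
        fits = []
        for tid, track in X.groupby("track_id"):
            if len(track) < self.min_frames:
                continue
            curve = compute_msd(track, dt=self.dt)
            f = fit_anomalous(curve, fit_fraction=self.fit_fraction)
            curves[int(tid)] = curve
            fits.append(f)
            rows.append(
                {
                    "track_id": int(tid),
                    "D": f.D,
                    "alpha": f.alpha,
                    "mobility_class": f.mobility_class,
                    "fit_lags": f.fit_lags,
                    "rss": f.rss,
                    "ok": f.ok,
                }
            )
        self.fits_ = pd.DataFrame(
            rows,
            columns=["track_id", "D", "alpha", "mobility_class", "fit_lags", "rss", "ok"],
        )
        self.curves_ = curves
        self.summary_ = summarize_mobility(fits) if fits else None
        return self


def link_tracks(
    detections: pd.DataFrame, max_disp: float = 0.4, min_frames: int = 10,
    dt: float = 0.032,
) -> pd.DataFrame:
    """Greedy nearest-neighbour frame-to-frame linking of detections.

    *detections* has ``frame`` plus coordinate columns (µm). Candidate
    links between consecutive frames are taken shortest-first; no link may
    exceed ``max_disp`` (µm). Unmatched detections seed new tracks; tracks
    shorter than ``min_frames`` are discarded.
    """
    cols = [c for c in ("x_um", "y_um", "z_um") if c in detections.columns]
    frames = sorted(detections["frame"].unique())
    next_track = 0
    active: dict[int, np.ndarray] = {}  # track_id -> last position
    assignments = []  # (orig index, track_id)

    by_frame = {f: detections[detections["frame"] == f] for f in frames}
    prev_frame = None
    for f in frames:
        det = by_frame[f]
        pos = det[cols].to_numpy(float)
        idx = det.index.to_numpy()
        if prev_frame is not None and f == prev_frame + 1 and active:
            track_ids = list(active)
            last = np.array([active[t] for t in track_ids])
            dmat = np.linalg.norm(last[:, None, :] - pos[None, :, :], axis=2)
            cand = [
                (dmat[a, b], a, b)
                for a in range(len(track_ids))
                for b in range(len(pos))
                if dmat[a, b] <= max_disp
            ]
            cand.sort()
            used_t, used_d = set(), set()
            new_active = {}
            for dist, a, b in cand:
                if a in used_t or b in used_d:
                    continue
                used_t.add(a)
                used_d.add(b)
                tid = track_ids[a]
                new_active[tid] = pos[b]
                assignments.append((idx[b], tid))
            for b in range(len(pos)):
                if b not in used_d:
                    new_active[next_track] = pos[b]
                    assignments.append((idx[b], next_track))
                    next_track += 1
            active = new_active
        else:
            active = {}
            for b in range(len(pos)):
                active[next_track] = pos[b]
                assignments.append((idx[b], next_track))
                next_track += 1
        prev_frame = f

    tid_map = pd.Series(dict(assignments))
    out = detections.copy()
    out["track_id"] = tid_map.reindex(detections.index).astype(int)
    sizes = out.groupby("track_id")["frame"].size()
    keep = sizes.index[sizes >= min_frames]
    out = out[out["track_id"].isin(keep)].copy()
    if "t_s" not in out.columns:
        out["t_s"] = out["frame"] * dt
    order = ["track_id", "frame", "t_s"] + cols
    return out[order].sort_values(["track_id", "frame"]).reset_index(drop=True)
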