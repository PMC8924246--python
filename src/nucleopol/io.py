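"""Reading, validation and ROI filtering of localisation and trajectory tables.

Single-molecule localisation microscopy (SMLM) software exports per-molecule
coordinate lists as delimited text. This module maps vendor exports onto one
canonical in-memory schema (a pandas DataFrame) and applies the validation
rules the downstream spatial statistics assume:

``LocalizationTable`` columns
    ``x_nm, y_nm`` : 2D position in nanometres
    ``frame``      : acquisition frame index
    ``precision_nm``: fitted localisation precision (> 0)
    ``channel``    : dye / target label (non-empty string)

``TrajectoryTable`` columns
    ``track_id, frame, t_s, x_um, y_um`` and optionally ``z_um``

Coordinates are continuous positions; rendered-pixel indexing never appears.
Region-of-interest filtering treats polygon boundary points as inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "LOC_COLUMNS",
    "TRAJ_COLUMNS",
    "ROI",
    "ReadReport",
    "read_localizations",
    "write_localizations",
    "clip_to_roi",
    "read_trajectories",
    "write_trajectories",
    "rectangle_roi",
    "LOC_DIALECTS",
    "TRAJ_DIALECTS",
]

LOC_COLUMNS = ["x_nm", "y_nm", "frame", "precision_nm", "channel"]
TRAJ_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um", "z_um"]

#: Column-mapping dialects: canonical name -> vendor column name.
LOC_DIALECTS: dict[str, dict[str, str]] = {
    "canonical": {c: c for c in LOC_COLUMNS},
    # ThunderSTORM default CSV export (nm units).
    "thunderstorm": {
        "x_nm": "x [nm]",
        "y_nm": "y [nm]",
        "frame": "frame",
        "precision_nm": "uncertainty [nm]",
        "channel": "channel",
    },
    # Zeiss Zen localisation-table export.
    "zeiss": {
        "x_nm": "Position X [nm]",
        "y_nm": "Position Y [nm]",
        "frame": "First Frame",
        "precision_nm": "Precision [nm]",
        "channel": "Channel",
    },
}

TRAJ_DIALECTS: dict[str, dict[str, str]] = {
    "canonical": {c: c for c in TRAJ_COLUMNS},
    # MOSAIC particle-tracker style export (µm units).
    "mosaic": {
        "track_id": "Trajectory",
        "frame": "Frame",
        "x_um": "x",
        "y_um": "y",
        "z_um": "z",
    },
}


class FormatError(ValueError):
    """A required column is missing or a structural rule is violated."""


class EmptyInputError(ValueError):
    """No valid rows survive validation."""


class GeometryError(ValueError):
    """Degenerate or invalid ROI geometry."""


@dataclass(frozen=True)
class ROI:
    """Simple polygonal region of interest, vertices in nm.

    Boundary points count as inside (deterministic convention used by
    :func:`clip_to_roi` and all spatial statistics).
    """

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise GeometryError("ROI polygon needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError("ROI polygon is degenerate or self-intersecting")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        """Polygon area in nm²."""
        return float(self.polygon.area)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) in nm."""
        return self.polygon.bounds

    def is_rectangle(self, tol: float = 1e-9) -> bool:
        """True when the polygon is an axis-aligned rectangle."""
        minx, miny, maxx, maxy = self.bounds
        rect = Polygon(
            [(minx, miny), (maxx, miny), (maxx, maxy), (minx, maxy)]
        )
        return abs(self.polygon.symmetric_difference(rect).area) <= tol * rect.area

    def contains_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised point-in-polygon test, boundary inclusive."""
        import shapely

        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        poly = self.polygon
        return shapely.covers(poly, pts)


def rectangle_roi(width_nm: float, height_nm: float, origin=(0.0, 0.0)) -> ROI:
    """Axis-aligned rectangular ROI with lower-left corner at *origin*."""
    x0, y0 = origin
    return ROI(
        (
            (x0, y0),
            (x0 + width_nm, y0),
            (x0 + width_nm, y0 + height_nm),
            (x0, y0 + height_nm),
        )
    )


@dataclass
class ReadReport:
    """Bookkeeping for a read: kept + dropped = rows seen."""

    n_input: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    reasons: dict = field(default_factory=dict)


def _resolve_dialect(dialect, table: dict) -> dict[str, str]:
    if dialect is None:
        return table["canonical"]
    if isinstance(dialect, str):
        try:
            return table[dialect]
        except KeyError:
            raise FormatError(f"unknown dialect {dialect!r}") from None
    return dict(dialect)


def read_localizations(path, dialect=None, channel: str | None = None):
    """Read a delimited localisation table onto the canonical schema.

    Parameters
    ----------
    path : str or file-like
        CSV file with a header row.
    dialect : str or mapping, optional
        Name of a built-in dialect (``canonical``, ``thunderstorm``,
        ``zeiss``) or an explicit mapping canonical-name -> column-name.
    channel : str, optional
        Channel label to assign when the file has no channel column.

    Returns
    -------
    (DataFrame, ReadReport)
        Validated table (invalid rows dropped and counted) and the report.

    Raises
    ------
    FormatError
        If a required column is absent.
    EmptyInputError
        If no valid rows remain.
    """
    mapping = _resolve_dialect(dialect, LOC_DIALECTS)
    raw = pd.read_csv(path)
    out = {}
    for canon in LOC_COLUMNS:
        src = mapping.get(canon, canon)
        if src in raw.columns:
            out[canon] = raw[src]
        elif canon == "channel" and channel is not None:
            out[canon] = channel
        else:
            raise FormatError(f"missing required column {src!r} (for {canon})")
    df = pd.DataFrame(out)

    report = ReadReport(n_input=len(df))
    num = df[["x_nm", "y_nm", "precision_nm"]].apply(pd.to_numeric, errors="coerce")
    finite = np.isfinite(num).all(axis=1)
    pos_prec = num["precision_nm"] > 0
    chan_ok = df["channel"].astype(str).str.len() > 0
    valid = finite & pos_prec & chan_ok
    report.reasons = {
        "non_finite": int((~finite).sum()),
        "non_positive_precision": int((finite & ~pos_prec).sum()),
        "empty_channel": int((finite & pos_prec & ~chan_ok).sum()),
    }
    df = df.loc[valid].reset_index(drop=True)
    df["x_nm"] = df["x_nm"].astype(float)
    df["y_nm"] = df["y_nm"].astype(float)
    df["frame"] = df["frame"].astype(int)
    df["precision_nm"] = df["precision_nm"].astype(float)
    df["channel"] = df["channel"].astype(str)
    report.n_kept = len(df)
    report.n_dropped = report.n_input - report.n_kept
    if report.n_kept == 0:
        raise EmptyInputError("no valid localisations in input")
    return df, report


def write_localizations(df: pd.DataFrame, path) -> None:
    """Write the canonical localisation CSV (round-trips bit-identically)."""
    df.to_csv(path, index=False, columns=LOC_COLUMNS)


def clip_to_roi(df: pd.DataFrame, roi: ROI) -> pd.DataFrame:
    """Retain rows whose (x, y) lies inside the ROI (boundary inclusive).

    Idempotent: clipping twice equals clipping once.
    """
    inside = roi.contains_points(df["x_nm"].to_numpy(), df["y_nm"].to_numpy())
    return df.loc[inside].reset_index(drop=True)


def read_trajectories(path, dialect=None, min_frames: int = 10, dt: float = 0.032):
    """Read a delimited 2D/3D trajectory table.

    Tracks shorter than *min_frames* are excluded (count reported). When the
    file lacks an absolute-time column, ``t_s = frame * dt`` (default frame
    interval 32 ms). Within a track, frames must be strictly increasing.

    Returns
    -------
    (DataFrame, ReadReport)
    """
    mapping = _resolve_dialect(dialect, TRAJ_DIALECTS)
    raw = pd.read_csv(path)
    out = {}
    for canon in ["track_id", "frame", "x_um", "y_um"]:
        src = mapping.get(canon, canon)
        if src not in raw.columns:
            raise FormatError(f"missing required column {src!r} (for {canon})")
        out[canon] = raw[src]
    z_src = mapping.get("z_um", "z_um")
    if z_src in raw.columns:
        out["z_um"] = raw[z_src]
    t_src = mapping.get("t_s", "t_s")
    if t_src in raw.columns:
        out["t_s"] = raw[t_src]
    df = pd.DataFrame(out)
    df["track_id"] = df["track_id"].astype(int)
    df["frame"] = df["frame"].astype(int)
    if "t_s" not in df.columns:
        df["t_s"] = df["frame"] * float(dt)

    for tid, grp in df.groupby("track_id"):
        if not np.all(np.diff(grp["frame"].to_numpy()) > 0):
            raise FormatError(f"non-monotonic frames in track {tid}")

    sizes = df.groupby("track_id")["frame"].size()
    keep_ids = sizes.index[sizes >= min_frames]
    report = ReadReport(n_input=int(sizes.size))
    report.n_kept = int(keep_ids.size)
    report.n_dropped = report.n_input - report.n_kept
    report.reasons = {"short_track": report.n_dropped}
    cols = [c for c in TRAJ_COLUMNS if c in df.columns]
    df = df[df["track_id"].isin(keep_ids)][cols].reset_index(drop=True)
    return df, report


def write_trajectories(df: pd.DataFrame, path) -> None:
    cols = [c for c in TRAJ_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)
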