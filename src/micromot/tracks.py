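"""Migration-track metrics for scrape-wound assays.

Cell positions are tracked at the edge of a scrape wound over several hours
(typically 6 h).  From each timestamped 2D track the module computes

* path length (sum of successive step lengths, um),
* net displacement (start-to-end distance, um),
* signed displacement into the wound (component of the net displacement along
  the wound normal, um; negative when the cell retreats),
* speed (path length / elapsed time, um/min),
* migration angle (degrees in [0, 180] between the net displacement and the
  wound edge, with 90 = perpendicular to the edge), and
* directional persistence (net displacement / path length, 1 = perfectly
  straight path).

All metrics are invariant under rigid motions applied jointly to the track
and the wound frame; path length (and hence speed and persistence) depends on
the sampling interval, which should be reported alongside the metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import TrackError

METRIC_NAMES = (
    "path_length_um",
    "net_displacement_um",
    "displacement_into_wound_um",
    "speed_um_per_min",
    "angle_deg",
    "persistence",
)


@dataclass(frozen=True)
class WoundFrame:
    """Wound-edge reference frame: a point on the edge and the into-wound normal."""

    edge_point: tuple[float, float]
    wound_normal: tuple[float, float]

    def __post_init__(self) -> None:
        n = np.asarray(self.wound_normal, dtype=float)
        norm = float(np.linalg.norm(n))
        if norm == 0:
            raise TrackError("wound_normal must be a non-zero vector")
        object.__setattr__(self, "wound_normal", (float(n[0] / norm), float(n[1] / norm)))
        object.__setattr__(self, "edge_point", (float(self.edge_point[0]), float(self.edge_point[1])))

    @property
    def edge_direction(self) -> tuple[float, float]:
        """Unit vector along the wound edge (normal rotated by +90 degrees)."""
        nx, ny = self.wound_normal
        return (-ny, nx)


@dataclass
class CellTrack:
    """A timestamped 2D position series for one cell."""

    cell_id: str
    times_min: np.ndarray
    positions_um: np.ndarray
    condition: str | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.times_min.ndim != 1 or self.times_min.size < 2:
            raise TrackError("a track needs at least 2 time samples")
        if self.positions_um.shape != (self.times_min.size, 2):
            raise TrackError(
                f"positions shape {self.positions_um.shape} does not match "
                f"{self.times_min.size} time samples"
            )
        if not np.all(np.diff(self.times_min) > 0):
            raise TrackError("times must be strictly increasing")


@dataclass
class TrackMetrics:
    cell_id: str
    condition: str | None
    path_length_um: float
    net_displacement_um: float
    displacement_into_wound_um: float
    speed_um_per_min: float
    angle_deg: float
    persistence: float


def compute_track_metrics(track: CellTrack, frame: WoundFrame) -> TrackMetrics:
    """Compute the 2D migration metrics of one track in a wound frame.

    Persistence is clipped to [0, 1] against floating-point round-off and is
    NaN for a stationary track; the angle is NaN when the net displacement is
    zero (a closed loop has no direction).
    """
    steps = np.diff(track.positions_um, axis=0)
    path = float(np.linalg.norm(steps, axis=1).sum())
    d = track.positions_um[-1] - track.positions_um[0]
    net = float(np.linalg.norm(d))
    n = np.asarray(frame.wound_normal)
    e = np.asarray(frame.edge_direction)
    into_wound = float(d @ n)
    elapsed = float(track.times_min[-1] - track.times_min[0])
    speed = path / elapsed
    if net > 0:
        angle = float(np.degrees(np.arccos(np.clip((d @ e) / net, -1.0, 1.0))))
    else:
        angle = math.nan
    persistence = min(net / path, 1.0) if path > 0 else math.nan
    return TrackMetrics(
        cell_id=track.cell_id,
        condition=track.condition,
        path_length_um=path,
        net_displacement_um=net,
        displacement_into_wound_um=into_wound,
        speed_um_per_min=speed,
        angle_deg=angle,
        persistence=persistence,
    )


def step_angles_deg(track: CellTrack, frame: WoundFrame) -> np.ndarray:
    """Per-step variant of the migration angle (degrees in [0, 180]).

    Zero-length steps yield NaN and should be excluded before averaging.
    """
    steps = np.diff(track.positions_um, axis=0)
    norms = np.linalg.norm(steps, axis=1)
    e = np.asarray(frame.edge_direction)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(norms > 0, (steps @ e) / norms, np.nan)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def summarize_group(metrics: list[TrackMetrics], condition: str | None = None) -> pd.DataFrame:
    """Mean, standard deviation (NaN when n < 2) and n for each metric.

    Rows follow the fixed metric order of :data:`METRIC_NAMES`; NaN metric
    values (undefined angles/persistences) are excluded per metric, with n
    reporting the values actually averaged.
    """
    if not metrics:
        raise TrackError("summarize_group requires at least one track")
    if condition is None:
        conds = {m.condition for m in metrics}
        condition = conds.pop() if len(conds) == 1 else None
    rows = []
    for name in METRIC_NAMES:
        values = np.asarray([getattr(m, name) for m in metrics], dtype=float)
        values = values[~np.isnan(values)]
        rows.append(
            {
                "condition": condition,
                "metric": name,
                "mean": float(values.mean()) if values.size else math.nan,
                "sd": float(values.std(ddof=1)) if values.size > 1 else math.nan,
                "n": int(values.size),
            }
        )
    return pd.DataFrame(rows)


def tracks_from_table(df: pd.DataFrame) -> list[CellTrack]:
    """Build tracks from a long table (cell_id, t_min, x_um, y_um[, condition])."""
    required = {"cell_id", "t_min", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise TrackError(f"track table is missing columns: {sorted(missing)}")
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("t_min")
        condition = grp["condition"].iloc[0] if "condition" in grp.columns else None
        out.append(
            CellTrack(
                cell_id=str(cell_id),
                times_min=grp["t_min"].to_numpy(),
                positions_um=grp[["x_um", "y_um"]].to_numpy(),
                condition=condition,
            )
        )
    return out


def tracks_to_table(tracks: list[CellTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for t, (x, y) in zip(tr.times_min, tr.positions_um):
            rows.append(
                {"cell_id": tr.cell_id, "t_min": t, "x_um": x, "y_um": y, "condition": tr.condition}
            )
    return pd.DataFrame(rows)
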