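"""Inverted-Transwell Matrigel invasion scoring from nuclei z-stacks.

Cells seeded under a porous insert migrate upward into an overlying Matrigel
plug; confocal z-stacks of the nuclear stain are acquired from the insert
surface up through the gel at a fixed z-interval (4 um).  A cell is scored
*invasive* when its nucleus lies strictly more than 8 um into the gel and
*deep* beyond 24 um (roughly half-way through a 0-60 um stack).  Percentages
are pooled over at least five fields of view (FOV) per insert; 500-1000
nuclei per condition is the typical counting scale.

Nuclei are 3D connected components (26-connectivity) of the thresholded
stack; the depth of a nucleus is the z-plane nearest its 3D centroid times
the z-interval (per-plane counting, no sub-plane interpolation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import GeometryError, SegmentationError, UndefinedStatisticError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ZStackSpec:
    """Acquisition geometry of a nuclei z-stack."""

    z_interval_um: float = 4.0
    n_planes: int = 16
    plane0_depth_um: float = 0.0  # Transwell surface
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        if not (self.z_interval_um > 0):
            raise GeometryError(f"z_interval_um must be > 0, got {self.z_interval_um}")
        if self.n_planes < 2:
            raise GeometryError(f"n_planes must be >= 2, got {self.n_planes}")

    @property
    def max_depth_um(self) -> float:
        return self.plane0_depth_um + (self.n_planes - 1) * self.z_interval_um

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_size_um**2 * self.z_interval_um


@dataclass
class NucleusRecord:
    """One detected nucleus with its quantized depth into the gel."""

    nucleus_id: int
    centroid_xy: tuple[float, float]  # (row, col) px within the FOV
    depth_um: float
    fov_id: str | None = None


@dataclass
class InvasionScore:
    """Invasive/deep counts and percentages for one condition or FOV set."""

    condition: str | None
    n_total: int
    n_invasive: int
    n_deep: int
    pct_invasive: float
    pct_deep: float
    per_fov: pd.DataFrame = field(default_factory=pd.DataFrame)


def detect_nuclei(
    stack: np.ndarray,
    spec: ZStackSpec,
    min_volume_um3: float = 20.0,
    method: str = "otsu",
    manual_value: float | None = None,
    fov_id: str | None = None,
) -> list[NucleusRecord]:
    """Detect nuclei as 3D components of a thresholded (z, y, x) stack.

    Components with volume strictly greater than ``min_volume_um3`` yield one
    record each; depth is the z-plane nearest the 3D centroid times the
    z-interval.  A constant stack raises :class:`SegmentationError`.
    """
    arr = np.asarray(stack)
    if arr.ndim != 3:
        raise SegmentationError(f"expected a 3D (z, y, x) stack, got shape {arr.shape}")
    if arr.shape[0] != spec.n_planes:
        raise GeometryError(
            f"stack has {arr.shape[0]} planes but spec declares {spec.n_planes}"
        )
    if float(arr.min()) == float(arr.max()):
        raise SegmentationError("constant stack: threshold is degenerate")
    if method == "otsu":
        thr = float(threshold_otsu(arr))
    elif method == "manual":
        if manual_value is None:
            raise SegmentationError("manual thresholding requires manual_value")
        thr = float(manual_value)
    else:
        raise SegmentationError(f"unknown threshold method {method!r}")
    mask = arr > thr
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return []
    # a structure-free stack makes the global threshold bisect the noise;
    # require candidate peaks to clear the robust noise floor
    background = float(np.median(arr[~mask])) if not mask.all() else float(arr.min())
    sigma = 1.4826 * float(np.median(np.abs(arr - np.median(arr))))
    min_peak = background + 6.0 * sigma
    idx = np.arange(1, n + 1)
    volumes = ndimage.sum_labels(np.ones_like(labels, dtype=np.int32), labels, idx)
    volumes = volumes * spec.voxel_volume_um3
    peaks = ndimage.maximum(arr, labels, idx)
    centroids = ndimage.center_of_mass(mask, labels, idx)
    records: list[NucleusRecord] = []
    nucleus_id = 0
    for vol, peak, (cz, cy, cx) in zip(volumes, peaks, centroids):
        if not (vol > min_volume_um3) or peak < min_peak:
            continue
        plane = int(np.clip(np.round(cz), 0, spec.n_planes - 1))
        records.append(
            NucleusRecord(
                nucleus_id=nucleus_id,
                centroid_xy=(float(cy), float(cx)),
                depth_um=float(spec.plane0_depth_um + plane * spec.z_interval_um),
                fov_id=fov_id,
            )
        )
        nucleus_id += 1
    return records


def score_invasion(
    records: list[NucleusRecord],
    invasive_threshold_um: float = 8.0,
    deep_threshold_um: float = 24.0,
    condition: str | None = None,
) -> InvasionScore:
    """Score nuclei against the strict invasion depth thresholds.

    A nucleus is invasive when its depth is strictly greater than
    ``invasive_threshold_um`` (default 8 um) and deep beyond
    ``deep_threshold_um`` (default 24 um).  Percentages are relative to the
    total nucleus count; scoring zero nuclei is undefined and raises.
    """
    if not records:
        raise UndefinedStatisticError("cannot score invasion of zero nuclei")
    depths = np.asarray([r.depth_um for r in records], dtype=float)
    fovs = [r.fov_id for r in records]
    n_total = len(records)
    invasive = depths > invasive_threshold_um
    deep = depths > deep_threshold_um
    per_fov = (
        pd.DataFrame({"fov_id": fovs, "invasive": invasive, "deep": deep})
        .groupby("fov_id", dropna=False)
        .agg(n_total=("invasive", "size"), n_invasive=("invasive", "sum"), n_deep=("deep", "sum"))
        .reset_index()
    )
    return InvasionScore(
        condition=condition,
        n_total=n_total,
        n_invasive=int(invasive.sum()),
        n_deep=int(deep.sum()),
        pct_invasive=100.0 * float(invasive.sum()) / n_total,
        pct_deep=100.0 * float(deep.sum()) / n_total,
        per_fov=per_fov,
    )


def aggregate_fovs(scores: list[InvasionScore], min_fovs: int = 5) -> InvasionScore:
    """Pool per-FOV scores into one count-weighted score.

    The pooled percentage equals the count-weighted mean of FOV percentages.
    Fewer than ``min_fovs`` FOVs logs a warning (the assay convention is at
    least five per insert) but still pools.
    """
    if not scores:
        raise UndefinedStatisticError("cannot aggregate zero FOVs")
    if len(scores) < min_fovs:
        log.warning("aggregating %d FOVs, fewer than the recommended %d", len(scores), min_fovs)
    conds = {s.condition for s in scores}
    condition = conds.pop() if len(conds) == 1 else None
    n_total = sum(s.n_total for s in scores)
    n_invasive = sum(s.n_invasive for s in scores)
    n_deep = sum(s.n_deep for s in scores)
    per_fov = pd.concat([s.per_fov for s in scores], ignore_index=True)
    return InvasionScore(
        condition=condition,
        n_total=n_total,
        n_invasive=n_invasive,
        n_deep=n_deep,
        pct_invasive=100.0 * n_invasive / n_total,
        pct_deep=100.0 * n_deep / n_total,
        per_fov=per_fov,
    )
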