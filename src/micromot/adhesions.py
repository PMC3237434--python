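"""Focal-adhesion detection, regional assignment, and morphometry.

Focal adhesions (FAs) are punctate-to-elongated plaques imaged with an
adhesion marker (vinculin/paxillin).  In square-constrained cells FAs
concentrate at the corners; the quantities of interest are FA counts and
lengths in corner versus side interior zones of equal area and equal island
edge contact (see :func:`micromot.geometry.interior_region_masks`).

FA length is the major-axis length of the best-fit second-moment ellipse, the
standard morphometric surrogate when no explicit length definition is given.
Region membership is decided by the zone containing the FA centroid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import SegmentationError
from .geometry import CORNER, SIDE, RegionPartition, interior_region_masks

log = logging.getLogger(__name__)


@dataclass
class AdhesionRecord:
    """One detected focal adhesion."""

    component_id: int
    centroid: tuple[float, float]  # (row, col) px
    length_um: float  # second-moment major-axis length
    area_um2: float
    region: str | None = None  # "corner" | "side" | None before assignment
    cell_id: str | None = None


@dataclass
class AdhesionSummary:
    """Per-cell FA counts and mean lengths by region (NaN when a region is empty)."""

    cell_id: str | None
    n_corner: int
    n_side: int
    mean_length_corner_um: float
    mean_length_side_um: float


def detect_adhesions(
    image: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 0.25,
    method: str = "otsu",
    manual_value: float | None = None,
    peak_fraction: float | None = 0.4,
    smooth_sigma_px: float = 1.0,
    cell_id: str | None = None,
) -> list[AdhesionRecord]:
    """Detect FAs in a single-channel adhesion-marker image.

    The image is denoised with a small Gaussian (``smooth_sigma_px``), then a
    first global threshold (``otsu`` or ``manual``) proposes candidate
    components.  When ``peak_fraction`` is set (default 0.4) each candidate
    is re-thresholded at that fraction of its peak amplitude over the image
    background, a fixed-fraction-of-peak outline in the spirit of the
    full-width-half-maximum convention.  This separates bright plaques from
    diffuse cytoplasmic signal, and the 0.4 fraction makes the second-moment
    length of a diffraction-blurred elongated adhesion unbiased under the
    imaging model documented in the methods note (0.8 um plaque width,
    ~0.3 um PSF); set ``peak_fraction=None`` for plain global thresholding.

    Components (8-connectivity) with area strictly greater than
    ``min_area_um2`` (default 0.25 um^2, sub-resolution speckle rejection)
    are returned with centroid, area, and length (major axis of the
    second-moment ellipse).  Regions are unset; see
    :func:`assign_adhesion_regions`.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise SegmentationError(f"expected a single-channel 2D image, got shape {img.shape}")
    if float(img.min()) == float(img.max()):
        raise SegmentationError("constant image: threshold is degenerate")
    if smooth_sigma_px > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma_px)
    if method == "otsu":
        thr = float(threshold_otsu(img))
    elif method == "manual":
        if manual_value is None:
            raise SegmentationError("manual thresholding requires manual_value")
        thr = float(manual_value)
    else:
        raise SegmentationError(f"unknown threshold method {method!r}")
    mask = img > thr
    if peak_fraction is not None and mask.any() and not mask.all():
        background = float(np.median(img[~mask]))
        # robust noise scale; candidate peaks must clear it, otherwise a
        # structure-free frame would be shattered into noise detections
        sigma = 1.4826 * float(np.median(np.abs(img - np.median(img))))
        min_peak = background + 6.0 * sigma
        labels0 = cc_label(mask, connectivity=2)
        refined = np.zeros_like(mask)
        for prop in regionprops(labels0, intensity_image=img):
            peak = float(prop.intensity_max)
            if peak < min_peak:
                continue
            local_thr = max(thr, background + peak_fraction * (peak - background))
            sl = prop.slice
            comp = labels0[sl] == prop.label
            refined[sl] |= comp & (img[sl] > local_thr)
        mask = refined
    labels = cc_label(mask, connectivity=2)
    px2 = pixel_size_um**2
    records: list[AdhesionRecord] = []
    for prop in regionprops(labels):
        area = prop.area * px2
        if not (area > min_area_um2):
            continue
        records.append(
            AdhesionRecord(
                component_id=int(prop.label),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                length_um=float(prop.axis_major_length * pixel_size_um),
                area_um2=float(area),
                cell_id=cell_id,
            )
        )
    return records


def assign_adhesion_regions(
    records: list[AdhesionRecord],
    partition: RegionPartition,
    band_depth_um: float | None = None,
) -> list[AdhesionRecord]:
    """Label each FA by the interior zone containing its centroid.

    ``band_depth_um`` defaults to L/4, i.e. corner zones equal to the four
    corner cells of the 4x4 grid.  Records whose centroid falls outside both
    zones are dropped (count logged), so
    ``n_corner + n_side + n_dropped == n_detected``.
    """
    if band_depth_um is None:
        band_depth_um = partition.island.side_length_um / 4.0
    zones = interior_region_masks(partition, band_depth_um)
    out: list[AdhesionRecord] = []
    n_dropped = 0
    for rec in records:
        r = int(round(rec.centroid[0]))
        c = int(round(rec.centroid[1]))
        if 0 <= r < zones.shape[0] and 0 <= c < zones.shape[1]:
            z = int(zones[r, c])
        else:
            z = 0
        if z == CORNER:
            out.append(replace(rec, region="corner"))
        elif z == SIDE:
            out.append(replace(rec, region="side"))
        else:
            n_dropped += 1
    if n_dropped:
        log.info("assign_adhesion_regions: dropped %d records outside both zones", n_dropped)
    return out


def summarize_adhesions(records: list[AdhesionRecord], cell_id: str | None = None) -> AdhesionSummary:
    """Counts and mean lengths by region; empty regions flag NaN means."""
    corner = [r.length_um for r in records if r.region == "corner"]
    side = [r.length_um for r in records if r.region == "side"]
    return AdhesionSummary(
        cell_id=cell_id,
        n_corner=len(corner),
        n_side=len(side),
        mean_length_corner_um=float(np.mean(corner)) if corner else math.nan,
        mean_length_side_um=float(np.mean(side)) if side else math.nan,
    )
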