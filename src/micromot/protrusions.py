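"""Membrane-extension and circular-dorsal-ruffle quantification.

PDGF-stimulated fibroblasts on square adhesive islands extend actin-rich
lateral protrusions (lamellipodia) from the cell periphery and can form
circular dorsal ruffles (CDRs), transient ring-shaped actin structures on the
apical surface.  This module segments the actin channel, extracts
boundary-emanating extensions classified as corner or side by their dominant
island-boundary contact, detects CDRs as interior annular structures, and
summarizes per-cell and per-timepoint region areas.

Operational definitions (config-exposed):

* an extension is a connected component of the thresholded actin mask outside
  the island footprint that contacts the island boundary and has projected
  area strictly greater than ``min_area_um2`` (default 1 um^2);
* its region is the class (corner/side) with the greater boundary contact
  length, ties resolving to corner;
* a CDR is a bright component lying wholly inside the footprint eroded by
  ``erosion_um`` whose annularity (hole area / filled area) exceeds
  ``min_annularity``; its area is the ring-filled area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import GeometryError, IntegrityError, SegmentationError
from .geometry import CORNER, SIDE, RegionPartition

THRESHOLD_METHODS = ("otsu", "percentile", "manual")


@dataclass
class SegmentationResult:
    """Thresholded actin channel: cell mask and extension candidates."""

    cell_mask: np.ndarray
    extension_candidate_mask: np.ndarray
    threshold_value: float
    method: str


@dataclass
class ExtensionRecord:
    """One detected lateral membrane extension."""

    component_id: int
    area_um2: float
    emanation_point: tuple[float, float]  # (row, col) px on the boundary band
    region: str  # "corner" | "side"
    timepoint_min: float | None = None
    cell_id: str | None = None


@dataclass
class CDRRecord:
    """One detected circular dorsal ruffle (interior annular component)."""

    component_id: int
    area_um2: float  # ring-filled area
    annularity: float  # hole area / filled area
    centroid: tuple[float, float]  # (row, col) px
    timepoint_min: float | None = None
    cell_id: str | None = None


@dataclass
class ExtensionSummary:
    """Per-cell, per-timepoint extension/CDR areas and counts."""

    cell_id: str | None
    timepoint_min: float | None
    corner_area_um2: float
    side_area_um2: float
    cdr_area_um2: float
    corner_fraction: float  # NaN when corner+side == 0
    n_extensions: int
    n_cdrs: int


def segment_actin(
    image: np.ndarray,
    method: str = "otsu",
    manual_value: float | None = None,
    percentile: float = 99.0,
) -> SegmentationResult:
    """Threshold a single-channel actin image into bright-structure masks.

    ``method`` is one of ``otsu`` (default), ``percentile`` (bright tail at
    the given percentile) or ``manual`` (``manual_value`` required).  A
    constant image has no meaningful threshold and raises
    :class:`SegmentationError`.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise SegmentationError(f"expected a single-channel 2D image, got shape {img.shape}")
    if method not in THRESHOLD_METHODS:
        raise SegmentationError(f"unknown threshold method {method!r}; use one of {THRESHOLD_METHODS}")
    lo, hi = float(img.min()), float(img.max())
    if lo == hi:
        raise SegmentationError("constant image: threshold is degenerate")
    if method == "otsu":
        thr = float(threshold_otsu(img))
    elif method == "percentile":
        thr = float(np.percentile(img, percentile))
    else:
        if manual_value is None:
            raise SegmentationError("manual thresholding requires manual_value")
        thr = float(manual_value)
    mask = img > thr
    cell_mask = ndimage.binary_fill_holes(mask)
    return SegmentationResult(
        cell_mask=cell_mask,
        extension_candidate_mask=mask,
        threshold_value=thr,
        method=method,
    )


def _check_shapes(seg: SegmentationResult, partition: RegionPartition) -> None:
    if seg.extension_candidate_mask.shape != partition.frame_shape:
        raise GeometryError(
            f"segmentation shape {seg.extension_candidate_mask.shape} does not match "
            f"partition frame {partition.frame_shape}"
        )


def _contact_zones(partition: RegionPartition):
    """Boundary bands dilated by one pixel, cached on the partition."""
    cache = partition.__dict__.setdefault("_cache", {})
    if "contact_zones" not in cache:
        struct = np.ones((3, 3), dtype=bool)
        cache["contact_zones"] = (
            ndimage.binary_dilation(partition.corner_mask, structure=struct),
            ndimage.binary_dilation(partition.side_mask, structure=struct),
        )
    return cache["contact_zones"]


def extract_extensions(
    seg: SegmentationResult,
    partition: RegionPartition,
    min_area_um2: float = 1.0,
    cell_id: str | None = None,
    timepoint_min: float | None = None,
) -> list[ExtensionRecord]:
    """Extract boundary-emanating extensions from a segmented actin image.

    Connected components (8-connectivity) of the candidate mask outside the
    island footprint are kept when they contact the island boundary band and
    their projected area is strictly greater than ``min_area_um2``.  The
    region label is decided by majority boundary-contact length, ties to
    corner; the emanation point is the centroid of the contacted boundary
    pixels.
    """
    _check_shapes(seg, partition)
    px2 = partition.island.pixel_size_um**2
    footprint = partition.footprint_mask()
    exterior = seg.extension_candidate_mask & ~footprint
    labels = cc_label(exterior, connectivity=2)
    n = int(labels.max())
    if n == 0:
        return []
    # boundary band dilated by one pixel so exterior components adjacent to
    # the boundary register contact
    corner_contact_zone, side_contact_zone = _contact_zones(partition)
    areas_px = np.bincount(labels.ravel(), minlength=n + 1)
    corner_contact = np.bincount(labels[corner_contact_zone], minlength=n + 1)
    side_contact = np.bincount(labels[side_contact_zone], minlength=n + 1)
    # emanation point = centroid of the component's contacted band pixels
    zone = corner_contact_zone | side_contact_zone
    zr, zc = np.nonzero(zone)
    zlab = labels[zr, zc]
    contact_n = np.bincount(zlab, minlength=n + 1)
    sum_r = np.bincount(zlab, weights=zr, minlength=n + 1)
    sum_c = np.bincount(zlab, weights=zc, minlength=n + 1)
    records: list[ExtensionRecord] = []
    for lab in range(1, n + 1):
        if contact_n[lab] == 0:
            continue  # exterior debris not touching the boundary
        area = areas_px[lab] * px2
        if not (area > min_area_um2):
            continue
        region = "corner" if corner_contact[lab] >= side_contact[lab] else "side"
        records.append(
            ExtensionRecord(
                component_id=int(lab),
                area_um2=float(area),
                emanation_point=(
                    float(sum_r[lab] / contact_n[lab]),
                    float(sum_c[lab] / contact_n[lab]),
                ),
                region=region,
                timepoint_min=timepoint_min,
                cell_id=cell_id,
            )
        )
    return records


def detect_cdrs(
    seg: SegmentationResult,
    partition: RegionPartition,
    min_annularity: float = 0.1,
    erosion_um: float = 1.0,
    cell_id: str | None = None,
    timepoint_min: float | None = None,
) -> list[CDRRecord]:
    """Detect circular dorsal ruffles as interior annular bright components.

    A component qualifies when it lies wholly inside the island footprint
    eroded by ``erosion_um`` (no boundary contact) and its annularity
    (hole area / filled area) is strictly greater than ``min_annularity``.
    ``area_um2`` is the ring-filled area, matching the convention that a CDR's
    size is the area it encircles.
    """
    _check_shapes(seg, partition)
    px2 = partition.island.pixel_size_um**2
    interior = partition.footprint_mask(margin_um=erosion_um)
    labels = cc_label(seg.extension_candidate_mask, connectivity=2)
    n = int(labels.max())
    if n == 0:
        return []
    # pixels outside the eroded footprint disqualify a component outright
    outside_counts = np.bincount(labels[~interior], minlength=n + 1)
    slices = ndimage.find_objects(labels)
    records: list[CDRRecord] = []
    for lab in range(1, n + 1):
        if outside_counts[lab] > 0:
            continue  # touches or crosses the eroded boundary: lateral, not dorsal
        sl = slices[lab - 1]
        comp = labels[sl] == lab
        filled = ndimage.binary_fill_holes(comp)
        n_filled = int(filled.sum())
        n_hole = n_filled - int(comp.sum())
        annularity = n_hole / n_filled if n_filled else 0.0
        if not (annularity > min_annularity):
            continue
        rr, cc = np.nonzero(filled)
        records.append(
            CDRRecord(
                component_id=int(lab),
                area_um2=float(n_filled * px2),
                annularity=float(annularity),
                centroid=(float(rr.mean() + sl[0].start), float(cc.mean() + sl[1].start)),
                timepoint_min=timepoint_min,
                cell_id=cell_id,
            )
        )
    return records


def summarize_extensions(
    extensions: list[ExtensionRecord],
    cdrs: list[CDRRecord] | None = None,
    cell_id: str | None = None,
    timepoint_min: float | None = None,
) -> ExtensionSummary:
    """Sum member record areas into a per-cell summary (areas conserve).

    ``corner_fraction = corner / (corner + side)`` is NaN (flagged undefined)
    when no lateral extension area was measured.
    """
    cdrs = cdrs or []
    for rec in extensions:
        if rec.cell_id is not None and cell_id is not None and rec.cell_id != cell_id:
            raise IntegrityError(f"record cell_id {rec.cell_id!r} != summary cell_id {cell_id!r}")
    corner = sum(r.area_um2 for r in extensions if r.region == "corner")
    side = sum(r.area_um2 for r in extensions if r.region == "side")
    cdr_area = sum(r.area_um2 for r in cdrs)
    total = corner + side
    fraction = corner / total if total > 0 else math.nan
    return ExtensionSummary(
        cell_id=cell_id,
        timepoint_min=timepoint_min,
        corner_area_um2=float(corner),
        side_area_um2=float(side),
        cdr_area_um2=float(cdr_area),
        corner_fraction=float(fraction),
        n_extensions=len(extensions),
        n_cdrs=len(cdrs),
    )


def assemble_timecourse(
    summaries: list[ExtensionSummary], condition: str = ""
) -> pd.DataFrame:
    """Collapse per-cell summaries into a long-format time-course table.

    One row per (timepoint, region) with mean area, standard deviation
    (NaN when n < 2) and n.  Duplicate (cell, timepoint) pairs raise
    :class:`IntegrityError`.
    """
    seen: set[tuple] = set()
    rows = []
    for s in summaries:
        key = (s.cell_id, s.timepoint_min)
        if key in seen:
            raise IntegrityError(f"duplicate (cell, timepoint) summary: {key}")
        seen.add(key)
        for region, area in (
            ("corner", s.corner_area_um2),
            ("side", s.side_area_um2),
            ("cdr", s.cdr_area_um2),
        ):
            rows.append(
                {
                    "condition": condition,
                    "timepoint_min": s.timepoint_min,
                    "region": region,
                    "area_um2": area,
                }
            )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["condition", "timepoint_min", "region"], dropna=False)["area_um2"]
        .agg(mean_area_um2="mean", sd_area_um2="std", n="count")
        .reset_index()
    )
    region_order = pd.CategoricalDtype(["corner", "side", "cdr"], ordered=True)
    out["region"] = out["region"].astype(region_order)
    out = out.sort_values(["condition", "timepoint_min", "region"]).reset_index(drop=True)
    out["region"] = out["region"].astype(str)
    return out
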