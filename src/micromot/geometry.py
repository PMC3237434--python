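"""Square adhesive island geometry and the corner/side region partition.

Cells confined to square micropatterned ECM islands polarize geometrically:
traction and focal adhesions concentrate at the four corners.  To quantify
that preference, the cell outline is overlaid with a 4x4 grid that divides
the island boundary into *corner* regions (the four corner grid cells, i.e.
the outer quarter of each edge at both ends) and *side* regions (the eight
edge-interior grid cells, i.e. the central half of each edge).  Each class
covers exactly half of the perimeter (2L each for side length L), so raw
corner/side area or count comparisons are not confounded by boundary length.

Coordinate conventions
----------------------
Image coordinates are 0-based ``(row, col)`` pixel indices with the origin at
the top-left; physical coordinates are ``pixel * pixel_size_um``.  Each island
carries a local frame ``(u, v)`` in micrometres with the island corner mapped
from ``origin`` at ``(0, 0)`` and ``u, v`` in ``[0, L]``; ``rotation_deg``
rotates the island in the image plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np

from .errors import ClassificationError, GeometryError

#: Label values used in all region label images.
CORNER = 1
SIDE = 2

_REGION_NAMES = {CORNER: "corner", SIDE: "side"}


@dataclass(frozen=True)
class IslandModel:
    """Geometric model of one square adhesive island.

    Parameters
    ----------
    origin:
        ``(row, col)`` pixel position of the island's local ``(0, 0)`` corner.
    side_length_um:
        Physical side length L in micrometres.  Micropatterned islands for
        single cells are 30-50 um on a side (areas 900-2500 um^2).
    pixel_size_um:
        Physical size of one pixel (um/pixel).
    rotation_deg:
        In-plane rotation of the island, degrees, counter-clockwise in the
        ``(x, y) = (col, row)`` plane.
    """

    origin: tuple[float, float]
    side_length_um: float
    pixel_size_um: float
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (self.side_length_um > 0):
            raise GeometryError(f"side_length_um must be > 0, got {self.side_length_um}")
        if not (self.pixel_size_um > 0):
            raise GeometryError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def side_length_px(self) -> float:
        return self.side_length_um / self.pixel_size_um

    @property
    def area_um2(self) -> float:
        return self.side_length_um**2

    def to_local(self, points_rc: np.ndarray) -> np.ndarray:
        """Map image points ``(row, col)`` (px) to local ``(u, v)`` (um)."""
        pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
        r0, c0 = self.origin
        x = (pts[:, 1] - c0) * self.pixel_size_um
        y = (pts[:, 0] - r0) * self.pixel_size_um
        th = np.deg2rad(self.rotation_deg)
        u = x * np.cos(th) + y * np.sin(th)
        v = -x * np.sin(th) + y * np.cos(th)
        return np.column_stack([u, v])

    def to_image(self, points_uv: np.ndarray) -> np.ndarray:
        """Map local ``(u, v)`` (um) points to image ``(row, col)`` (px)."""
        pts = np.atleast_2d(np.asarray(points_uv, dtype=float))
        th = np.deg2rad(self.rotation_deg)
        x = pts[:, 0] * np.cos(th) - pts[:, 1] * np.sin(th)
        y = pts[:, 0] * np.sin(th) + pts[:, 1] * np.cos(th)
        r0, c0 = self.origin
        return np.column_stack([y / self.pixel_size_um + r0, x / self.pixel_size_um + c0])

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "IslandModel":
        d = json.loads(text)
        d["origin"] = tuple(d["origin"])
        return cls(**d)


def _local_grids(island: IslandModel, frame_shape: tuple[int, int]):
    # the affine map is separable in row/col, so build it from 1D outer sums
    r0, c0 = island.origin
    s = island.pixel_size_um
    th = np.deg2rad(island.rotation_deg)
    x = (np.arange(frame_shape[1], dtype=float) - c0) * s
    y = (np.arange(frame_shape[0], dtype=float) - r0) * s
    u = np.add.outer(y * np.sin(th), x * np.cos(th))
    v = np.add.outer(y * np.cos(th), -x * np.sin(th))
    return u, v


def _classify_uv(u: np.ndarray, v: np.ndarray, L: float) -> np.ndarray:
    """Corner/side label of the boundary point nearest to each local point.

    The position along the nearest edge determines the class: within the outer
    quarter of the edge (distance <= L/4 from a vertex, ties inclusive) is
    corner, the central half is side.
    """
    uc = np.clip(u, 0.0, L)
    vc = np.clip(v, 0.0, L)
    du = np.minimum(uc, L - uc)
    dv = np.minimum(vc, L - vc)
    # nearest edge is vertical (u = 0 or L) when du <= dv; its along-edge
    # coordinate is v, otherwise u.  Grid-junction tie-break: <= gives corner.
    pos = np.where(du <= dv, vc, uc)
    m = np.minimum(pos, L - pos)
    return np.where(m <= L / 4.0 + 1e-9, CORNER, SIDE).astype(np.int8)


def _boundary_distance_uv(u: np.ndarray, v: np.ndarray, L: float) -> np.ndarray:
    """Unsigned distance (um) from local points to the island boundary."""
    dx = np.maximum(np.maximum(-u, u - L), 0.0)
    dy = np.maximum(np.maximum(-v, v - L), 0.0)
    outside = np.hypot(dx, dy)
    inside = np.minimum(np.minimum(u, L - u), np.minimum(v, L - v))
    return np.where(outside > 0, outside, np.maximum(inside, 0.0))


@dataclass(frozen=True)
class RegionPartition:
    """Corner/side partition of a square island boundary.

    ``corner_mask``/``side_mask`` are one-pixel boundary bands rasterized over
    ``frame_shape``; boundary lengths are pixel-count estimates (count times
    pixel size), so the two classes agree to rasterization tolerance.
    """

    island: IslandModel
    frame_shape: tuple[int, int]
    corner_mask: np.ndarray
    side_mask: np.ndarray
    corner_boundary_length_um: float
    side_boundary_length_um: float

    @property
    def boundary_mask(self) -> np.ndarray:
        return self.corner_mask | self.side_mask

    def label_image(self) -> np.ndarray:
        lab = np.zeros(self.frame_shape, dtype=np.uint8)
        lab[self.corner_mask] = CORNER
        lab[self.side_mask] = SIDE
        return lab

    def _uv(self):
        # cached full-frame local coordinates; partitions are reused across
        # many cells of a cohort, so this dominates without the cache
        cache = self.__dict__.setdefault("_cache", {})
        if "uv" not in cache:
            cache["uv"] = _local_grids(self.island, self.frame_shape)
        return cache["uv"]

    def footprint_mask(self, margin_um: float = 0.0) -> np.ndarray:
        """Pixels inside the island, optionally eroded by ``margin_um``."""
        cache = self.__dict__.setdefault("_cache", {})
        key = ("footprint", float(margin_um))
        if key not in cache:
            u, v = self._uv()
            L = self.island.side_length_um
            inside = (u >= 0) & (u <= L) & (v >= 0) & (v <= L)
            if margin_um > 0:
                inside &= _boundary_distance_uv(u, v, L) >= margin_um
            cache[key] = inside
        return cache[key]


def default_frame_shape(island: IslandModel, margin_um: float = 15.0) -> tuple[int, int]:
    """Frame that contains the island bounding box plus a margin on all sides."""
    corners_uv = np.array(
        [[0, 0], [island.side_length_um, 0], [0, island.side_length_um],
         [island.side_length_um, island.side_length_um]]
    )
    rc = island.to_image(corners_uv)
    m = margin_um / island.pixel_size_um
    return (int(np.ceil(rc[:, 0].max() + m)) + 1, int(np.ceil(rc[:, 1].max() + m)) + 1)


def build_partition(
    island: IslandModel,
    frame_shape: tuple[int, int] | None = None,
    band_halfwidth_um: float | None = None,
) -> RegionPartition:
    """Build the 4x4-grid corner/side boundary partition of an island.

    The boundary band contains pixels whose centre lies within half a pixel of
    the island outline; each band pixel receives exactly one label, so the
    corner and side masks partition the rasterized boundary.
    """
    if frame_shape is None:
        frame_shape = default_frame_shape(island)
    L = island.side_length_um
    u, v = _local_grids(island, frame_shape)
    if band_halfwidth_um is None:
        band_halfwidth_um = island.pixel_size_um / 2.0
    band = _boundary_distance_uv(u, v, L) <= band_halfwidth_um + 1e-9
    labels = _classify_uv(u, v, L)
    corner_mask = band & (labels == CORNER)
    side_mask = band & (labels == SIDE)
    # pixel-count length estimates, normalized by the band width in pixels;
    # pixels exactly on a corner/side junction have zero-measure membership,
    # so they contribute half to each class even though the mask labels them
    # corner by the documented tie-break
    uc = np.clip(u, 0.0, L)
    vc = np.clip(v, 0.0, L)
    pos = np.where(np.minimum(uc, L - uc) <= np.minimum(vc, L - vc), vc, uc)
    m = np.minimum(pos, L - pos)
    n_tie = int((band & (np.abs(m - L / 4.0) <= 1e-9)).sum())
    width_px = max(1.0, 2.0 * band_halfwidth_um / island.pixel_size_um)
    corner_len = (corner_mask.sum() - 0.5 * n_tie) * island.pixel_size_um / width_px
    side_len = (side_mask.sum() + 0.5 * n_tie) * island.pixel_size_um / width_px
    return RegionPartition(
        island=island,
        frame_shape=frame_shape,
        corner_mask=corner_mask,
        side_mask=side_mask,
        corner_boundary_length_um=float(corner_len),
        side_boundary_length_um=float(side_len),
    )


def classify_boundary_point(
    partition: RegionPartition, point_rc: Iterable[float], tol_um: float = 1.0
) -> str:
    """Classify a boundary point (image px) as ``"corner"`` or ``"side"``.

    The point is snapped to the island boundary if it lies within ``tol_um``;
    otherwise a :class:`ClassificationError` is raised.  Points exactly on a
    corner/side grid junction resolve to corner (documented tie-break).
    """
    island = partition.island
    uv = island.to_local(np.asarray(point_rc, dtype=float))
    L = island.side_length_um
    d = float(_boundary_distance_uv(uv[:, 0], uv[:, 1], L)[0])
    if d > tol_um:
        raise ClassificationError(
            f"point {tuple(point_rc)} is {d:.3g} um from the island boundary "
            f"(tolerance {tol_um} um)"
        )
    lab = int(_classify_uv(uv[:, 0], uv[:, 1], L)[0])
    return _REGION_NAMES[lab]


def interior_region_masks(partition: RegionPartition, band_depth_um: float) -> np.ndarray:
    """Interior corner/side zones of equal total area and edge contact.

    Corner zones are L-shaped bands of depth ``band_depth_um`` hugging the two
    edges at each vertex over the outer quarter of each edge; side zones are
    bands along the central half of each edge with depth chosen so the two
    classes have exactly equal total area.  Both classes contact the island
    edge over 2L in total.  At ``band_depth_um = L/4`` the corner zones are
    exactly the four corner cells of the 4x4 grid; deeper bands would let the
    corner bands intrude on the side bands' territory and break the equal-area
    identity, so the valid depth range is (0, L/4].

    Returns a label image over the partition frame (0 background,
    1 corner, 2 side).
    """
    island = partition.island
    L = island.side_length_um
    d = float(band_depth_um)
    if not (0 < d <= L / 4.0):
        raise GeometryError(
            f"band_depth_um must lie in (0, L/4] = (0, {L / 4}], got {band_depth_um}"
        )
    e = min(d, L / 4.0)
    d_side = d - 2.0 * e * e / L  # equal-area side band depth
    u, v = partition._uv()
    inside = (u >= 0) & (u <= L) & (v >= 0) & (v <= L)
    du = np.minimum(u, L - u)
    dv = np.minimum(v, L - v)
    pos_u = np.minimum(u, L - u)  # distance along horizontal edges to nearest vertex
    pos_v = np.minimum(v, L - v)
    quarter = L / 4.0
    corner = inside & (
        ((du <= d) & (pos_v <= quarter)) | ((dv <= d) & (pos_u <= quarter))
    )
    side = (
        inside
        & ~corner
        & (((du <= d_side) & (pos_v > quarter)) | ((dv <= d_side) & (pos_u > quarter)))
    )
    lab = np.zeros(partition.frame_shape, dtype=np.int8)
    lab[corner] = CORNER
    lab[side] = SIDE
    return lab


def save_partition(partition: RegionPartition, tiff_path, json_path) -> None:
    """Export the partition label image as TIFF and the geometry as JSON."""
    import tifffile

    tifffile.imwrite(str(tiff_path), partition.label_image())
    with open(json_path, "w") as fh:
        fh.write(partition.island.to_json())
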