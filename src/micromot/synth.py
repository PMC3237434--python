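"""Seeded synthetic microscopy data with known ground truth.

Every quantification stage in this package is exercised against synthetic
inputs that emulate the corresponding assay:

* :func:`generate_island_cell_image` -- one square cell on a 50x50 um
  fibronectin island, with bright peripheral extension lobes placed with a
  controllable corner bias, optional interior annular CDRs, and a separate
  adhesion channel with region-specific focal-adhesion counts and lengths;
* :func:`simulate_tracks` -- persistent biased random walks of cells at a
  scrape-wound edge over a 6 h / 6 min-interval sampling scale;
* :func:`generate_invasion_stack` -- nuclei z-stacks (16 planes at 4 um,
  0-60 um) with depths drawn from a non-invasive/invasive mixture.

All generators are deterministic: the same parameters and seed produce
bit-identical outputs.  One root seed spawns independent substreams for
geometry and for sensor noise so stages can be regenerated independently.
Analytic ground truth (areas, regions, lengths, depths) is recorded at
placement time and is consistent with the rasterized images up to the stated
rasterization conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DensityError, GeometryError
from .geometry import IslandModel, _local_grids, default_frame_shape
from .invasion import ZStackSpec
from .tracks import CellTrack, WoundFrame

# ---------------------------------------------------------------------------
# parameters


def default_island(side_length_um: float = 50.0, pixel_size_um: float = 0.2,
                   margin_um: float = 15.0) -> IslandModel:
    """Axis-aligned island centred in a frame with the given margin."""
    m = margin_um / pixel_size_um
    return IslandModel(origin=(m, m), side_length_um=side_length_um,
                       pixel_size_um=pixel_size_um)


@dataclass
class SyntheticParams:
    """Ground-truth parameters of the synthetic assays.

    Defaults reproduce the study conditions: 50 um islands at 0.2 um/pixel,
    four extension lobes per cell totalling ~200 um^2, 5 um CDR rings with a
    3 um hole, corner FAs longer than side FAs (4 vs 2 um), 6 h tracks
    sampled every 6 min, and a 0-60 um invasion depth range.
    """

    seed: int = 0
    island: IslandModel = field(default_factory=default_island)
    frame_margin_um: float = 15.0
    # lateral extensions
    corner_bias: float = 0.5  # probability a lobe emanates from a corner region
    mean_total_extension_um2: float = 200.0
    n_extension_lobes: int = 4
    extension_areas_um2: tuple[float, ...] | None = None  # explicit override
    lobe_inset_um: float = 0.5  # how far a lobe crosses inside the island edge
    # circular dorsal ruffles
    cdr_rate: float = 0.0  # expected CDRs per cell (Poisson)
    cdr_radius_um: float = 5.0
    cdr_hole_radius_um: float = 3.0
    # focal adhesions (separate channel)
    fa_count_corner: int = 10
    fa_count_side: int = 4
    fa_length_mean_corner_um: float = 4.0
    fa_length_mean_side_um: float = 2.0
    fa_length_sd_um: float = 0.5
    fa_width_um: float = 0.8
    adhesion_spec: tuple[tuple[str, float], ...] | None = None  # (region, length) override
    # imaging / noise model
    background: float = 10.0
    cell_body_level: float = 30.0
    adhesion_cell_level: float = 25.0
    structure_level: float = 200.0
    noise_sd: float = 5.0
    psf_sigma_um: float = 0.3
    # wound tracks
    track_speed_um_min: float = 0.5
    track_persistence: float = 0.7  # weight of the previous step direction
    track_bias: float = 0.5  # weight of the wound-normal direction
    track_kappa: float = 10.0  # von Mises concentration scale
    track_n_steps: int = 60
    track_dt_min: float = 6.0
    track_start_spread_um: float = 100.0
    # invasion stacks
    fraction_invasive: float = 0.3
    invasive_min_depth_um: float = 12.0
    depth_scale_um: float = 12.0
    noninvasive_max_depth_um: float = 6.0
    nucleus_r_xy_um: float = 4.0
    nucleus_r_z_um: float = 4.0
    nucleus_level: float = 200.0
    fov_size_um: float = 128.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.corner_bias <= 1.0):
            raise GeometryError(f"corner_bias must be in [0, 1], got {self.corner_bias}")
        if not (0.0 <= self.fraction_invasive <= 1.0):
            raise GeometryError(f"fraction_invasive must be in [0, 1], got {self.fraction_invasive}")
        for name in ("mean_total_extension_um2", "cdr_radius_um", "track_speed_um_min",
                     "track_dt_min", "depth_scale_um", "nucleus_r_xy_um"):
            if getattr(self, name) < 0:
                raise GeometryError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# ground-truth containers


@dataclass
class LobeTruth:
    region: str
    area_full_um2: float  # planted disk area
    area_exterior_um2: float  # analytic area outside the island footprint
    emanation_uv: tuple[float, float]
    radius_um: float


@dataclass
class CdrTruth:
    center_uv: tuple[float, float]
    outer_radius_um: float
    inner_radius_um: float
    filled_area_um2: float


@dataclass
class AdhesionTruth:
    region: str
    length_um: float
    centroid_uv: tuple[float, float]
    orientation_rad: float


@dataclass
class CellImageTruth:
    island: IslandModel
    lobes: list[LobeTruth]
    cdrs: list[CdrTruth]
    adhesions: list[AdhesionTruth]
    structure_mask: np.ndarray  # pre-noise bright-structure mask (actin channel)

    @property
    def corner_area_um2(self) -> float:
        return sum(l.area_exterior_um2 for l in self.lobes if l.region == "corner")

    @property
    def side_area_um2(self) -> float:
        return sum(l.area_exterior_um2 for l in self.lobes if l.region == "side")

    @property
    def corner_fraction(self) -> float:
        total = self.corner_area_um2 + self.side_area_um2
        return self.corner_area_um2 / total if total > 0 else math.nan


@dataclass
class TrackTruth:
    speed_um_min: float
    persistence: float
    bias: float
    n_steps: int
    dt_min: float
    starts_um: np.ndarray


@dataclass
class InvasionTruth:
    depths_um: np.ndarray
    invasive: np.ndarray  # bool, drawn mixture component
    positions_um: np.ndarray
    fraction_invasive: float


# ---------------------------------------------------------------------------
# low-level painters


def _paint_disk(img: np.ndarray, center_rc: tuple[float, float], radius_px: float,
                level: float) -> None:
    r0, c0 = center_rc
    rmin = max(int(math.floor(r0 - radius_px)) - 1, 0)
    rmax = min(int(math.ceil(r0 + radius_px)) + 2, img.shape[0])
    cmin = max(int(math.floor(c0 - radius_px)) - 1, 0)
    cmax = min(int(math.ceil(c0 + radius_px)) + 2, img.shape[1])
    if rmin >= rmax or cmin >= cmax:
        raise GeometryError("painted structure falls outside the image frame")
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2
    sub = img[rmin:rmax, cmin:cmax]
    sub[mask] = np.maximum(sub[mask], level)


def _paint_annulus(img: np.ndarray, center_rc, r_in_px: float, r_out_px: float,
                   level: float) -> None:
    r0, c0 = center_rc
    rmin = max(int(math.floor(r0 - r_out_px)) - 1, 0)
    rmax = min(int(math.ceil(r0 + r_out_px)) + 2, img.shape[0])
    cmin = max(int(math.floor(c0 - r_out_px)) - 1, 0)
    cmax = min(int(math.ceil(c0 + r_out_px)) + 2, img.shape[1])
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    mask = (d2 <= r_out_px**2) & (d2 >= r_in_px**2)
    sub = img[rmin:rmax, cmin:cmax]
    sub[mask] = np.maximum(sub[mask], level)


def _paint_ellipse(img: np.ndarray, center_rc, a_px: float, b_px: float,
                   phi_rad: float, level: float) -> None:
    r0, c0 = center_rc
    ext = max(a_px, b_px)
    rmin = max(int(math.floor(r0 - ext)) - 1, 0)
    rmax = min(int(math.ceil(r0 + ext)) + 2, img.shape[0])
    cmin = max(int(math.floor(c0 - ext)) - 1, 0)
    cmax = min(int(math.ceil(c0 + ext)) + 2, img.shape[1])
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    dx = cc - c0
    dy = rr - r0
    xr = dx * math.cos(phi_rad) + dy * math.sin(phi_rad)
    yr = -dx * math.sin(phi_rad) + dy * math.cos(phi_rad)
    mask = (xr / a_px) ** 2 + (yr / b_px) ** 2 <= 1.0
    sub = img[rmin:rmax, cmin:cmax]
    sub[mask] = np.maximum(sub[mask], level)


def _circular_segment_area(r: float, h: float) -> float:
    """Area of the circular segment of sagitta ``h`` in a disk of radius ``r``."""
    h = min(max(h, 0.0), 2 * r)
    return r * r * math.acos(1.0 - h / r) - (r - h) * math.sqrt(2 * r * h - h * h)


# boundary parametrization: edge index -> (point(u_along), outward normal)
def _edge_point(edge: int, t: float, L: float) -> tuple[tuple[float, float], tuple[float, float]]:
    if edge == 0:
        return (t, 0.0), (0.0, -1.0)
    if edge == 1:
        return (L, t), (1.0, 0.0)
    if edge == 2:
        return (t, L), (0.0, 1.0)
    return (0.0, t), (-1.0, 0.0)


def _finalize(img: np.ndarray, params: SyntheticParams, noise_rng: np.random.Generator) -> np.ndarray:
    sigma_px = params.psf_sigma_um / params.island.pixel_size_um
    if sigma_px > 0:
        img = ndimage.gaussian_filter(img, sigma=sigma_px)
    if params.noise_sd > 0:
        img = img + noise_rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img, 0.0, None).astype(np.float32)


# ---------------------------------------------------------------------------
# island cell images


def generate_island_cell_image(
    params: SyntheticParams,
    rng: np.random.Generator | None = None,
    channels: tuple[str, ...] = ("actin", "adhesion"),
) -> tuple[np.ndarray, np.ndarray | None, CellImageTruth]:
    """Render one synthetic square cell: (actin image, adhesion image, truth).

    ``channels`` restricts rendering; an omitted channel is returned as
    ``None`` (truth placement draws are identical either way, so the actin
    channel is bit-identical whether or not adhesions are rendered).

    The cell body fills the island at a dim cytoplasmic level; extension
    lobes are bright disks placed at boundary points drawn from corner/side
    arcs according to ``corner_bias`` and crossing ``lobe_inset_um`` inside
    the edge, so their analytic exterior area is the planted disk area minus
    one circular segment.  CDR rings and focal adhesions are painted at
    placement positions recorded in the truth.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    seed_seq = getattr(rng.bit_generator, "seed_seq", None)
    if seed_seq is not None:
        geom_rng, noise_rng, noise_rng2 = (np.random.default_rng(s) for s in seed_seq.spawn(3))
    else:  # pragma: no cover - exotic bit generators without a seed sequence
        geom_rng = noise_rng = noise_rng2 = rng
    island = params.island
    L = island.side_length_um
    px = island.pixel_size_um
    render_adhesion = "adhesion" in channels
    shape = default_frame_shape(island, margin_um=params.frame_margin_um)
    actin = np.full(shape, params.background, dtype=np.float64)
    adhesion = np.full(shape, params.background, dtype=np.float64) if render_adhesion else None

    # cell body: fill the island footprint
    u, v = _local_grids(island, shape)
    inside = (u >= 0) & (u <= L) & (v >= 0) & (v <= L)
    actin[inside] = np.maximum(actin[inside], params.cell_body_level)
    if render_adhesion:
        adhesion[inside] = np.maximum(adhesion[inside], params.adhesion_cell_level)

    structures = np.zeros(shape, dtype=bool)

    # --- extension lobes -------------------------------------------------
    lobes: list[LobeTruth] = []
    if params.extension_areas_um2 is not None:
        areas = list(params.extension_areas_um2)
    elif params.mean_total_extension_um2 > 0 and params.n_extension_lobes > 0:
        mean_lobe = params.mean_total_extension_um2 / params.n_extension_lobes
        # gamma(k=6) lobe-to-lobe variability, truncated at 3x the mean: a
        # single lobe beyond that is not a realistic lamellipodium and would
        # outgrow the imaging frame
        areas = list(np.minimum(
            geom_rng.gamma(shape=6.0, scale=mean_lobe / 6.0, size=params.n_extension_lobes),
            3.0 * mean_lobe,
        ))
    else:
        areas = []
    placed_pts: list[tuple[float, float, float]] = []  # (u, v, radius)
    clearance = 2.5  # um kept clear of corner/side junctions
    for area in areas:
        radius = math.sqrt(area / math.pi)
        is_corner = bool(geom_rng.random() < params.corner_bias)
        for _ in range(200):
            edge = int(geom_rng.integers(0, 4))
            if is_corner:
                lo, hi = radius, max(L / 4.0 - clearance, radius + 1e-6)
                t = float(geom_rng.uniform(lo, hi))
                if geom_rng.random() < 0.5:
                    t = L - t
            else:
                t = float(geom_rng.uniform(L / 4.0 + clearance, 3 * L / 4.0 - clearance))
            (u0, v0), normal = _edge_point(edge, t, L)
            ok = all(
                math.hypot(u0 - pu, v0 - pv) >= radius + pr + 1.0
                for pu, pv, pr in placed_pts
            )
            if ok:
                break
        placed_pts.append((u0, v0, radius))
        inset = min(params.lobe_inset_um, radius)
        center_uv = (u0 + normal[0] * (radius - inset), v0 + normal[1] * (radius - inset))
        center_rc = island.to_image(np.array(center_uv))[0]
        r_px = radius / px
        if (center_rc[0] - r_px < 0 or center_rc[0] + r_px >= shape[0]
                or center_rc[1] - r_px < 0 or center_rc[1] + r_px >= shape[1]):
            raise GeometryError(
                f"extension lobe of radius {radius:.1f} um exceeds the image frame; "
                "increase frame_margin_um"
            )
        _paint_disk(actin, (center_rc[0], center_rc[1]), r_px, params.structure_level)
        _paint_disk(structures, (center_rc[0], center_rc[1]), radius / px, True)
        area_full = math.pi * radius**2
        area_ext = area_full - _circular_segment_area(radius, inset)
        lobes.append(
            LobeTruth(
                region="corner" if is_corner else "side",
                area_full_um2=area_full,
                area_exterior_um2=area_ext,
                emanation_uv=(u0, v0),
                radius_um=radius,
            )
        )

    # --- circular dorsal ruffles -----------------------------------------
    cdrs: list[CdrTruth] = []
    n_cdr = int(geom_rng.poisson(params.cdr_rate)) if params.cdr_rate > 0 else 0
    margin = params.cdr_radius_um + 2.0
    for _ in range(n_cdr):
        placed = False
        for _ in range(100):
            cu = float(geom_rng.uniform(margin, L - margin))
            cv = float(geom_rng.uniform(margin, L - margin))
            if all(
                math.hypot(cu - c.center_uv[0], cv - c.center_uv[1])
                >= 2 * params.cdr_radius_um + 1.0
                for c in cdrs
            ):
                placed = True
                break
        if not placed:
            continue
        center_rc = island.to_image(np.array([cu, cv]))[0]
        _paint_annulus(
            actin,
            (center_rc[0], center_rc[1]),
            params.cdr_hole_radius_um / px,
            params.cdr_radius_um / px,
            params.structure_level,
        )
        _paint_annulus(
            structures,
            (center_rc[0], center_rc[1]),
            params.cdr_hole_radius_um / px,
            params.cdr_radius_um / px,
            True,
        )
        cdrs.append(
            CdrTruth(
                center_uv=(cu, cv),
                outer_radius_um=params.cdr_radius_um,
                inner_radius_um=params.cdr_hole_radius_um,
                filled_area_um2=math.pi * params.cdr_radius_um**2,
            )
        )

    # --- focal adhesions (separate channel) -------------------------------
    adhesions: list[AdhesionTruth] = []
    if params.adhesion_spec is not None:
        spec = list(params.adhesion_spec)
    else:
        spec = [("corner", float(geom_rng.normal(params.fa_length_mean_corner_um,
                                                 params.fa_length_sd_um)))
                for _ in range(params.fa_count_corner)]
        spec += [("side", float(geom_rng.normal(params.fa_length_mean_side_um,
                                                params.fa_length_sd_um)))
                 for _ in range(params.fa_count_side)]
    inset_zone = 1.5
    centers: list[tuple[float, float]] = []
    for region, length in spec:
        length = max(length, 0.8)
        for _ in range(100):
            if region == "corner":
                vtx = int(geom_rng.integers(0, 4))
                a = float(geom_rng.uniform(inset_zone, L / 4.0 - inset_zone))
                b = float(geom_rng.uniform(inset_zone, L / 4.0 - inset_zone))
                cu = a if vtx in (0, 3) else L - a
                cv = b if vtx in (0, 1) else L - b
            else:
                edge = int(geom_rng.integers(0, 4))
                t = float(geom_rng.uniform(L / 4.0 + inset_zone, 3 * L / 4.0 - inset_zone))
                w = float(geom_rng.uniform(1.0, L / 8.0 - 1.0))
                if edge == 0:
                    cu, cv = t, w
                elif edge == 1:
                    cu, cv = L - w, t
                elif edge == 2:
                    cu, cv = t, L - w
                else:
                    cu, cv = w, t
            # keep plaques from merging: centers at least half-lengths apart plus a gap
            if all(math.hypot(cu - x, cv - y) >= 5.0 for x, y in centers):
                break
        centers.append((cu, cv))
        phi = float(geom_rng.uniform(0, math.pi))
        if render_adhesion:
            center_rc = island.to_image(np.array([cu, cv]))[0]
            _paint_ellipse(
                adhesion,
                (center_rc[0], center_rc[1]),
                (length / 2.0) / px,
                (params.fa_width_um / 2.0) / px,
                phi,
                params.structure_level,
            )
        adhesions.append(
            AdhesionTruth(region=region, length_um=length, centroid_uv=(cu, cv),
                          orientation_rad=phi)
        )

    truth = CellImageTruth(
        island=island,
        lobes=lobes,
        cdrs=cdrs,
        adhesions=adhesions,
        structure_mask=structures.copy(),
    )
    actin = _finalize(actin, params, noise_rng)
    if render_adhesion:
        adhesion = _finalize(adhesion, params, noise_rng2)
    return actin, adhesion, truth


# ---------------------------------------------------------------------------
# wound-edge tracks


def simulate_tracks(
    params: SyntheticParams,
    n_cells: int,
    frame: WoundFrame,
    rng: np.random.Generator | None = None,
) -> tuple[list[CellTrack], TrackTruth]:
    """Simulate persistent biased random walks at a wound edge.

    Each step direction is drawn from a von Mises distribution whose mean is
    the resultant of the previous direction (weight ``track_persistence``)
    and the wound normal (weight ``track_bias``), with concentration
    ``track_kappa`` times the resultant length; a zero resultant falls back
    to a uniform direction, so zero persistence and zero bias give an
    unbiased random walk.  Step length is ``speed * dt``.
    """
    if params.track_n_steps < 2:
        raise GeometryError("track_n_steps must be >= 2")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    e = np.asarray(frame.edge_direction)
    nvec = np.asarray(frame.wound_normal)
    p0 = np.asarray(frame.edge_point)
    dt = params.track_dt_min
    step_len = params.track_speed_um_min * dt
    times = np.arange(params.track_n_steps + 1) * dt
    tracks: list[CellTrack] = []
    starts = []
    for i in range(n_cells):
        start = p0 + e * rng.uniform(-0.5, 0.5) * params.track_start_spread_um
        starts.append(start)
        pos = [start]
        u_prev = None
        for _ in range(params.track_n_steps):
            v = params.track_bias * nvec.copy()
            if u_prev is not None:
                v = v + params.track_persistence * u_prev
            norm = float(np.linalg.norm(v))
            if norm < 1e-12:
                theta = rng.uniform(-math.pi, math.pi)
            else:
                theta = rng.vonmises(math.atan2(v[1], v[0]), params.track_kappa * norm)
            u_prev = np.array([math.cos(theta), math.sin(theta)])
            pos.append(pos[-1] + u_prev * step_len)
        tracks.append(
            CellTrack(
                cell_id=f"cell{i:03d}",
                times_min=times.copy(),
                positions_um=np.asarray(pos),
            )
        )
    truth = TrackTruth(
        speed_um_min=params.track_speed_um_min,
        persistence=params.track_persistence,
        bias=params.track_bias,
        n_steps=params.track_n_steps,
        dt_min=dt,
        starts_um=np.asarray(starts),
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# invasion z-stacks


def generate_invasion_stack(
    params: SyntheticParams,
    n_cells: int,
    spec: ZStackSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, InvasionTruth]:
    """Render a nuclei z-stack with depths drawn from the invasion mixture.

    With probability ``fraction_invasive`` a nucleus depth is
    ``invasive_min_depth_um + Exp(depth_scale_um)`` (clipped 2 um below the
    stack top); otherwise it is uniform on ``[0, noninvasive_max_depth_um]``.
    The gap between the non-invasive maximum (6 um) and the invasive minimum
    (12 um) keeps the truth label stable under 4 um plane quantization at the
    strict 8 um threshold.  Nuclei are ellipsoids (r_xy x r_z) placed without
    xy overlap; exceeding the packing density raises :class:`DensityError`.
    """
    if spec is None:
        spec = ZStackSpec()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    px = spec.pixel_size_um
    n_xy = int(round(params.fov_size_um / px))
    stack = np.full((spec.n_planes, n_xy, n_xy), params.background, dtype=np.float64)
    r_xy_px = params.nucleus_r_xy_um / px
    min_sep = 2 * params.nucleus_r_xy_um + 1.0
    positions: list[tuple[float, float]] = []
    margin = params.nucleus_r_xy_um + 1.0
    tries_budget = 300 * n_cells
    while len(positions) < n_cells and tries_budget > 0:
        tries_budget -= 1
        x = float(rng.uniform(margin, params.fov_size_um - margin))
        y = float(rng.uniform(margin, params.fov_size_um - margin))
        if all(math.hypot(x - a, y - b) >= min_sep for a, b in positions):
            positions.append((x, y))
    if len(positions) < n_cells:
        raise DensityError(
            f"could only place {len(positions)}/{n_cells} nuclei without overlap; "
            "reduce n_cells or enlarge fov_size_um"
        )
    invasive = rng.random(n_cells) < params.fraction_invasive
    depths = np.where(
        invasive,
        np.clip(
            params.invasive_min_depth_um + rng.exponential(params.depth_scale_um, n_cells),
            None,
            spec.max_depth_um - 2.0,
        ),
        rng.uniform(0.0, params.noninvasive_max_depth_um, n_cells),
    )
    z_planes = spec.plane0_depth_um + np.arange(spec.n_planes) * spec.z_interval_um
    for (x, y), d in zip(positions, depths):
        for k, zk in enumerate(z_planes):
            dz = zk - d
            if abs(dz) >= params.nucleus_r_z_um:
                continue
            rad = params.nucleus_r_xy_um * math.sqrt(1.0 - (dz / params.nucleus_r_z_um) ** 2)
            if rad < px:
                continue
            _paint_disk(stack[k], (y / px, x / px), rad / px, params.nucleus_level)
    sigma_px = params.psf_sigma_um / px
    if sigma_px > 0:
        stack = ndimage.gaussian_filter(stack, sigma=(0, sigma_px, sigma_px))
    if params.noise_sd > 0:
        stack = stack + rng.normal(0.0, params.noise_sd, size=stack.shape)
    stack = np.clip(stack, 0.0, None).astype(np.float32)
    truth = InvasionTruth(
        depths_um=np.asarray(depths),
        invasive=np.asarray(invasive),
        positions_um=np.asarray(positions),
        fraction_invasive=params.fraction_invasive,
    )
    return stack, truth
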