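"""Synthetic subject phantoms for en-face OCTA slabs.

A phantom is one "eye": ground-truth boolean maps for the superficial (SCP)
and deep (DCP) capillary plexus, branching superficial large vessels, a
foveal avascular zone (FAZ), and a fine bright/dark choriocapillaris (CC)
texture.  The capillary mesh is built from the edge network of a Voronoi
tessellation of random seed points, which mimics the closed-loop polygonal
topology of the retinal capillary bed; the mesh is then thickened or pruned
pixel-by-pixel until the requested foreground fraction is hit, so the stored
``truth_fractions`` are exact pixel counts of the rendered maps.

All geometry is parameterised in microns where a physical scale exists
(vessel caliber, FAZ radius) and converted to pixels through the scan pitch,
so phantoms remain comparable across raster sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi, QhullError
from skimage.draw import line as _draw_line

__all__ = ["PhantomParams", "SubjectPhantom", "generate_phantom"]

MIN_SIDE = 64


@dataclass(frozen=True)
class PhantomParams:
    """Tunable geometry of a synthetic subject.

    Densities are Voronoi seed points per pixel^2 (a density of 0.02 gives
    cells of roughly 7 px, i.e. intercapillary spaces of ~160 um at the
    default 6 mm / 256 px pitch).  Target fractions are the requested
    foreground (flow) pixel fractions of each boolean map.
    """

    side: int = 1024
    cc_scale: int = 2                      # CC raster is cc_scale x side
    scan_width_um: float = 6000.0
    scp_capillary_density: float = 0.020
    dcp_capillary_density: float = 0.028
    large_vessel_count: int = 6
    vessel_width_um: Tuple[float, float] = (85.0, 120.0)
    max_vessel_fraction: float = 0.10
    faz_radius_um: float = 270.0
    scp_target_fraction: Optional[float] = 0.34
    dcp_target_fraction: Optional[float] = 0.38
    cc_flow_fraction: float = 0.75
    cc_texture_sigma_px: float = 1.2

    def __post_init__(self) -> None:
        if self.side < MIN_SIDE:
            raise ValueError(f"image side must be >= {MIN_SIDE} px, got {self.side}")
        if self.cc_scale < 1:
            raise ValueError("cc_scale must be >= 1")
        for name in ("scp_capillary_density", "dcp_capillary_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.large_vessel_count < 0:
            raise ValueError("large_vessel_count must be >= 0")
        if not 0.0 <= self.cc_flow_fraction <= 1.0:
            raise ValueError("cc_flow_fraction must be in [0, 1]")

    @property
    def pixel_pitch_um(self) -> float:
        return self.scan_width_um / self.side

    @property
    def cc_side(self) -> int:
        return self.side * self.cc_scale


@dataclass
class SubjectPhantom:
    """Ground truth for one synthetic eye."""

    seed: int
    params: PhantomParams
    large_vessel_map: np.ndarray      # bool, (side, side)
    scp_capillary_map: np.ndarray     # bool, (side, side)
    dcp_capillary_map: np.ndarray     # bool, (side, side)
    faz_mask: np.ndarray              # bool, (side, side)
    cc_flow_map: np.ndarray           # bool, (cc_side, cc_side)
    cc_texture: np.ndarray            # float in [0, 1], (cc_side, cc_side)
    #: per-pixel capillary signal amplitude (0 outside the capillary maps);
    #: spatially coherent perfusion heterogeneity, so the dimmest capillaries
    #: are the first to sink into the noise floor under attenuation
    scp_capillary_brightness: np.ndarray = None
    dcp_capillary_brightness: np.ndarray = None
    truth_fractions: Dict[str, float] = field(default_factory=dict)

    @property
    def scp_truth_map(self) -> np.ndarray:
        """Full SCP flow truth: capillaries plus large vessels."""
        return self.scp_capillary_map | self.large_vessel_map

    def validate(self) -> None:
        side = self.params.side
        for name in ("large_vessel_map", "scp_capillary_map",
                     "dcp_capillary_map", "faz_mask"):
            arr = getattr(self, name)
            if arr.shape != (side, side) or arr.dtype != bool:
                raise ValueError(f"{name} must be a bool ({side}, {side}) grid")
        if self.faz_mask.any():
            if (self.faz_mask & self.scp_truth_map).any():
                raise ValueError("FAZ contains SCP foreground pixels")
            if (self.faz_mask & self.dcp_capillary_map).any():
                raise ValueError("FAZ contains DCP foreground pixels")
        expected = {
            "SCP": float(self.scp_truth_map.mean()),
            "DCP": float(self.dcp_capillary_map.mean()),
            "CC": float(self.cc_flow_map.mean()),
        }
        if self.truth_fractions != expected:
            raise ValueError("truth_fractions do not match the rendered maps")


# ---------------------------------------------------------------------------
# capillary mesh

def _voronoi_edges(rng: np.random.Generator, side: int, n_points: int
                   ) -> List[np.ndarray]:
    """Rasterised finite Voronoi ridge segments, one pixel array per edge."""
    if n_points < 4:
        return []
    pts = rng.uniform(0, side, size=(n_points, 2))
    try:
        vor = Voronoi(pts)
    except QhullError:
        return []
    edges: List[np.ndarray] = []
    for (a, b) in vor.ridge_vertices:
        if a == -1 or b == -1:
            continue
        pa, pb = vor.vertices[a], vor.vertices[b]
        # drop ridges that run far outside the field
        if max(abs(pa).max(), abs(pb).max()) > 4 * side:
            continue
        rr, cc = _draw_line(int(round(pa[0])), int(round(pa[1])),
                            int(round(pb[0])), int(round(pb[1])))
        keep = (rr >= 0) & (rr < side) & (cc >= 0) & (cc < side)
        if keep.any():
            edges.append(rr[keep] * side + cc[keep])
    return edges


#: half-width of a capillary tube in px (distance-transform radius); keeps
#: the rendered mesh a network of constant-caliber tubes rather than blobs
CAPILLARY_TUBE_RADIUS = 1.0


def _tube_mesh(seed_base: int, side: int, n_points: int,
               forbidden: np.ndarray) -> np.ndarray:
    """Constant-caliber tube network over a Voronoi edge skeleton."""
    rng = np.random.default_rng(np.random.SeedSequence([seed_base, n_points]))
    edges = _voronoi_edges(rng, side, n_points)
    lines = np.zeros(side * side, dtype=bool)
    for px in edges:
        lines[px] = True
    lines2d = lines.reshape(side, side)
    if not lines2d.any():
        return lines2d
    dist = ndimage.distance_transform_edt(~lines2d)
    return (dist <= CAPILLARY_TUBE_RADIUS) & ~forbidden


def _mesh_with_fraction(
    rng: np.random.Generator,
    side: int,
    density: float,
    forbidden: np.ndarray,
    fixed: np.ndarray,
    target_fraction: Optional[float],
) -> np.ndarray:
    """Capillary mesh map, optionally calibrated to a target total fraction.

    The mesh is a network of constant-caliber tubes over the edge skeleton
    of a Voronoi tessellation — capillary density in the retina varies by
    intercapillary spacing, not by caliber.  When a target foreground
    fraction is requested, the tessellation's cell count is adjusted (the
    total edge length grows like sqrt(cells)) until the rendered fraction
    brackets the target, and the residual handful of pixels is annexed
    from, or pruned at, the tube boundary so the achieved fraction lands
    within one pixel of the request.  ``fixed`` pixels (large vessels)
    count toward the target but are never edited; ``forbidden`` pixels
    (FAZ) never receive capillaries.
    """
    if density <= 0:
        return np.zeros((side, side), dtype=bool)
    n_points = max(4, int(round(density * side * side)))
    seed_base = int(rng.integers(0, 2 ** 31))
    available = ~forbidden & ~fixed
    mesh2d = _tube_mesh(seed_base, side, n_points, forbidden) & available

    if target_fraction is None or not mesh2d.any():
        return mesh2d

    total_target = int(round(target_fraction * side * side))
    cap_target = total_target - int(fixed.sum())
    if cap_target <= 0:
        return np.zeros_like(mesh2d)

    # secant iteration on the cell count: fraction ~ sqrt(n_points)
    for _ in range(6):
        frac = mesh2d.sum() / (side * side)
        goal = cap_target / (side * side)
        if abs(frac - goal) < 0.01 or frac <= 0:
            break
        n_points = int(np.clip(n_points * (goal / frac) ** 2,
                               4, 0.2 * side * side))
        mesh2d = _tube_mesh(seed_base, side, n_points, forbidden) & available

    n_mesh = int(mesh2d.sum())
    if n_mesh > cap_target:
        # peel boundary pixels (largest distance from the skeleton first)
        dist_in = ndimage.distance_transform_edt(mesh2d)
        cand = np.flatnonzero(mesh2d.ravel())
        key = -dist_in.ravel()[cand] + rng.random(cand.size) * 1e-6
        drop = cand[np.argsort(key)[: n_mesh - cap_target]]
        out = mesh2d.copy().ravel()
        out[drop] = False
        return out.reshape(side, side)
    if n_mesh < cap_target:
        # annex the nearest available boundary pixels
        dist = ndimage.distance_transform_edt(~mesh2d)
        cand = np.flatnonzero(available.ravel() & ~mesh2d.ravel())
        key = dist.ravel()[cand] + rng.random(cand.size) * 1e-6
        need = min(cap_target - n_mesh, cand.size)
        out = mesh2d.copy().ravel()
        out[cand[np.argsort(key)[:need]]] = True
        return out.reshape(side, side)
    return mesh2d


# ---------------------------------------------------------------------------
# large vessels

def _trace_vessel(rng: np.random.Generator, side: int, start: np.ndarray,
                  heading: float, faz_center: float, faz_stop: float
                  ) -> np.ndarray:
    """Random-walk centerline from the border toward the macula."""
    pos = start.astype(float)
    pts = [pos.copy()]
    step = 1.0
    drift = rng.uniform(-0.05, 0.05)
    for _ in range(4 * side):
        heading += drift + rng.normal(0, 0.06)
        pos = pos + step * np.array([math.cos(heading), math.sin(heading)])
        if not (0 <= pos[0] < side and 0 <= pos[1] < side):
            break
        if math.hypot(pos[0] - faz_center, pos[1] - faz_center) < faz_stop:
            break
        pts.append(pos.copy())
    return np.array(pts)


def _render_vessels(rng: np.random.Generator, params: PhantomParams,
                    faz_center: float, faz_r_px: float) -> np.ndarray:
    side = params.side
    vessels = np.zeros((side, side), dtype=bool)
    if params.large_vessel_count == 0:
        return vessels
    pitch = params.pixel_pitch_um
    lo, hi = params.vessel_width_um
    centerlines: List[Tuple[np.ndarray, float]] = []
    for k in range(params.large_vessel_count):
        # enter from a random border point, aim broadly at the center
        edge = rng.integers(4)
        t = rng.uniform(0, side)
        start = {0: (0.0, t), 1: (side - 1.0, t),
                 2: (t, 0.0), 3: (t, side - 1.0)}[int(edge)]
        start = np.array(start)
        # coordinates are (row, col); heading is atan2(d_col, d_row)
        heading = math.atan2(faz_center - start[1], faz_center - start[0]) + rng.uniform(-0.4, 0.4)
        width_px = max(4.0, rng.uniform(lo, hi) / pitch)
        path = _trace_vessel(rng, side, start, heading, faz_center, 1.6 * faz_r_px)
        if len(path) < 8:
            continue
        centerlines.append((path, width_px))
        if rng.random() < 0.5:  # one side branch
            i = rng.integers(len(path) // 3, max(len(path) // 3 + 1, 2 * len(path) // 3))
            bpath = _trace_vessel(
                rng, side, path[int(i)],
                heading + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.1),
                faz_center, 1.6 * faz_r_px)
            if len(bpath) >= 8:
                centerlines.append((bpath, max(4.0, 0.7 * width_px)))
    budget = params.max_vessel_fraction * side * side
    for path, width_px in centerlines:
        canvas = np.ones((side, side), dtype=bool)
        rr = np.clip(np.round(path[:, 0]).astype(int), 0, side - 1)
        cc = np.clip(np.round(path[:, 1]).astype(int), 0, side - 1)
        canvas[rr, cc] = False
        dist = ndimage.distance_transform_edt(canvas)
        candidate = vessels | (dist <= width_px / 2.0)
        if candidate.sum() > budget and vessels.any():
            break  # arcade coverage is anatomically bounded
        vessels = candidate
    return vessels


# ---------------------------------------------------------------------------

def generate_phantom(seed: int, params: Optional[PhantomParams] = None
                     ) -> SubjectPhantom:
    """Generate one synthetic subject, deterministically for a given seed.

    Parameters
    ----------
    seed : int
        Seed for all stochastic structure of this subject.
    params : PhantomParams, optional
        Geometry; defaults are a plausible healthy macula at a 6 x 6 mm
        field (SCP flow fraction ~0.34, DCP ~0.38, CC flow ~0.75).
    """
    params = params or PhantomParams()
    side = params.side
    rng = np.random.default_rng(np.random.SeedSequence([0x0C7A, int(seed)]))

    pitch = params.pixel_pitch_um
    faz_r_px = params.faz_radius_um / pitch
    center = (side - 1) / 2.0
    rr, cc = np.mgrid[0:side, 0:side]
    ry = faz_r_px * rng.uniform(0.85, 1.15)
    rx = faz_r_px * rng.uniform(0.85, 1.15)
    faz = (((rr - center) / ry) ** 2 + ((cc - center) / rx) ** 2) <= 1.0

    vessels = _render_vessels(rng, params, center, faz_r_px) & ~faz

    scp_cap = _mesh_with_fraction(
        rng, side, params.scp_capillary_density,
        forbidden=faz, fixed=vessels,
        target_fraction=params.scp_target_fraction) & ~vessels
    dcp_cap = _mesh_with_fraction(
        rng, side, params.dcp_capillary_density,
        forbidden=faz, fixed=np.zeros_like(faz),
        target_fraction=params.dcp_target_fraction)

    # coherent perfusion heterogeneity: capillary amplitude 0.15..0.85 of a
    # large vessel, varying over ~8 px patches; the dim tail is what fades
    # first when the illumination is attenuated
    def _brightness(cap_map: np.ndarray) -> np.ndarray:
        f = ndimage.gaussian_filter(rng.standard_normal((side, side)), 8.0)
        lo_, hi_ = f.min(), f.max()
        u = (f - lo_) / (hi_ - lo_) if hi_ > lo_ else np.zeros_like(f)
        return (0.15 + 0.7 * u) * cap_map

    scp_brightness = _brightness(scp_cap)
    dcp_brightness = _brightness(dcp_cap)

    cc_side = params.cc_side
    if params.scp_capillary_density > 0 or params.dcp_capillary_density > 0:
        field_ = ndimage.gaussian_filter(
            rng.standard_normal((cc_side, cc_side)),
            params.cc_texture_sigma_px)
        q = np.quantile(field_, 1.0 - params.cc_flow_fraction)
        cc_flow = field_ > q
        lo, hi = field_.min(), field_.max()
        u = (field_ - lo) / (hi - lo) if hi > lo else np.zeros_like(field_)
        # bright ground-glass flow pixels vs dark intercapillary spaces
        cc_texture = np.where(cc_flow, 0.85 + 0.15 * u, 0.10 + 0.25 * u)
    else:
        cc_flow = np.zeros((cc_side, cc_side), dtype=bool)
        cc_texture = np.zeros((cc_side, cc_side), dtype=float)

    phantom = SubjectPhantom(
        seed=int(seed),
        params=params,
        large_vessel_map=vessels,
        scp_capillary_map=scp_cap,
        dcp_capillary_map=dcp_cap,
        faz_mask=faz,
        cc_flow_map=cc_flow,
        cc_texture=cc_texture,
        scp_capillary_brightness=scp_brightness,
        dcp_capillary_brightness=dcp_brightness,
        truth_fractions={
            "SCP": float((scp_cap | vessels).mean()),
            "DCP": float(dcp_cap.mean()),
            "CC": float(cc_flow.mean()),
        },
    )
    phantom.validate()
    return phantom
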