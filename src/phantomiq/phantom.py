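"""Digital structured cardiac phantom: analytic geometry and voxelization.

The phantom emulates a thorax section for coronary CT angiography image
quality work: an elliptical 30 x 20 cm body of soft tissue containing
hollow lungs, plaster-like ribs and a vertebra, a contrast-filled left
ventricle surrounded by myocardium, coronary arteries of 1.0-4.0 mm
diameter running through the myocardium (one with a 70% diameter
stenosis, one carrying a stent), and a slanted-plane contrast wedge used
for through-plane resolution measurements.  Iodinated spaces are filled
with dilute contrast (18 mgI/ml, fixed at 424 HU).

Every structure is defined by a signed-distance function (negative
inside).  Voxelization mixes material HU at boundaries in proportion to
voxel occupancy, either by a linear signed-distance ramp one voxel wide
(fast, volume conserving; the default) or by per-axis supersampled
point-in-solid counting (the reference oracle, practical on small grids).
The analytic geometry is retained alongside the volume as ground truth
for every downstream measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

from .resolution import CircularEdge, EdgeSpec, PlanarEdge
from .volume import Grid, VoxelVolume

# -- material table ----------------------------------------------------------

AIR_HU = -1000.0
SOFT_TISSUE_HU = 40.0
MYOCARDIUM_HU = 40.0
BONE_HU = 700.0
CONTRAST_HU = 424.0
STENT_HU = 1900.0


# -- component specs ---------------------------------------------------------


@dataclass(frozen=True)
class StenosisSpec:
    """Smooth focal diameter reduction along a vessel.

    ``severity`` is a diameter fraction: at the lesion centre the true
    diameter is ``(1 - severity)`` times the reference diameter, tapering
    to the reference with a raised-cosine profile over ``length_mm``.
    """

    s_center: float
    severity: float = 0.70
    length_mm: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 < self.severity < 1.0):
            raise ValueError("stenosis severity must be in (0, 1)")
        if self.length_mm <= 0:
            raise ValueError("stenosis length must be positive")

    def diameter_factor(self, s: np.ndarray) -> np.ndarray:
        u = (np.asarray(s, dtype=float) - self.s_center) / (self.length_mm / 2.0)
        bump = np.where(np.abs(u) < 1.0, 0.5 * (1.0 + np.cos(np.pi * np.clip(u, -1, 1))), 0.0)
        return 1.0 - self.severity * bump


@dataclass(frozen=True)
class VesselSpec:
    """A coronary artery as a centerline polyline with a diameter profile."""

    label: str
    centerline: np.ndarray  # (N, 3) world mm
    diameter_mm: float | np.ndarray  # scalar or per-point
    stenosis: StenosisSpec | None = None

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if pts.shape[0] < 2 or pts.shape[1] != 3:
            raise ValueError(f"vessel {self.label!r}: centerline needs >= 2 3-D points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError(f"vessel {self.label!r}: arc length must be strictly increasing")
        object.__setattr__(self, "centerline", pts)
        d = np.asarray(self.diameter_mm, dtype=float)
        if np.any(d <= 0):
            raise ValueError(f"vessel {self.label!r}: diameters must be positive")
        if np.any(d < 1.0 - 1e-9) or np.any(d > 4.0 + 1e-9):
            raise ValueError(
                f"vessel {self.label!r}: nominal diameters must lie in [1.0, 4.0] mm"
            )


@dataclass(frozen=True)
class StentSpec:
    """A stent modelled as a dense metal sleeve on the vessel wall.

    The struts are homogenised into a cylindrical shell whose outer radius
    is the vessel wall and whose radial thickness is ``strut_thickness_mm``
    (struts protrude into the lumen, as deployed stent struts do).  An
    optional ring pattern (``ring_count`` rings of axial width
    ``ring_width_mm``) replaces the continuous sleeve.
    """

    vessel_label: str
    s_center: float
    length_mm: float
    nominal_diameter_mm: float
    strut_hu: float = STENT_HU
    strut_thickness_mm: float = 0.4
    ring_count: int | None = None
    ring_width_mm: float = 0.3

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.strut_thickness_mm <= 0:
            raise ValueError("stent dimensions must be positive")

    @property
    def s_start(self) -> float:
        return self.s_center - self.length_mm / 2.0

    @property
    def s_end(self) -> float:
        return self.s_center + self.length_mm / 2.0


@dataclass(frozen=True)
class EllipseRegion:
    center_xy: tuple[float, float]
    semi_axes: tuple[float, float]


@dataclass(frozen=True)
class BoneElement:
    label: str
    center_xy: tuple[float, float]
    radius: float
    hu: float = BONE_HU


@dataclass(frozen=True)
class WedgeSpec:
    """Contrast block whose top surface is a plane tilted to the axial plane."""

    center_xy: tuple[float, float]
    footprint_mm: float = 16.0
    tilt_deg: float = 30.0
    z_plane: float = 0.0
    z_bottom: float = -14.0

    def __post_init__(self) -> None:
        if not (0.0 < self.tilt_deg <= 30.0):
            raise ValueError("wedge tilt must be in (0, 30] degrees")


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of the digital phantom (world mm, HU)."""

    body_axes: tuple[float, float] = (300.0, 200.0)  # outer ellipse diameters
    body_center: tuple[float, float] = (0.0, 0.0)
    lungs: tuple[EllipseRegion, ...] = (
        EllipseRegion((-60.0, 0.0), (18.0, 45.0)),
        EllipseRegion((60.0, 0.0), (18.0, 45.0)),
    )
    bones: tuple[BoneElement, ...] = (
        BoneElement("vertebra", (0.0, -62.0), 10.0),
        BoneElement("rib-l1", (-60.0, 55.0), 5.0),
        BoneElement("rib-r1", (60.0, 55.0), 5.0),
        BoneElement("rib-l2", (-75.0, 0.0), 5.0),
        BoneElement("rib-r2", (75.0, 0.0), 5.0),
        BoneElement("rib-l3", (-60.0, -55.0), 5.0),
        BoneElement("rib-r3", (60.0, -55.0), 5.0),
    )
    heart_center: tuple[float, float] = (0.0, 0.0)
    ventricle_radius: float = 30.0
    myocardium_outer_radius: float = 40.0
    vessels: tuple[VesselSpec, ...] = ()
    stent: StentSpec | None = None
    wedge: WedgeSpec | None = WedgeSpec(center_xy=(0.0, 54.0))
    contrast_hu: float = CONTRAST_HU
    soft_tissue_hu: float = SOFT_TISSUE_HU
    myocardium_hu: float = MYOCARDIUM_HU
    bone_hu: float = BONE_HU
    air_hu: float = AIR_HU
    iodine_mg_per_ml: float = 18.0

    def __post_init__(self) -> None:
        if self.body_axes[0] <= 0 or self.body_axes[1] <= 0:
            raise ValueError("body axes must be positive")
        if not (self.contrast_hu > self.myocardium_hu > self.air_hu):
            raise ValueError("need contrast HU > myocardium HU > lung/air HU")
        if self.stent is not None:
            if self.stent.strut_hu <= self.contrast_hu:
                raise ValueError("stent strut HU must exceed the contrast HU")
            if self.stent.vessel_label not in {v.label for v in self.vessels}:
                raise ValueError(f"stent vessel {self.stent.vessel_label!r} not found")

    def vessel(self, label: str) -> VesselSpec:
        for v in self.vessels:
            if v.label == label:
                return v
        raise KeyError(f"no vessel labelled {label!r}")


# -- vessel geometry ---------------------------------------------------------


class VesselGeometry:
    """Arc-length parameterised centerline with the true diameter profile."""

    def __init__(self, spec: VesselSpec):
        self.spec = spec
        pts = spec.centerline
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self.arc = np.concatenate([[0.0], np.cumsum(seg)])
        self.points = pts
        d = np.asarray(spec.diameter_mm, dtype=float)
        self._diam = np.full(len(pts), float(d)) if d.ndim == 0 else d

    @property
    def label(self) -> str:
        return self.spec.label

    @property
    def length(self) -> float:
        return float(self.arc[-1])

    def point_at(self, s) -> np.ndarray:
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        return np.stack(
            [np.interp(s, self.arc, self.points[:, k]) for k in range(3)], axis=-1
        )

    def tangent_at(self, s: float) -> np.ndarray:
        i = int(np.clip(np.searchsorted(self.arc, s) - 1, 0, len(self.arc) - 2))
        t = self.points[i + 1] - self.points[i]
        return t / np.linalg.norm(t)

    def reference_diameter_at(self, s) -> np.ndarray:
        return np.interp(np.asarray(s, dtype=float), self.arc, self._diam)

    def diameter_at(self, s) -> np.ndarray:
        """True local diameter, including the stenosis reduction."""
        d = self.reference_diameter_at(s)
        if self.spec.stenosis is not None:
            d = d * self.spec.stenosis.diameter_factor(s)
        return d

    def densified(self, pitch: float) -> tuple[np.ndarray, np.ndarray]:
        """Centerline resampled at <= ``pitch`` arc-length steps."""
        n = max(int(np.ceil(self.length / pitch)) + 1, 2)
        s = np.linspace(0.0, self.length, n)
        return s, self.point_at(s)


@dataclass
class PhantomTruth:
    """Analytic ground truth: the spec plus derived measurement geometry."""

    spec: PhantomSpec
    vessels: dict[str, VesselGeometry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.vessels:
            self.vessels = {v.label: VesselGeometry(v) for v in self.spec.vessels}

    def ventricle_edge(self, z_range: tuple[float, float],
                       band_halfwidth: float = 2.5) -> EdgeSpec:
        """Circular ventricle/myocardium boundary for in-plane MTF."""
        return EdgeSpec(
            geometry=CircularEdge(self.spec.heart_center,
                                  self.spec.ventricle_radius, z_range),
            band_halfwidth=band_halfwidth,
            contrast=(self.spec.contrast_hu, self.spec.myocardium_hu),
        )

    def z_edge(self, band_halfwidth: float = 2.0,
               footprint_margin: float = 2.0) -> EdgeSpec:
        """Slanted-plane edge (<= 30 deg to axial) for Z-direction MTF."""
        w = self.spec.wedge
        if w is None:
            raise ValueError("phantom has no wedge structure")
        t = math.radians(w.tilt_deg)
        half = w.footprint_mm / 2.0 - footprint_margin
        cx, cy = w.center_xy
        geom = PlanarEdge(
            point=(cx, cy, w.z_plane),
            normal=(-math.sin(t), 0.0, math.cos(t)),
            footprint=((cx - half, cx + half), (cy - half, cy + half)),
        )
        return EdgeSpec(geometry=geom, band_halfwidth=band_halfwidth,
                        contrast=(self.spec.contrast_hu, self.spec.soft_tissue_hu))


# -- signed-distance fields --------------------------------------------------


def _ellipse_sdf(x, y, center, semi_axes):
    """Approximate signed distance to an ellipse (exact on axes)."""
    a, b = semi_axes
    u, v = x - center[0], y - center[1]
    f = np.hypot(u / a, v / b) - 1.0
    g = np.hypot(u / a**2, v / b**2)
    return f / np.maximum(g, 1e-9)


def _circle_sdf(x, y, center, radius):
    return np.hypot(x - center[0], y - center[1]) - radius


@dataclass
class _Structure:
    name: str
    hu: float
    sdf: Callable  # sdf(x, y, z) broadcastable
    z_invariant: bool
    bounds: tuple[tuple[float, float], ...] | None = None  # world bbox or None


def _tube_sdf_factory(geom: VesselGeometry, s_range: tuple[float, float] | None = None,
                      radius_fn: Callable | None = None,
                      shell: tuple[float, float] | None = None):
    """SDF of a varying-radius tube (or cylindrical shell) around a centerline.

    ``radius_fn(s)`` defaults to the true vessel radius.  ``shell`` gives
    (inner, outer) radial offsets relative to the centerline for stent
    sleeves; ``s_range`` restricts the tube to an arc-length interval.
    """
    pts = geom.points
    arc = geom.arc
    if radius_fn is None:
        radius_fn = lambda s: geom.diameter_at(s) / 2.0

    # densify curved centerlines so per-segment closest points are accurate
    if len(pts) > 2 or geom.spec.stenosis is not None:
        s_f, p_f = geom.densified(0.25)
    else:
        s_f, p_f = arc, pts

    def sdf(x, y, z):
        shape = np.broadcast_shapes(np.shape(x), np.shape(y), np.shape(z))
        p = np.empty(shape + (3,))
        p[..., 0], p[..., 1], p[..., 2] = x, y, z
        best = np.full(shape, np.inf)
        best_s = np.zeros(shape)
        best_r = np.zeros(shape)
        for i in range(len(p_f) - 1):
            a, b = p_f[i], p_f[i + 1]
            ab = b - a
            ab2 = float(ab @ ab)
            t = np.clip(((p - a) @ ab) / ab2, 0.0, 1.0)
            closest = a + t[..., None] * ab
            radial = np.linalg.norm(p - closest, axis=-1)
            s_here = s_f[i] + t * (s_f[i + 1] - s_f[i])
            closer = radial < best
            best = np.where(closer, radial, best)
            best_s = np.where(closer, s_here, best_s)
            best_r = np.where(closer, radial, best_r)
        r_local = radius_fn(best_s)
        if shell is None:
            d = best_r - r_local
        else:
            inner, outer = shell
            mid = (inner + outer) / 2.0
            half = (outer - inner) / 2.0
            d = np.abs(best_r - mid) - half
        if s_range is not None:
            # cap the tube at the arc-length interval ends
            cap = np.maximum(s_range[0] - best_s, best_s - s_range[1])
            d = np.maximum(d, cap)
        return d

    return sdf


def _phantom_structures(spec: PhantomSpec, truth: PhantomTruth,
                        include_stent: bool = True) -> list[_Structure]:
    """Painting order = material priority (later paints over earlier)."""
    out: list[_Structure] = []
    out.append(_Structure(
        "body", spec.soft_tissue_hu,
        lambda x, y, z: _ellipse_sdf(x, y, spec.body_center,
                                     (spec.body_axes[0] / 2, spec.body_axes[1] / 2)),
        z_invariant=True))
    for i, lung in enumerate(spec.lungs):
        out.append(_Structure(
            f"lung-{i}", spec.air_hu,
            lambda x, y, z, L=lung: _ellipse_sdf(x, y, L.center_xy, L.semi_axes),
            z_invariant=True))
    for bone in spec.bones:
        out.append(_Structure(
            bone.label, bone.hu,
            lambda x, y, z, B=bone: _circle_sdf(x, y, B.center_xy, B.radius),
            z_invariant=True,
            bounds=((bone.center_xy[0] - bone.radius - 1, bone.center_xy[0] + bone.radius + 1),
                    (bone.center_xy[1] - bone.radius - 1, bone.center_xy[1] + bone.radius + 1),
                    (-np.inf, np.inf))))
    out.append(_Structure(
        "myocardium", spec.myocardium_hu,
        lambda x, y, z: _circle_sdf(x, y, spec.heart_center, spec.myocardium_outer_radius),
        z_invariant=True))
    out.append(_Structure(
        "ventricle", spec.contrast_hu,
        lambda x, y, z: _circle_sdf(x, y, spec.heart_center, spec.ventricle_radius),
        z_invariant=True))
    if spec.wedge is not None:
        w = spec.wedge
        t = math.radians(w.tilt_deg)
        n = np.array([-math.sin(t), 0.0, math.cos(t)])
        half = w.footprint_mm / 2.0
        cx, cy = w.center_xy

        def wedge_sdf(x, y, z, n=n, cx=cx, cy=cy, w=w, half=half):
            d_plane = (x - cx) * n[0] + (y - cy) * n[1] + (z - w.z_plane) * n[2]
            d_box = np.maximum(
                np.maximum(np.abs(x - cx) - half, np.abs(y - cy) - half),
                w.z_bottom - z,
            )
            return np.maximum(d_plane, d_box)

        zmax = w.z_plane + math.tan(t) * half + 1.0
        out.append(_Structure(
            "wedge", spec.contrast_hu, wedge_sdf, z_invariant=False,
            bounds=((cx - half - 1, cx + half + 1), (cy - half - 1, cy + half + 1),
                    (w.z_bottom - 1, zmax))))
    for v in spec.vessels:
        geom = truth.vessels[v.label]
        margin = float(np.max(np.atleast_1d(v.diameter_mm))) / 2.0 + 1.5
        lo = geom.points.min(axis=0) - margin
        hi = geom.points.max(axis=0) + margin
        out.append(_Structure(
            f"vessel-{v.label}", spec.contrast_hu, _tube_sdf_factory(geom),
            z_invariant=False,
            bounds=tuple((lo[k], hi[k]) for k in range(3))))
    if include_stent and spec.stent is not None:
        out.append(_stent_structure(spec, truth))
    return out


def _stent_structure(spec: PhantomSpec, truth: PhantomTruth) -> _Structure:
    st = spec.stent
    geom = truth.vessels[st.vessel_label]
    r_outer = st.nominal_diameter_mm / 2.0
    r_inner = r_outer - st.strut_thickness_mm
    base = _tube_sdf_factory(geom, s_range=(st.s_start, st.s_end),
                             shell=(r_inner, r_outer))
    if st.ring_count:
        pitch = st.length_mm / st.ring_count
        halfw = st.ring_width_mm / 2.0

        def ring_sdf(x, y, z, base=base, st=st, pitch=pitch, halfw=halfw):
            d = base(x, y, z)
            # distance along z to the nearest ring plane (vessels run ~axially)
            zz = np.asarray(z) - (st.s_center - st.length_mm / 2 + pitch / 2)
            off = np.abs(((zz + pitch / 2) % pitch) - pitch / 2) - halfw
            return np.maximum(d, off)

        sdf = ring_sdf
    else:
        sdf = base
    lo = geom.point_at(st.s_start) - r_outer - 1.5
    hi = geom.point_at(st.s_end) + r_outer + 1.5
    return _Structure(
        "stent", st.strut_hu, sdf, z_invariant=False,
        bounds=tuple((min(lo[k], hi[k]), max(lo[k], hi[k])) for k in range(3)))


def add_stent(
    volume: VoxelVolume,
    spec: PhantomSpec,
    truth: PhantomTruth,
    method: Literal["sdf", "supersample"] = "sdf",
    supersample: int = 5,
) -> VoxelVolume:
    """Paint the stent sleeve onto a copy of a stent-free phantom volume."""
    if spec.stent is None:
        return volume.copy()
    out = volume.copy()
    st = _stent_structure(spec, truth)
    region = _region_slices(out.grid, st.bounds)
    if region is None:
        return out
    occ = occupancy_from_sdf(st.sdf, out.grid, method=method,
                             supersample=supersample, region=region)
    target = out.values[region]
    target *= 1.0 - occ
    target += out.values.dtype.type(st.hu) * occ
    return out


# -- voxelization ------------------------------------------------------------


def occupancy_from_sdf(
    sdf: Callable,
    grid: Grid,
    method: Literal["sdf", "supersample"] = "sdf",
    supersample: int = 5,
    aa_width: float | None = None,
    region: tuple[slice, slice, slice] | None = None,
) -> np.ndarray:
    """Voxel occupancy of the solid ``sdf(x,y,z) < 0`` on a grid region.

    ``"sdf"`` maps signed distance through a linear ramp of width
    ``aa_width`` (default: the smallest voxel spacing), which conserves
    volume to first order.  ``"supersample"`` counts ``supersample``^3
    sub-voxel points inside the solid for boundary voxels — the slow,
    assumption-free reference.
    """
    if region is None:
        region = (slice(None), slice(None), slice(None))
    coords = [grid.axis_coords(a)[region[a]] for a in range(3)]
    X = coords[0][:, None, None]
    Y = coords[1][None, :, None]
    Z = coords[2][None, None, :]
    d = np.asarray(sdf(X, Y, Z), dtype=np.float64)
    d = np.broadcast_to(d, (len(coords[0]), len(coords[1]), len(coords[2]))).copy()

    h = min(grid.spacing) if aa_width is None else aa_width
    if method == "sdf":
        return np.clip(0.5 - d / h, 0.0, 1.0).astype(np.float32)
    if method != "supersample":
        raise ValueError(f"unknown antialiasing method {method!r}")

    half_diag = 0.5 * math.sqrt(sum(s * s for s in grid.spacing))
    occ = (d < 0).astype(np.float32)
    edge = np.abs(d) <= half_diag
    if edge.any():
        ii = np.nonzero(edge)
        px = coords[0][ii[0]]
        py = coords[1][ii[1]]
        pz = coords[2][ii[2]]
        n = supersample
        offs = (np.arange(n) + 0.5) / n - 0.5
        counts = np.zeros(px.shape, dtype=np.int64)
        for ox in offs:
            for oy in offs:
                for oz in offs:
                    dd = sdf(px + ox * grid.spacing[0],
                             py + oy * grid.spacing[1],
                             pz + oz * grid.spacing[2])
                    counts += (np.asarray(dd) < 0).astype(np.int64)
        occ[ii] = counts / float(n**3)
    return occ


def _region_slices(grid: Grid, bounds) -> tuple[slice, slice, slice] | None:
    sl = []
    for ax in range(3):
        coords = grid.axis_coords(ax)
        lo, hi = bounds[ax]
        inside = np.nonzero((coords >= lo) & (coords <= hi))[0]
        if inside.size == 0:
            return None
        sl.append(slice(int(inside[0]), int(inside[-1]) + 1))
    return tuple(sl)


def rasterize_tube(
    centerline: np.ndarray,
    diameter_mm: float | np.ndarray,
    grid: Grid,
    method: Literal["sdf", "supersample"] = "sdf",
    supersample: int = 5,
    stenosis: StenosisSpec | None = None,
) -> np.ndarray:
    """Occupancy field of a (possibly stenosed) tube on a grid, in [0, 1]."""
    spec = VesselSpec("tube", np.asarray(centerline, dtype=float), diameter_mm,
                      stenosis=stenosis)
    geom = VesselGeometry(spec)
    return occupancy_from_sdf(_tube_sdf_factory(geom), grid,
                              method=method, supersample=supersample)


def _validate_geometry(spec: PhantomSpec, truth: PhantomTruth, grid: Grid) -> None:
    min_radius = min(
        float(np.min(np.atleast_1d(v.diameter_mm))) / 2.0 for v in spec.vessels
    ) if spec.vessels else np.inf
    if max(grid.spacing[:2]) > min_radius:
        raise ValueError(
            f"grid spacing {max(grid.spacing[:2]):.3f} mm is coarser than the "
            f"smallest vessel radius {min_radius:.3f} mm"
        )
    a, b = spec.body_axes[0] / 2.0, spec.body_axes[1] / 2.0
    hx, hy = spec.heart_center
    r_heart = spec.myocardium_outer_radius
    for v in spec.vessels:
        geom = truth.vessels[v.label]
        s, pts = geom.densified(1.0)
        radii = geom.reference_diameter_at(s) / 2.0
        body = np.hypot((pts[:, 0] - spec.body_center[0]) / a,
                        (pts[:, 1] - spec.body_center[1]) / b)
        if np.any(body >= 1.0):
            raise ValueError(f"vessel {v.label!r} leaves the phantom body")
        inside_heart = np.hypot(pts[:, 0] - hx, pts[:, 1] - hy) + radii
        if np.any(inside_heart > r_heart + 1e-6):
            raise ValueError(f"vessel {v.label!r} leaves the heart region")
    if spec.stent is not None:
        geom = truth.vessels[spec.stent.vessel_label]
        if spec.stent.s_start < -1e-9 or spec.stent.s_end > geom.length + 1e-9:
            raise ValueError("stent segment extends beyond its vessel")


def build_digital_phantom(
    spec: PhantomSpec,
    grid: Grid,
    method: Literal["sdf", "supersample"] = "sdf",
    supersample: int = 5,
    include_stent: bool = True,
    dtype=np.float32,
) -> tuple[VoxelVolume, PhantomTruth]:
    """Voxelize the phantom and return the volume with its analytic truth.

    Materials are painted in priority order (stent over vessel lumen over
    heart over bone over soft tissue over air) with occupancy-weighted HU
    mixing at boundaries.  ``include_stent=False`` builds the stent-free
    model used as ground truth for lumen-width scoring.
    """
    truth = PhantomTruth(spec=spec)
    _validate_geometry(spec, truth, grid)

    vol = np.full(grid.shape, spec.air_hu, dtype=dtype)
    for st in _phantom_structures(spec, truth, include_stent=include_stent):
        region = None
        if st.bounds is not None:
            region = _region_slices(grid, st.bounds)
            if region is None:
                continue  # structure entirely outside the grid
        if st.z_invariant:
            # evaluate the 2-D occupancy once and broadcast along z
            sub = region or (slice(None),) * 3
            g2 = (sub[0], sub[1], slice(0, 1))
            occ = occupancy_from_sdf(st.sdf, grid, method=method,
                                     supersample=supersample, region=g2)[:, :, 0]
            target = vol[sub[0], sub[1], :]
            target *= 1.0 - occ[:, :, None]
            target += dtype(st.hu) * occ[:, :, None]
        else:
            sub = region or (slice(None),) * 3
            occ = occupancy_from_sdf(st.sdf, grid, method=method,
                                     supersample=supersample, region=sub)
            target = vol[sub]
            target *= 1.0 - occ
            target += dtype(st.hu) * occ
    return VoxelVolume(vol, grid), truth


# -- default study phantom ---------------------------------------------------

MODEL_MATRIX = 1024
MODEL_FOV_MM = 160.0
MODEL_SLICE_INTERVAL = 0.25


def default_model_grid(z_extent_mm: float = 32.0) -> Grid:
    """Ground-truth grid: 1024 matrix over a 160 mm FoV, 0.25 mm slices."""
    nz = int(round(z_extent_mm / MODEL_SLICE_INTERVAL)) + 1
    px = MODEL_FOV_MM / MODEL_MATRIX
    return Grid.centered((MODEL_MATRIX, MODEL_MATRIX, nz),
                         (px, px, MODEL_SLICE_INTERVAL))


def _straight_vessel(label: str, angle_deg: float, diameter: float,
                     z_extent: float, ring_radius: float = 35.0,
                     stenosis: StenosisSpec | None = None) -> VesselSpec:
    a = math.radians(angle_deg)
    x, y = ring_radius * math.cos(a), ring_radius * math.sin(a)
    half = z_extent / 2.0
    line = np.array([[x, y, -half], [x, y, half]])
    return VesselSpec(label, line, diameter, stenosis=stenosis)


def default_phantom_spec(z_extent_mm: float = 32.0,
                         stent_length_mm: float = 15.0) -> PhantomSpec:
    """The standard study phantom.

    Four straight coronary segments (3.2 mm normal, 1.3 mm with a 70%
    stenosis, 3.0 mm carrying the stent, 1.0 mm plain) run axially through
    the myocardium at 35 mm from the heart centre, plus one gently curved
    4.0 mm segment; the stent sleeve is 15 mm long (BeStent-like 3.0 mm
    device).  Vessel z-extent follows the phantom z-extent.
    """
    half = z_extent_mm / 2.0
    zc = np.linspace(-half, half, 33)
    curved = np.stack([2.0 * np.sin(np.pi * zc / z_extent_mm),
                       np.full_like(zc, -35.0), zc], axis=1)
    vessels = (
        _straight_vessel("normal-3.2", 0.0, 3.2, z_extent_mm),
        _straight_vessel("stenotic-1.3", 90.0, 1.3, z_extent_mm,
                         stenosis=StenosisSpec(s_center=z_extent_mm / 2.0)),
        _straight_vessel("stented-3.0", 180.0, 3.0, z_extent_mm),
        _straight_vessel("small-1.0", 45.0, 1.0, z_extent_mm),
        VesselSpec("curved-4.0", curved, 4.0),
    )
    stent = StentSpec(
        vessel_label="stented-3.0",
        s_center=z_extent_mm / 2.0,
        length_mm=stent_length_mm,
        nominal_diameter_mm=3.0,
    )
    return PhantomSpec(vessels=vessels, stent=stent)
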