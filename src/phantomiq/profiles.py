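"""Vessel profile curves and width metrics along coronary centerlines.

A profile curve samples the volume along a line orthogonal to the vessel
centerline at a given arc length, by trilinear interpolation at a pitch
of a quarter pixel.  Widths are read off the profile against thresholds
defined as fractions of the *digital model's* peak CT number: W_90% and
W_10% for vessels, and for stents the lumen width W_lumen at the 110%
threshold between the two strut peaks (stent blooming narrows, and can
close, that interval).  All width crossings are located by sub-sample
linear interpolation, and percent errors are computed from unrounded
values and rounded last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .phantom import PhantomTruth
from .volume import VoxelVolume


@dataclass
class ProfileCurve:
    """HU samples along a line orthogonal to a centerline.

    positions are mm offsets from the centerline (symmetric about 0) at a
    uniform pitch.
    """

    positions: np.ndarray
    values: np.ndarray
    pitch: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.size != self.values.size:
            raise ValueError("positions and values must have equal length")

    @property
    def peak(self) -> float:
        return float(self.values.max())

    def central_peak(self, center_fraction: float = 0.5) -> float:
        """Maximum within the central fraction of the sampled extent.

        Long profiles can end inside bright neighbouring structures; the
        vessel's own peak is always the one near the centerline.
        """
        half = center_fraction * float(np.abs(self.positions).max())
        keep = np.abs(self.positions) <= max(half, self.pitch)
        return float(self.values[keep].max())

    def resampled(self, positions: np.ndarray) -> "ProfileCurve":
        pos = np.asarray(positions, dtype=float)
        vals = np.interp(pos, self.positions, self.values)
        return ProfileCurve(pos, vals, float(pos[1] - pos[0]))


@dataclass
class WidthMetrics:
    """Profile-curve summary against the digital model truth.

    Widths are in mm; a width of 0 means the threshold was never reached.
    ``errors`` maps metric name -> percent error vs the model (absent for
    model widths that are zero).
    """

    peak_ct: float
    w10: float
    w90: float
    model_peak: float
    model_w10: float
    model_w90: float
    errors: dict[str, float | None]


def _profile_frame(truth: PhantomTruth, vessel_label: str, s: float):
    geom = truth.vessels[vessel_label]
    if not (0.0 <= s <= geom.length):
        raise ValueError(
            f"arc length {s} outside vessel {vessel_label!r} extent [0, {geom.length:.2f}]"
        )
    center = geom.point_at(s)
    tangent = geom.tangent_at(s)
    ez = np.array([0.0, 0.0, 1.0])
    normal = np.cross(tangent, ez)
    if np.linalg.norm(normal) < 1e-6:  # axial vessel: use +x
        normal = np.array([1.0, 0.0, 0.0])
    normal = normal / np.linalg.norm(normal)
    return geom, center, tangent, normal


def extract_profile(
    volumes: VoxelVolume | Sequence[VoxelVolume],
    truth: PhantomTruth,
    vessel_label: str,
    s: float,
    pitch: float | None = None,
    extent_factor: float = 4.0,
    min_extent_mm: float = 8.0,
    s_window_mm: float = 0.0,
    n_lines: int = 1,
) -> ProfileCurve:
    """Sample the orthogonal profile at arc length ``s`` of a vessel.

    ``pitch`` defaults to a quarter of the in-plane pixel; the profile
    extends ``extent_factor`` times the local reference diameter (at least
    ``min_extent_mm``) either side of the centerline.  With ``n_lines > 1``
    profiles at ``n_lines`` arc positions spread over ``s_window_mm`` are
    averaged; a sequence of repeat volumes is likewise averaged.
    """
    if isinstance(volumes, VoxelVolume):
        volumes = [volumes]
    grid = volumes[0].grid
    for v in volumes[1:]:
        if v.grid != grid:
            raise ValueError("repeat volumes must share one grid")
    geom, center, tangent, normal = _profile_frame(truth, vessel_label, s)
    if pitch is None:
        pitch = min(grid.spacing[:2]) / 4.0
    half = max(extent_factor * float(geom.reference_diameter_at(s)), min_extent_mm) / 2.0
    n = int(math.ceil(half / pitch))
    offsets = np.arange(-n, n + 1) * pitch

    if n_lines > 1:
        s_list = s + np.linspace(-s_window_mm / 2.0, s_window_mm / 2.0, n_lines)
        s_list = np.clip(s_list, 0.0, geom.length)
    else:
        s_list = np.array([s])

    ext = grid.world_extent()
    acc = np.zeros(offsets.size, dtype=np.float64)
    for sk in s_list:
        ck = geom.point_at(float(sk))
        pts = ck[None, :] + offsets[:, None] * normal[None, :]
        for ax in range(3):
            if pts[:, ax].min() < ext[ax][0] or pts[:, ax].max() > ext[ax][1]:
                raise ValueError("profile sampling line exits the volume")
        for v in volumes:
            acc += v.sample_world(pts)
    acc /= len(s_list) * len(volumes)
    return ProfileCurve(offsets, acc, pitch)


def make_cpr(
    volume: VoxelVolume,
    truth: PhantomTruth,
    vessel_label: str,
    s_range: tuple[float, float] | None = None,
    s_pitch: float | None = None,
    offset_extent_mm: float = 8.0,
    pitch: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Straightened (curved planar reformation) image of a vessel.

    Returns ``(image, s_axis, offset_axis)`` where ``image[i, j]`` samples
    arc length ``s_axis[i]`` at orthogonal offset ``offset_axis[j]``.
    """
    geom = truth.vessels[vessel_label]
    if s_range is None:
        s_range = (0.0, geom.length)
    if pitch is None:
        pitch = min(volume.grid.spacing[:2]) / 4.0
    if s_pitch is None:
        s_pitch = pitch
    s_axis = np.arange(s_range[0], s_range[1] + s_pitch / 2, s_pitch)
    n = int(math.ceil(offset_extent_mm / 2.0 / pitch))
    offs = np.arange(-n, n + 1) * pitch
    rows = []
    for sk in s_axis:
        _, ck, tk, nk = _profile_frame(truth, vessel_label, float(sk))
        pts = ck[None, :] + offs[:, None] * nk[None, :]
        rows.append(volume.sample_world(pts))
    return np.stack(rows, axis=0), s_axis, offs


def _cross_down(x0, y0, x1, y1, thr):
    """x where the segment (x0,y0)-(x1,y1) crosses y=thr."""
    if y1 == y0:
        return x1
    return x0 + (thr - y0) * (x1 - x0) / (y1 - y0)


def width_at_threshold(
    profile: ProfileCurve, model_peak: float, fraction: float,
    center_fraction: float = 0.5,
) -> float:
    """Width of the profile's central peak at ``fraction * model_peak``.

    The width is the length of the maximal contiguous interval containing
    the profile's *central* peak — the maximum within the central
    ``center_fraction`` of the sampled extent, so that bright neighbouring
    structures (e.g. the ventricle pool at the end of a long profile) are
    ignored — where the value stays at or above the threshold, with the
    two boundary crossings located by linear interpolation.  Returns 0.0
    when the peak never reaches the threshold (a valid reading for
    severely blurred stenoses).
    """
    if model_peak <= 0:
        raise ValueError("model peak must be positive")
    thr = fraction * model_peak
    vals = profile.values
    pos = profile.positions
    half = center_fraction * float(np.abs(pos).max())
    central = np.nonzero(np.abs(pos) <= max(half, profile.pitch))[0]
    peak_idx = int(central[np.argmax(vals[central])])
    if vals[peak_idx] < thr:
        return 0.0
    left = peak_idx
    while left > 0 and vals[left - 1] >= thr:
        left -= 1
    right = peak_idx
    while right < vals.size - 1 and vals[right + 1] >= thr:
        right += 1
    x_left = pos[left] if left == 0 else _cross_down(
        pos[left - 1], vals[left - 1], pos[left], vals[left], thr)
    x_right = pos[right] if right == vals.size - 1 else _cross_down(
        pos[right], vals[right], pos[right + 1], vals[right + 1], thr)
    return float(x_right - x_left)


def percent_error(measured: float, truth: float) -> float | None:
    """Signed percent error; ``None`` (reported "(-)") when truth is 0."""
    if truth == 0:
        return None
    return 100.0 * (measured - truth) / truth


def round_half_away(x: float, digits: int = 1) -> float:
    """Round half away from zero (the convention of printed tables)."""
    scale = 10.0**digits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def measure_vessel_profile(
    profile: ProfileCurve, model_profile: ProfileCurve
) -> WidthMetrics:
    """Peak CT number and W_10% / W_90% of a vessel profile vs the model.

    The model profile (from the resampled digital model at the same
    location) defines the 100% level; if its pitch differs it is
    resampled onto the measurement positions first.
    """
    if abs(model_profile.pitch - profile.pitch) > 1e-9 or (
        model_profile.positions.size != profile.positions.size
    ):
        model_profile = model_profile.resampled(profile.positions)
    model_peak = model_profile.central_peak()
    w10 = width_at_threshold(profile, model_peak, 0.10)
    w90 = width_at_threshold(profile, model_peak, 0.90)
    m_w10 = width_at_threshold(model_profile, model_peak, 0.10)
    m_w90 = width_at_threshold(model_profile, model_peak, 0.90)
    peak = profile.central_peak()
    return WidthMetrics(
        peak_ct=peak,
        w10=w10,
        w90=w90,
        model_peak=model_peak,
        model_w10=m_w10,
        model_w90=m_w90,
        errors={
            "peak_ct": percent_error(peak, model_peak),
            "w10": percent_error(w10, m_w10),
            "w90": percent_error(w90, m_w90),
        },
    )


@dataclass
class LumenMetrics:
    """Stent lumen width at the 110% threshold vs the stent-free truth."""

    w_lumen: float
    w_truth: float
    error: float | None
    threshold: float
    strut_positions: tuple[float, float]


def measure_stent_lumen(
    profile: ProfileCurve,
    model_profile: ProfileCurve,
    truth_fraction: float = 0.5,
) -> LumenMetrics:
    """Lumen width between the stent strut peaks at 110% of the model peak.

    The model profile must come from the *stent-free* digital model; its
    peak sets the 100% level.  The lumen width is the longest contiguous
    interval between the two strut maxima nearest the centerline where the
    measured profile stays at or below 1.10 x model peak (0 when blooming
    keeps the whole inter-strut region above it).  The reference W_truth
    is the stent-free model's vessel width, read at ``truth_fraction`` of
    its peak (default: full width at half maximum).
    """
    if abs(model_profile.pitch - profile.pitch) > 1e-9 or (
        model_profile.positions.size != profile.positions.size
    ):
        model_profile = model_profile.resampled(profile.positions)
    model_peak = model_profile.central_peak()
    thr = 1.10 * model_peak

    pos, vals = profile.positions, profile.values
    peaks, props = find_peaks(vals, height=thr)
    left_peaks = peaks[pos[peaks] < 0]
    right_peaks = peaks[pos[peaks] > 0]
    if left_peaks.size == 0 or right_peaks.size == 0:
        raise ValueError("no strut peaks found on both sides; profile not on a stent?")
    li = int(left_peaks[np.argmax(pos[left_peaks])])  # nearest to centre
    ri = int(right_peaks[np.argmin(pos[right_peaks])])

    w_truth = width_at_threshold(model_profile, model_peak, truth_fraction)

    seg_vals = vals[li : ri + 1]
    seg_pos = pos[li : ri + 1]
    below = seg_vals <= thr
    w_lumen = 0.0
    i = 0
    while i < below.size:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < below.size and below[j + 1]:
            j += 1
        x_left = seg_pos[i] if i == 0 else _cross_down(
            seg_pos[i - 1], seg_vals[i - 1], seg_pos[i], seg_vals[i], thr)
        x_right = seg_pos[j] if j == below.size - 1 else _cross_down(
            seg_pos[j], seg_vals[j], seg_pos[j + 1], seg_vals[j + 1], thr)
        w_lumen = max(w_lumen, float(x_right - x_left))
        i = j + 1

    return LumenMetrics(
        w_lumen=w_lumen,
        w_truth=w_truth,
        error=percent_error(w_lumen, w_truth),
        threshold=thr,
        strut_positions=(float(pos[li]), float(pos[ri])),
    )
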