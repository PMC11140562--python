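"""Image-noise metrics: ROI standard deviation and the noise power spectrum.

The noise ROI is a box placed inside the contrast-filled ventricle.  Both
metrics are evaluated slice by slice on axial planes and averaged, the NPS
additionally over repeated acquisitions.  NPS values are normalised to
HU^2 mm^2 so that the 2-D spectral integral recovers the noise variance
(Parseval), up to the variance removed by detrending.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .volume import VoxelVolume


@dataclass(frozen=True)
class ROISpec:
    """Half-open box ROI in world mm: ``[center - size/2, center + size/2)``."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValueError("ROI size must be positive")

    def index_slices(self, volume: VoxelVolume) -> tuple[slice, slice, slice]:
        """Voxel-index slices of the voxel centres inside the ROI."""
        slices = []
        for ax in range(3):
            lo = self.center[ax] - self.size[ax] / 2.0
            hi = self.center[ax] + self.size[ax] / 2.0
            coords = volume.grid.axis_coords(ax)
            inside = np.nonzero((coords >= lo - 1e-9) & (coords < hi - 1e-9))[0]
            if inside.size == 0:
                raise ValueError(f"ROI does not cover any voxel centre on axis {ax}")
            if inside[0] > 0 and coords[0] > lo + 1e-9:
                raise ValueError("ROI extends outside the volume")
            if coords[-1] < hi - volume.grid.spacing[ax] - 1e-9 and inside[-1] == len(coords) - 1:
                raise ValueError("ROI extends outside the volume")
            slices.append(slice(int(inside[0]), int(inside[-1]) + 1))
        return tuple(slices)

    def extract(self, volume: VoxelVolume) -> np.ndarray:
        sx, sy, sz = self.index_slices(volume)
        return volume.values[sx, sy, sz]


@dataclass
class NoiseStats:
    """Slice-averaged noise SD and mean CT number inside an ROI."""

    sd: float
    mean: float


@dataclass
class NPSResult:
    """Radially averaged 2-D noise power spectrum.

    freq : radial spatial frequencies, cycle/mm
    nps : radial NPS, HU^2 mm^2
    df : per-axis frequency resolution (1 / ROI extent), cycle/mm
    variance_integral : 2-D spectral integral, HU^2
    low_freq_cutoff : lowest resolvable frequency (1 / in-plane ROI extent)
    nps_2d : slice/repeat-averaged 2-D spectrum (fftshifted), HU^2 mm^2
    """

    freq: np.ndarray
    nps: np.ndarray
    df: tuple[float, float]
    variance_integral: float
    low_freq_cutoff: float
    nps_2d: np.ndarray


def roi_sd(volume: VoxelVolume, roi: ROISpec, ddof: int = 1) -> NoiseStats:
    """Mean over axial slices of the per-slice HU standard deviation.

    Also reports the mean HU (the "CT number" reading of the ROI).
    Adding a constant to the volume changes the mean but not the SD.
    """
    patch = roi.extract(volume).astype(np.float64)
    if patch.shape[0] * patch.shape[1] < 2:
        raise ValueError("ROI must contain at least 2 voxels per slice")
    per_slice_sd = patch.std(axis=(0, 1), ddof=ddof)
    return NoiseStats(sd=float(per_slice_sd.mean()), mean=float(patch.mean()))


def _poly2_design(nx: int, ny: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, nx)
    y = np.linspace(-1.0, 1.0, ny)
    X, Y = np.meshgrid(x, y, indexing="ij")
    cols = [np.ones_like(X), X, Y, X * Y, X**2, Y**2]
    return np.stack([c.ravel() for c in cols], axis=1)


def detrend_slices(
    patches: np.ndarray, method: Literal["poly2", "mean"] = "poly2"
) -> np.ndarray:
    """Remove a per-slice trend from a stack of 2-D patches (n, nx, ny)."""
    n, nx, ny = patches.shape
    flat = patches.reshape(n, -1)
    if method == "mean":
        return (flat - flat.mean(axis=1, keepdims=True)).reshape(patches.shape)
    if method != "poly2":
        raise ValueError(f"unknown detrend method {method!r}")
    A = _poly2_design(nx, ny)
    coef, *_ = np.linalg.lstsq(A, flat.T, rcond=None)
    return (flat - (A @ coef).T).reshape(patches.shape)


def estimate_nps(
    repeats: Sequence[VoxelVolume],
    roi: ROISpec,
    detrend: Literal["poly2", "ensemble"] = "poly2",
) -> NPSResult:
    """Estimate the slice-wise 2-D noise power spectrum inside an ROI.

    Per axial slice the ROI patch is detrended (second-order 2-D polynomial
    by default; ``"ensemble"`` subtracts the across-repeat mean image first,
    which needs at least two repeats), Fourier transformed, normalised by
    ROI and pixel area to HU^2 mm^2, then averaged over slices and repeats
    and radially binned in annuli one frequency sample wide.  No window
    function is applied; frequencies below 1/(ROI extent) are unresolved,
    which is reported as ``low_freq_cutoff``.
    """
    if len(repeats) == 0:
        raise ValueError("need at least one repeat volume")
    g0 = repeats[0].grid
    for v in repeats[1:]:
        if v.grid != g0:
            raise ValueError("all repeat volumes must share one grid")
    dx, dy, _ = g0.spacing

    stacks = []
    for v in repeats:
        patch = roi.extract(v).astype(np.float64)
        stacks.append(np.moveaxis(patch, 2, 0))  # (nz, nx, ny)
    data = np.stack(stacks, axis=0)  # (nrep, nz, nx, ny)
    nrep, nz, nx, ny = data.shape

    if detrend == "ensemble":
        if nrep < 2:
            raise ValueError("ensemble detrending needs >= 2 repeats")
        resid = data - data.mean(axis=0, keepdims=True)
        resid *= np.sqrt(nrep / (nrep - 1.0))  # unbiased noise power
        resid = detrend_slices(resid.reshape(-1, nx, ny), "mean")
    else:
        resid = detrend_slices(data.reshape(-1, nx, ny), "poly2")

    spec = np.fft.fft2(resid, axes=(1, 2))
    nps2d = (np.abs(spec) ** 2).mean(axis=0) * (dx * dy) / (nx * ny)

    dfx, dfy = 1.0 / (nx * dx), 1.0 / (ny * dy)
    variance = float(nps2d.sum() * dfx * dfy)

    fx = np.fft.fftfreq(nx, dx)
    fy = np.fft.fftfreq(ny, dy)
    fr = np.hypot(fx[:, None], fy[None, :])
    dfr = max(dfx, dfy)
    nbins = int(np.floor(fr.max() / dfr)) + 1
    which = np.minimum((fr / dfr + 0.5).astype(int), nbins - 1)
    sums = np.bincount(which.ravel(), weights=nps2d.ravel(), minlength=nbins)
    counts = np.bincount(which.ravel(), minlength=nbins)
    radial = sums / np.maximum(counts, 1)
    freq = np.arange(nbins) * dfr

    return NPSResult(
        freq=freq,
        nps=radial,
        df=(dfx, dfy),
        variance_integral=variance,
        low_freq_cutoff=1.0 / (nx * dx),
        nps_2d=np.fft.fftshift(nps2d),
    )
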