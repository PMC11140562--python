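"""Dose conversion and grid arithmetic.

Effective dose follows the standard dose-length-product convention:
``DLP = CTDIvol [mGy] x scan length [cm]`` and
``E = k x DLP`` with the chest conversion factor ``k`` in mSv/(mGy cm).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DoseParams:
    """Inputs of the effective-dose conversion.

    ctdivol : volume CT dose index, mGy
    scan_length_mm : scanned z-range, mm (converted to cm internally)
    k_factor : tissue conversion factor, mSv / (mGy cm); 0.014 for chest
    """

    ctdivol: float
    scan_length_mm: float
    k_factor: float = 0.014

    def __post_init__(self) -> None:
        if self.ctdivol < 0 or self.scan_length_mm < 0 or self.k_factor < 0:
            raise ValueError("dose parameters must be non-negative")


def dlp(p: DoseParams) -> float:
    """Dose-length product in mGy cm."""
    return p.ctdivol * (p.scan_length_mm / 10.0)


def effective_dose(p: DoseParams, *, digits: int | None = 2) -> float:
    """Effective dose in mSv; rounded to ``digits`` decimals for reporting."""
    dose = dlp(p) * p.k_factor
    return round(dose, digits) if digits is not None else dose


def pixel_size(fov_mm: float, matrix: int, *, digits: int | None = 2) -> float:
    """In-plane pixel size (mm) of a reconstruction field of view."""
    if matrix <= 0:
        raise ValueError("matrix size must be positive")
    px = fov_mm / matrix
    return round(px, digits) if digits is not None else px


def nyquist_frequency(spacing_mm: float) -> float:
    """Maximum representable spatial frequency, cycle/mm."""
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    return 1.0 / (2.0 * spacing_mm)
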