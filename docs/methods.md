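# Methods

`phantomiq` measures CT image quality for coronary CT angiography the way
a structured-phantom study does, but with the physical scan replaced by a
calibrated image-domain emulation. This note records the model, the
parameter choices that matter, the numerical decisions, and what the
synthetic setup can and cannot show about real scanners.

## The digital phantom

All geometry is analytic, defined in world millimetres, and voxelized on
demand; the analytic description is kept as ground truth so no boundary
detection or registration is ever needed.

**Anatomy.** An elliptical soft-tissue thorax (outer diameters
300 × 200 mm, 40 HU) contains two hollow (air, −1000 HU) lung regions,
seven plaster-like bone rods (700 HU; six ribs and one vertebra), and a
heart modelled as a contrast-filled cylindrical left-ventricle pool
(radius 30 mm) inside a myocardial cylinder (outer radius 40 mm, 40 HU).
Five coronary segments (diameters 4.0, 3.2, 3.0, 1.3 and 1.0 mm; one
gently curved, the rest axial) run through the myocardium at 35 mm from
the heart centre. The 1.3 mm segment carries a 70% *diameter* stenosis —
the standard CCTA severity convention — with a raised-cosine taper over
4 mm, so the true minimal diameter is exactly 0.3 × 1.3 = 0.39 mm. The
3.0 mm segment carries a 15 mm stent. A contrast-filled wedge block
with its top surface inclined 30° to the axial plane sits anteriorly;
its plane is the through-plane resolution edge. Iodinated spaces
(ventricle, vessels, wedge) use dilute contrast, 18 mgI/ml, whose CT
number is fixed at 424 HU at 120 kV.

The imaged volume is the reconstruction field of view (160 mm, matrix
1024, 0.15625 mm pixels, 0.25 mm slice interval), not the whole thorax;
the default axial extent is 32 mm, enough to hold the noise ROI
(40 × 40 × 25 mm), the slanted edge and the stented segment while
keeping a full study run around two minutes on one core.

**Hosting the stenosis on a 1.3 mm vessel.** The reference workflow
reports model widths at the stenosis of a few tenths of a millimetre,
which implies a sub-millimetre residual lumen; a 70% reduction of a
~1.3 mm vessel reproduces that regime (residual 0.39 mm), whereas a 70%
reduction of the 3.2 mm vessel would not. The normal-artery site is the
3.2 mm vessel.

**Stent model.** Real stent struts (~0.1 mm of metal in an open-cell
lattice) are far below the grid scale, so the stent is homogenised into
a cylindrical sleeve on the vessel wall: outer radius = vessel radius,
radial thickness 0.4 mm, effective 1900 HU. Thickness and HU were set
together with the preset PSFs so that the emulated images reproduce the
reported blooming behaviour regime — the lumen at the 110% threshold
closes completely under HIR-like blur and opens progressively under
DLR- and SR-DLR-like blur. They parameterise an effective metal load,
not a specific device.

**Voxelization.** Every structure is a signed-distance function (SDF);
materials are painted in priority order (stent > vessel lumen > heart >
bone > soft tissue > air) with occupancy-weighted HU mixing at
boundaries. The default antialiasing maps signed distance through a
linear ramp one voxel wide — volume conserving to first order and fast
enough for the 1024² grid. A reference voxelizer that counts 5³
supersampled points per boundary voxel is provided and used in tests as
the oracle; the two agree in integral measures to well under 1%.
Hard-voxelized boundaries would alias the edge-spread measurements; the
ramp reproduces the finite-resolution boundary of a printed phantom.

## Reconstruction emulation

The three reconstruction families are emulated only through their
second-order image statistics:

    model volume → Gaussian blur (σ_xy in-plane, σ_z axial)
                → trilinear resampling to the family's output grid
                → + stationary correlated noise (target SD, target NPS shape)

| preset | grid | σ_xy (mm) | σ_z (mm) | noise SD (HU) | NPS shape |
|---|---|---|---|---|---|
| HIR    | 512 / 0.3125 mm | 0.4248 | 0.4028 | 21.1 | ramp-lowpass, peak 0.15 cyc/mm |
| DLR    | 512 / 0.3125 mm | 0.3342 | 0.4048 | 19.0 | ramp-lowpass, peak 0.15 cyc/mm |
| SR-DLR | 1024 / 0.15625 mm | 0.2457 | 0.3635 | 13.1 | white |

Slice thickness (0.5 mm at 0.25 mm interval) is not modelled as a
separate box convolution; its smoothing is folded into σ_z.

**Calibration.** The σ values above were solved (secant iterations via
`phantomiq.recon.calibrate_preset`, measuring through the identical
noiseless emulation → ESF → MTF pipeline used in analysis) so that the
measured task-based MTF reaches 10% at the reference frequencies:
0.792 / 0.976 / 1.379 cycle/mm in-plane and 0.849 / 0.890 / 1.020
through-plane for HIR / DLR / SR-DLR. Closed-form Gaussian values are
the starting guesses; the converged values differ from them by a few
percent because the model-grid rasterization, resampling interpolation
and ESF binning each add a small, reproducible blur. Noise SDs are
exact by construction (the synthesized field is rescaled to the target
sample SD), and the NPS shapes encode the qualitative spectra:
low-frequency-weighted noise for the conventional families (S(f) ∝
f·exp(−f/0.15)), near-flat noise for SR-DLR — which makes the SR-DLR
spectrum orders of magnitude lower at low frequencies while slightly
higher per-frequency at high frequencies, as expected when a
"plastic-looking" low-frequency texture is suppressed.

**Noise synthesis.** Per axial slice, white Gaussian noise is filtered in
the frequency domain by √S(f) with the DC term removed (a physical NPS
vanishes at the origin); slices are independent. Repeat "scans" are
noise realizations with consecutive seeds; everything is bit-reproducible
given the master seed.

## Measurements

**Noise.** SD and mean CT number are measured slice by slice in a
40 × 40 × 25 mm ROI centred in the ventricle and averaged (over slices,
then over the three repeats). The NPS is the slice-wise 2-D periodogram
of the detrended ROI, normalised by pixel and ROI area to HU²·mm²,
averaged over slices and repeats, and radially binned in annuli one
frequency sample wide. Detrending is a per-slice second-order 2-D
polynomial fit (standard quantitative-CT practice; an ensemble-mean
subtraction mode is available when ≥2 repeats exist). No window is
applied; frequencies below 1/(ROI extent) = 0.025 cycle/mm are
unresolved and flagged as the low-frequency cutoff. The spectral
integral equals the detrended variance (Parseval) to within 2%.

**Task-based MTF.** The ESF is sampled by projecting every voxel centre
in a band (half-width 2.5 mm in-plane, 2 mm for the wedge) onto the
signed distance from the analytic boundary — the circular ventricle wall
for XY, the 30°-slanted plane for Z, where the slant yields sub-slice
sampling (0.25 mm × sin 30° = 0.125 mm). Samples are averaged in bins of
a quarter voxel (half the slant pitch for Z), the LSF is the central
finite difference, a Hann window 16× the LSF FWHM centred on the peak
suppresses tail noise, and the Fourier magnitude is normalised at zero
frequency. The known transfer functions of the finite difference and of
bin averaging are divided out. With an 8×-FWHM window the estimator
showed a ~3% positive bias on Gaussian edges (window-convolution
broadening); at 16× with the sinc compensation the bias is below 2%
over σ ∈ [0.2, 1.0] mm, which is why 16× is the default (both
configurable). f10/f50 are located by linear interpolation at the first
downward crossing.

**Profile curves.** Profiles are sampled orthogonally to the truth
centerline by trilinear interpolation at a quarter-pixel pitch, averaged
over the three repeats and over 9 closely spaced arc positions (±2 mm;
±0.5 mm at the stenosis, where the diameter varies along the vessel).
The peak CT number is the profile maximum near the centerline — "near"
meaning the central half of the sampled extent, because long profiles
can terminate inside the bright ventricle pool. W_90% and W_10% are the
widths of the interval around the central peak above 90% / 10% of the
*model* profile's peak, with sub-sample interpolated crossings, and 0.00
when the peak never reaches the threshold (the stenosis under all three
presets). W_lumen is the widest interval between the two strut peaks
nearest the centerline that stays at or below 110% of the stent-free
model peak. W_truth, the reference for the lumen error, is measured on
the stent-free model profile as its full width at half maximum — the
model's own vessel width — since the 110% threshold cannot intersect
the stent-free profile. Percent errors are computed from unrounded
values and rounded (half away from zero) last; an error against a zero
truth is reported as "-".

**Dose.** Effective dose is k·DLP with DLP = CTDIvol × scan length in
cm; the chest factor k = 0.014 mSv/(mGy·cm) and the study protocol
(3.7 mGy, 160 mm) give 0.83 mSv.

## What the synthetic study shows — and what it does not

The generator reproduces the *measured statistics* of the reference
scans: noise magnitude and texture, task-based resolution, and their
consequences for stenosis and stent-lumen quantification. Passing tests
therefore demonstrate that the measurement pipeline is unbiased against
known ground truth and that the calibrated emulation recovers the
configured operating points and every reported ordering (SD and
low-frequency NPS: SR-DLR < DLR < HIR; f10: SR-DLR > DLR > HIR;
W_lumen: SR-DLR > DLR > HIR = 0). They do not validate the proprietary
reconstructions themselves: no DCNN, no projection/sinogram physics, no
beam hardening, no spatially varying or non-Gaussian noise, no motion.
Absolute profile widths depend on the chosen vessel and stent geometry
(only orderings and the model-side widths are geometry-independent
claims), and a Gaussian PSF cannot reproduce edge-enhancement overshoot
that real nonlinear reconstructions sometimes show.

## Numerical details and degenerate inputs

- Grids are voxel-centre addressed; ROIs are half-open boxes in world mm.
  Resampling is trilinear with a background fill of −1000 HU; an
  identity resample returns bit-identical values.
- The emulator requires the model grid to be at least as fine as the
  output grid; zero blur + zero noise + matching grid is the identity.
- A noise target of 0 yields an exactly zero field; an identically zero
  NPS shape with a positive noise target is an error.
- ESF extraction fails loudly when the band is clipped by the volume,
  contains a single material, or the ESF has fewer than 8 bins.
- `width_at_threshold` returns 0.0 (not an error) when the threshold is
  never reached; `percent_error` against zero truth returns `None`.
- Degenerate vessels (non-increasing arc length, non-positive or
  out-of-range diameters) and stents whose HU does not exceed the
  contrast HU are rejected at construction.

## Problem sizes

Defaults were chosen so a complete study (phantom build, 3 presets × 3
repeats, all metrics) runs in about two minutes and under 5 GB on a
single core: 32 mm axial extent (129 model slices), full 1024² in-plane
model grid, three repeats. The test suite uses the same standard run
once, plus reduced configurations (16 mm axial extent, coarser unit-test
grids) where the full grid adds nothing to the property under test.
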