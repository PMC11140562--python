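# phantomiq

Structured digital cardiac phantom and task-based CT image-quality
metrics for coronary CT angiography (CCTA).

Modern CT reconstructions — hybrid iterative reconstruction (HIR),
deep-learning reconstruction (DLR) and super-resolution deep-learning
reconstruction (SR-DLR) — are nonlinear: their noise and resolution
depend on the object being scanned, so classic wire/bead phantoms do not
predict their clinical behaviour. The established remedy is a
*structured* phantom that mimics the anatomy (ribs, vertebra, hollow
lungs, a contrast-filled left ventricle, sub-4-mm coronary arteries with
a stenosis and an implanted stent) whose digital model doubles as ground
truth for every measurement. `phantomiq` implements that workflow
entirely in software, for physicists and algorithm developers who need a
reproducible desk-scale testbed for CCTA image-quality pipelines:

- **`phantomiq.phantom`** — analytic thorax/heart geometry (signed
  distance fields, occupancy-antialiased voxelization, exact vessel
  centerline/diameter truth; 18 mgI/ml contrast fixed at 424 HU).
- **`phantomiq.recon`** — image-domain emulation of the three
  reconstruction families by their second-order statistics: Gaussian PSF
  (σ_xy, σ_z), target noise SD, and target noise-power-spectrum shape on
  the family's output grid (512/0.31 mm or 1024/0.16 mm over a 160 mm
  FoV, 0.5/0.25 mm slices), with seeded repeat scans.
- **`phantomiq.noise`** — ROI noise SD (slice-by-slice, averaged) and the
  2-D noise power spectrum NPS(f) in HU²·mm² with Parseval-consistent
  normalisation.
- **`phantomiq.resolution`** — task-based MTF: the edge-spread function is
  sampled from the analytic ventricle/myocardium boundary (in-plane) or a
  plane inclined ≤30° to the axial plane (through-plane), differentiated
  to the LSF, windowed and Fourier transformed; `f10` is the frequency
  where MTF = 10%. For a Gaussian PSF, `f10 = √(ln 10 / (2π²σ²))`.
- **`phantomiq.profiles`** — profile curves orthogonal to vessel
  centerlines (and straightened CPR images): peak CT number, the widths
  `W_90%`/`W_10%` at 90%/10% of the digital model's peak, and the stent
  lumen width `W_lumen` at the 110% threshold between the strut peaks,
  each with percent error against the model.
- **`phantomiq.dose`** — CTDIvol → DLP → effective dose (`E = k · DLP`)
  and grid arithmetic.
- **`phantomiq.experiment` / CLI** — a seeded end-to-end runner producing
  metric tables, curve CSVs, plots and a JSON summary.

## Worked example

```python
from phantomiq import ExperimentConfig, run_experiment, write_report

result = run_experiment(ExperimentConfig(seed=1))
for name, r in result.presets.items():
    print(f"{name:7s} SD={r.noise_sd:5.1f} HU  f10_xy={r.mtf_xy.f10:.3f} "
          f"f10_z={r.mtf_z.f10:.3f} cyc/mm  W_lumen={r.lumen.w_lumen:.2f} mm")
print(f"model CT {result.model_mean_ct:.0f} HU, "
      f"effective dose {result.effective_dose_msv} mSv")
write_report(result, "report/")
```

prints (about two minutes on one core):

```
HIR     SD= 21.1 HU  f10_xy=0.792 f10_z=0.850 cyc/mm  W_lumen=0.00 mm
DLR     SD= 19.0 HU  f10_xy=0.976 f10_z=0.874 cyc/mm  W_lumen=0.50 mm
SR-DLR  SD= 13.1 HU  f10_xy=1.380 f10_z=1.017 cyc/mm  W_lumen=1.15 mm
model CT 424 HU, effective dose 0.83 mSv
```

Reading the numbers: the SR-DLR-like preset has both the lowest noise
(13.1 HU vs 21.1/19.0 HU) and the highest in-plane resolution (10% MTF
at 1.38 cycle/mm vs 0.98/0.79) — the combination that distinguishes
super-resolution reconstruction from the usual noise/resolution
trade-off. Downstream of that, the stent lumen at the 110% threshold is
completely "bloomed" shut under HIR-like blur (0.00 mm), partially open
under DLR (0.50 mm) and widest under SR-DLR (1.15 mm), against a
stent-free model width of 3.04 mm; the 70% stenosis (true residual
diameter 0.39 mm) reads `W_90% = 0.00` under all three presets.

The same pipeline is scriptable from the shell:

```sh
phantomiq run-all --seed 1 --out report/
phantomiq generate-phantom --out phantom/        # NIfTI volumes + truth JSON
```

## Scope

The emulator works purely in the image domain: it reproduces measured
noise magnitude, noise texture and task-based resolution of each
reconstruction family, not the proprietary algorithms, projection
physics, or scanner hardware. See `docs/methods.md` for the model,
calibration procedure, parameter defaults and limitations.
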