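# tfusnav

Model-based navigation for transcranial focused ultrasound (tFUS)
dose-delivery planning.

Low-intensity tFUS can stimulate deep brain nuclei (thalamus, amygdala,
hippocampus, ...) non-invasively, but the skull absorbs and scatters the
beam, so where the operator *points* the transducer and where the dose
actually *lands* can differ badly. The common practice — line-of-sight
targeting (LOST), placing the device so the target sits on its
centerline at the water focal depth — ignores the skull entirely.
`tfusnav` implements the alternative: pre-compute skull-aware beam
solutions for hundreds-to-thousands of *virtual transducers* tiled over
the subject's scalp, reduce each beam to the acoustic dose it deposits
in each labeled nucleus, and let the operator (or an optical-tracking
loop) navigate a per-scalp-position "dose map" in real time, because
every lookup is pre-computed.

It is a library for researchers in acoustic simulation and
neuronavigation, with a thin CLI for batch use.

## The model

**Materials.** CT/pseudo-CT Hounsfield units give bone porosity
φ = clip(1 − HU/1000, 0, 1), and each acoustic property mixes linearly:
x = φ·x_brain + (1−φ)·x_bone for x ∈ {ρ, c, α}, with IT'IS endpoint
values (ρ: 1046/1908 kg/m³, c: 1546/3514 m/s, α: 6.8/54.6 Np/m/MHz).

**Solver.** One-way hybrid angular-spectrum marching of the CW complex
pressure on a transducer-aligned grid (1.3·d transverse × 2·f axial,
λ/5 = 0.46 mm spacing at 650 kHz): spectral step exp(i·k_z·Δz) in a
water background, real-space phase/attenuation screen
exp(i(ω/c(r) − k_ref)Δz − α(r)Δz), plane-wave impedance transmission at
interfaces, absorbing transverse boundaries. Validated against a
brute-force Rayleigh–Sommerfeld integral (focal-plane correlation
≥ 0.999 in water).

**Dose and placement.** Dose in a nucleus = Σ intensity over its voxels
× voxel volume (arbitrary units). A *scalp map* is one dose value per
mesh face; its smoothed peak is the MBN placement. LOST and a
water-only ("Water") variant are implemented for comparison, plus group
statistics: min:max dose variability across subjects, percent dose
change, two-sided Welch t-test.

Everything runs on synthetic layered-head phantoms (nested ellipsoids,
seeded porous skull shell, labeled nuclei) so no subject data is
required.

## Worked example

```
python examples/02_water_beam.py
```

```
grid (173, 173, 283) at 0.4615 mm (lambda/5)
on-axis |p| peak at z = 62.8 mm (geometric focus 65 mm), pressure gain 17.9x the source amplitude
lateral -6 dB focal width: 3.2 mm
```

The F = 65 mm bowl focuses ~2 mm proximal to its geometric focus — the
diffraction focal shift expected at this Fresnel number — with a 3.2 mm
lateral focal width, the scale that makes millimetre placement errors
matter.

The other examples walk the full pipeline: `01` materials and phantom
construction, `03` beam-library pre-computation, scalp map and
MBN/LOST/Water placement on one subject, `04` simulated
optical-tracking navigation (pure lookups), `05` multi-subject dose
comparison with the variability and t-test statistics.

A CLI mirrors the batch steps
(`tfusnav phantom|precompute|scalpmap|place|compare|navigate`, each
taking `--config config.json`).

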