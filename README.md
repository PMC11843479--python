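# presir

Phase-restoring subpixel image registration for phase-sensitive
Fourier-domain OCT, with a discrete-scatterer speckle simulator, subpixel
motion estimators and phase-stability metrics.

## The problem

Phase-sensitive FD-OCT measures optical-path-length (OPL) changes from the
per-pixel phase difference between repeated B-scans,
`Δφ(x,z) = arg(Ã_T Ã_R*)`, with nanometer sensitivity
(`OPL = φ / 2k₀`, `k₀` the center wavenumber).  When the sample undergoes a
bulk translation `(Δx, Δz)` between frames, every scatterer's contribution
to the coherent speckle sum changes, so the measured phase difference is

    Δφ = 2k₀Δz + (pixel-specific displacement-induced error).

The error term is deterministic, varies from pixel to pixel along the same
A-line (so self-referencing does not cancel it), and grows with
displacement until the speckle decorrelates.  It limits motion detection
accuracy and phase sensitivity in optoretinography, Doppler OCT and
elastography whenever the subject moves.

## The method

Because a scatterer at OPL `z_j` enters the spectral interferogram as
`exp(i2kz_j)`, a bulk axial shift is *exactly* a phase ramp in the k
domain.  The registration core therefore

1. returns the complex B-scan (`M_z × M_x`) to the spectral domain —
   zero-pad to full range (`2M_z`), inverse DFT along depth;
2. multiplies `exp(−i2kΔz)` (full correction) or `exp(−i2(k−k₀)Δz)`
   (error-only: removes the sampling-point mismatch but keeps the bulk
   `2k₀Δz` term, so the OPL change itself remains measurable);
3. transforms back, discards the negative-frequency half, and corrects the
   lateral shift with a spatial-frequency ramp `exp(iuΔx)` (valid under
   lateral oversampling; tapered edge columns are masked).

No interpolation and no axial band-limit assumption are involved: the shift
is applied as if the sample had physically moved back.  Conventional
baselines — nearest-integer pixel rolling and the whole-image 2-D Fourier
shift that ignores the `k₀` carrier — are included for comparison, along
with the single-step upsampled cross-correlation estimator (κ-fold
matrix-multiply DFT refinement in a 1.5 × 1.5 px window, κ = 1000),
surface-phase axial estimation and coarse-to-fine volumetric registration.

## Worked example

Simulate a fully developed speckle phantom (axial/lateral FWHM 1.9/19.5 µm,
5 scatterers per coherence length, A-scan pitch = lateral FWHM/10), translate
it axially in 0.01 µm steps to 3 µm, and measure the spatial SD of the
per-pixel OPL change (σ_s):

```python
from presir.experiments import ExperimentConfig, run_translation_sweep

cfg = ExperimentConfig(motion="sweep", axial_range_um=3.0, step_um=0.01,
                       correction="none", seed=0)
res = run_translation_sweep(cfg)
print(f"uncorrected sigma_s at 3 um: {res.endpoint_sigma_s_nm:.1f} nm")

cfg2 = ExperimentConfig(motion="sweep", axial_range_um=3.0, step_um=0.01,
                        correction="presir_error_only", seed=0)
res2 = run_translation_sweep(cfg2)
print(f"after phase-restoring correction: {res2.sigma_s_nm.max():.3f} nm")
```

prints

```
uncorrected sigma_s at 3 um: 114.4 nm
after phase-restoring correction: 0.000 nm
```

i.e. a ~100 nm-scale error band builds up as the sample moves through the
1.9 µm axial PSF, and correcting the displacement with the known shift
removes it to well below a nanometer.  The same sweeps are available from
the shell as `presir repro-sweeps`; `presir simulate / shift / estimate /
register / analyze` operate on HDF5 B-scan stacks.

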