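# Methods

## Forward model

The sample is a set of discrete point scatterers with equal electric-field
reflectivity `r_j` at positions `(x_j, z_j)`, where `z` is optical path
length (OPL).  Each A-line at lateral position `x` records the complex
spectral interferogram

    I(x,k) = S(k) Σ_j r_j exp[−2(x−x_j)²/w_l²] exp(i2kz_j)

on a uniform wavenumber grid; `S(k)` is a unit-peak Gaussian amplitude
spectrum and `w_l` the 1/e² beam radius.  The complex B-scan is the DFT of
`I` along `k` evaluated on depth pixels `z_m = m·δz`, keeping the
positive-OPD half (`M_z = N_k/2` rows).  The sign convention places a
scatterer's peak at zero phase with local phase slope `−2k₀` along depth.
Fully developed speckle arises at the default density of 5 scatterers per
coherence length (taken as the axial intensity FWHM).

Model assumptions: 2-D (x,z) geometry — the out-of-plane beam dimension is
not modeled; a collimated, aberration-free Gaussian beam (no defocus/NA
dependence of lateral resolution with depth); rigid samples (no internal
deformation, flow, or intra-A-scan motion); noise, when enabled, is
i.i.d. circular complex Gaussian added in the spectral domain.

### Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `lambda0_um` | 0.84 | center wavelength; `k₀ = 2π/λ₀ ≈ 7.48 rad/µm`.  Typical for retinal SD-OCT; not uniquely determined by the system this emulates, configurable. |
| `axial_fwhm_um` | 1.9 | axial intensity-PSF FWHM.  Sets the spectrum width in closed form, `σ_k = √(ln 2)/FWHM` (Gaussian Fourier pair); the discrete-grid FWHM is verified to 1 % by test. |
| `lateral_fwhm_um` | 19.5 | lateral intensity-PSF FWHM; `w_l = FWHM/√(ln 2)`. |
| `lateral_pitch_um` | FWHM/10 | ten-fold lateral oversampling, the regime in which subpixel lateral estimation and Fourier-shift correction are valid. |
| `n_k` | 2048 | wavenumber samples; `M_z = n_k/2` depth pixels. |
| `span_sigmas` | 13 | full k-grid span in units of `σ_k`.  Chosen so `S(k)` falls to ~7×10⁻¹⁰ at the grid edge: spectral-truncation sidelobes then leak less than 10⁻⁹ (relative) into the discarded mirror half, which is what makes the image ↔ spectrum round trip and the axial correction exact at the 10⁻⁹–10⁻¹² level.  The axial pixel follows as `δz = π/(n_k·Δk) ≈ 0.55 µm`. |
| `guard_fraction` | 0.10 | depth fraction kept free of scatterers at each end of the range, preventing DC overlap and depth wrap.  With very shallow depth ranges (small `n_k`) the coherence-envelope tail of near-guard scatterers can still cross DC at the ~10⁻⁶ level; deep ranges push this below 10⁻¹². |
| noise SNR (dB) | off | peak intensity of a unit calibration reflector over noise variance **per quadrature** — the convention under which a pixel's phase noise is exactly `1/√SNR` rad.  A specular reflector is far brighter than speckle, so speckle-pixel SNR is correspondingly lower. |

## Registration operators

Axial: the kept image half is zero-padded back to full range and inverted
to the k domain, multiplied by `exp(−i2kΔz)` (full) or `exp(−i2(k−k₀)Δz)`
(error-only), and transformed back.  This is exact — modulus preserved per
element, group property `dz₁∘dz₂ = dz₁+dz₂`, and full-mode correction of a
simulated rigid axial displacement reproduces the reference image to
<10⁻⁹ relative.

Lateral: a phase ramp `exp(iuΔx)` in the lateral spatial-frequency domain.
Speckle is not periodic, and the wrap-around discontinuity of a plain
circular FFT shift leaks error across the whole image with only ~1/distance
decay (measured ~0.5 % at image center for 64 A-lines).  `lateral_shift`
therefore applies a raised-cosine taper over one beam radius at each edge
before the shift and invalidates the tapered plus wrapped columns in the
output mask; the masked interior error drops to ~2×10⁻⁴, limited by the
taper's spectral sidelobes.  `taper_columns=0` restores the exactly
invertible circular operator (used internally when synthesizing exactly
translated test pairs and by the brute-force correlation oracle).

Baselines: `pixel_shift_baseline` rolls by the nearest integer (ties round
away from zero — "nearest integer" alone does not fix the tie); residual
error peaks as the fractional displacement approaches half a pixel.
`ft_shift_baseline` shifts the complex image as a plain digital image in
both axes; it moves the speckle envelope but, lacking the `2k₀` carrier
term, cannot restore the phase, and is reproducibly worse than both the
phase-restoring corrector and (in phase terms) often the pixel baseline.

Shifts are specified in physical units (µm) and converted through the
pitches, so they remain unambiguous after axial upsampling.

## Motion estimation

`estimate_shift_2d` is the two-stage upsampled cross-correlation: a 2×
zero-padded spectrum gives a half-pixel peak; a κ-fold (default 1000)
matrix-multiply DFT evaluates the correlation on a fine grid only inside a
1.5 × 1.5 px neighbourhood.  Complex correlation is the default;
amplitude-only is a flag.  Two numerical choices matter:

* The kept image half is critically sampled along depth (its folded axial
  spectrum fills every frequency bin), which biases a correlation peak
  computed directly on it by ~5×10⁻³ px.  Both inputs are therefore
  axially oversampled 2× by k-domain zero padding first; a bulk axial
  shift is then an exact circular subpixel shift and planted displacements
  are recovered to the 1/κ grid.
* Ground-truth benchmarks use *exactly translated* pairs (shift operators
  with the circular lateral variant).  Translating the scatterer field
  itself makes content enter/leave the frame edges; the true correlation
  peak of such a windowed pair sits O(10⁻²–10⁻¹) px away from the physical
  shift at desk-scale widths (shrinking with aperture).  This is a property
  of the data, not the estimator: the estimator still agrees with the
  brute-force registered-correlation oracle, and
  estimate → register → re-estimate closes to < 2/κ px.

Ties in peak search resolve to the first maximum in row-major order.
Axial-only motion of samples with a specular surface uses the
amplitude-weighted circular mean of the surface phase change,
`dz = arg(Σ A_T A_R*)/(2k₀)`, valid per step below λ₀/4 and accumulated
over time for larger excursions.  Volumetric stacks are registered
coarse-to-fine: integer scan-direction offsets from 3-D amplitude
correlation of sparse sub-volumes (size/stride configurable; defaults 20
and 50), linearly interpolated per B-scan, then refined in-plane, keeping
the candidate reference scan with the highest correlation.

## Phase metrics

`σ_s` (accuracy) is the population SD across pixels of the measured OPL
change at one time point; `σ_t` (sensitivity) is the population SD over
time of one pixel's OPL trace.  Population rather than sample
normalization is fixed for reproducibility; at the pixel/frame counts used
the difference is immaterial.  Temporal unwrapping corrects 2π jumps per
pixel; pixels whose largest wrapped step exceeds 0.75π are flagged
unreliable (aliasing cannot be excluded) but not altered.  The
SNR-limited OPL noise floor is `(1/√SNR)/(2k₀)` per pixel and the
quadrature sum for a two-pixel (self-referenced) difference.  Outlier
rejection excludes pixels below 10 dB SNR or whose *centered* OPL trace
deviates from the per-frame spatial median by more than 5 scaled MADs
(traces are centered first so that a pixel is excluded for how it
fluctuates, not for the static offset inherited from reference-frame
noise); both thresholds are configurable.  Where a segmentation would be
needed (retinal layers), pixel sets are user-supplied.

## Simulation drivers and problem sizes

`run_translation_sweep` steps a fresh speckle slab to 3 µm in 0.01 µm
steps (axially, laterally, or both), unwraps each pixel's phase difference
with the initial frame, and tracks σ_s versus displacement;
`run_sinusoid_experiment` drives a 1 Hz, 2.7 µm peak-to-peak axial
sinusoid recorded as 600 B-scans at 200 Hz, estimates the motion from a
bright surface line, applies each corrector, self-references speckle
against the surface and compares per-pixel σ_t with a static acquisition.

Desk-scale extents are used: 64 A-lines (125 µm), a 30 µm slab,
`n_k = 256` — about 2×10³ analysis pixels and 10⁴ scatterers — chosen so a
full sweep completes in well under a minute while σ_s, an SD over ~200
independent speckle cells, has a few-percent standard error.  Frames along
a trajectory reuse the factorized forward model (axial steps are exact
spectral ramps; lateral weights are rebuilt only when `dx` changes), which
is algebraically identical to translating the field and re-simulating.

What the generator does not emulate: out-of-plane motion, rotation and
non-rigid deformation, depth-dependent beam width, multiple scattering and
tail artifacts, galvanometer jitter, and 1/f system phase drift.  Passing
tests therefore demonstrate correctness of the operators and estimators
under rigid in-plane translation — the regime the method addresses — not
performance on structurally decorrelating tissue.  Stability figures from
physical phantoms or in-vivo retinas require the corresponding hardware
and are represented only by simulation analogues (method ordering and
noise-floor attainment), not by their absolute values.

## Known limitations

* Lateral correction assumes oversampling and stable A-line-to-A-line
  phase; the tapered edge columns are lost to the mask.
* The y (scan) axis of volumetric registration is integer-resolution.
* `σ_s` values at large displacement include pixels whose unwrapped traces
  slipped by 2π near full decorrelation; this is part of the measured
  error, as in the underlying experiment design.
* HDF5 stacks store complex data as paired real datasets; no vendor raw
  formats.
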