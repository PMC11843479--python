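"""Close-to-reality FD-OCT speckle forward model.

A sample is a cloud of discrete point scatterers; each A-line records the
coherent superposition of light scattered from all scatterers inside the
Gaussian beam, producing a complex spectral interferogram

    I(x, k) = S(k) * sum_j r_j exp[-2 (x - x_j)^2 / w_l^2] exp(i 2 k z_j)

over a uniform wavenumber grid.  The complex B-scan is obtained by a DFT
along k, and fully developed speckle emerges when the scatterer density is a
few per coherence length.  The axial coordinate z is optical path length
(OPL), so a bulk axial displacement dz multiplies the interferogram by
exp(i 2 k dz) exactly — the property the registration core exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OCTSystem",
    "ScattererField",
    "SpectralFrame",
    "ComplexImage",
    "ImageStack",
    "generate_scatterer_field",
    "translate_field",
    "simulate_interferogram",
    "reconstruct_image",
    "analytic_image",
    "system_psf_fwhm",
    "image_noise_std",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OCTSystem:
    """Optical and sampling geometry of a spectral-domain OCT system.

    Parameters
    ----------
    lambda0_um:
        Center wavelength in micrometres (vacuum).  k0 = 2*pi/lambda0.
    axial_fwhm_um:
        FWHM of the axial *intensity* point-spread function, in OPL um.
        Sets the Gaussian source-spectrum width sigma_k = sqrt(ln 2)/FWHM.
    lateral_fwhm_um:
        FWHM of the lateral intensity PSF.  The beam 1/e^2 amplitude radius
        is w_l = FWHM/sqrt(ln 2).
    n_k:
        Number of wavenumber samples (even).  The image has M_z = n_k/2
        depth pixels.
    m_x:
        Number of A-lines per B-scan.
    lateral_pitch_um:
        A-scan spacing; defaults to lateral FWHM / 10 (ten-fold lateral
        oversampling).
    span_sigmas:
        Full k-grid span in units of sigma_k.  13 keeps the spectrum edge
        near 7e-10 of its peak so truncation leakage is negligible.
    guard_fraction:
        Fraction of the depth range reserved at each end; scatterers are
        never placed there, preventing wrap-around or DC overlap.
    """

    lambda0_um: float = 0.84
    axial_fwhm_um: float = 1.9
    lateral_fwhm_um: float = 19.5
    n_k: int = 2048
    m_x: int = 1000
    lateral_pitch_um: float | None = None
    span_sigmas: float = 13.0
    guard_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.lambda0_um <= 0 or self.axial_fwhm_um <= 0 or self.lateral_fwhm_um <= 0:
            raise ValueError("optical parameters must be positive")
        if self.n_k % 2 or self.n_k < 8:
            raise ValueError("n_k must be even and >= 8")
        if self.m_x < 1:
            raise ValueError("m_x must be positive")
        if self.lateral_pitch_um is None:
            object.__setattr__(self, "lateral_pitch_um", self.lateral_fwhm_um / 10.0)
        if self.lateral_pitch_um <= 0:
            raise ValueError("lateral pitch must be positive")

    # --- derived spectral geometry -----------------------------------
    @property
    def k0(self) -> float:
        """Center wavenumber, rad/um."""
        return 2.0 * np.pi / self.lambda0_um

    @property
    def sigma_k(self) -> float:
        """Std of the Gaussian *amplitude* spectrum, rad/um."""
        return np.sqrt(np.log(2.0)) / self.axial_fwhm_um

    @property
    def dk(self) -> float:
        return self.span_sigmas * self.sigma_k / self.n_k

    @property
    def k_grid(self) -> np.ndarray:
        """Uniform wavenumber grid; k0 is the grid midpoint."""
        n = np.arange(self.n_k)
        return self.k0 + (n - (self.n_k - 1) / 2.0) * self.dk

    @property
    def spectrum(self) -> np.ndarray:
        """Unit-peak Gaussian amplitude spectrum S(k) on the grid."""
        k = self.k_grid
        return np.exp(-((k - self.k0) ** 2) / (2.0 * self.sigma_k**2))

    @property
    def beam_radius_um(self) -> float:
        """1/e^2 intensity radius w_l of the probe beam, um."""
        return self.lateral_fwhm_um / np.sqrt(np.log(2.0))

    # --- image geometry ----------------------------------------------
    @property
    def m_z(self) -> int:
        return self.n_k // 2

    @property
    def axial_pitch_um(self) -> float:
        """Depth-pixel size in OPL um: dz = pi / (n_k * dk)."""
        return np.pi / (self.n_k * self.dk)

    @property
    def depth_range_um(self) -> float:
        """OPL depth covered by the kept (positive-OPD) image half."""
        return self.m_z * self.axial_pitch_um

    @property
    def guard_um(self) -> float:
        return self.guard_fraction * self.depth_range_um

    @property
    def x_grid(self) -> np.ndarray:
        return np.arange(self.m_x) * self.lateral_pitch_um

    @property
    def z_grid(self) -> np.ndarray:
        return np.arange(self.m_z) * self.axial_pitch_um

    @property
    def coherence_length_um(self) -> float:
        """Density bookkeeping length; equal to the axial intensity FWHM."""
        return self.axial_fwhm_um


@dataclass(frozen=True)
class ScattererField:
    """Point scatterers (x_j, z_j, r_j) inside a rectangular extent.

    Axial positions are OPL um and must stay inside the system's guarded
    depth span so reconstructed images neither wrap nor overlap DC.
    """

    x_um: np.ndarray
    z_um: np.ndarray
    r: np.ndarray
    x_extent: tuple[float, float]
    z_extent: tuple[float, float]

    def __post_init__(self) -> None:
        x, z, r = (np.asarray(a, dtype=float) for a in (self.x_um, self.z_um, self.r))
        if not (x.shape == z.shape == r.shape) or x.ndim != 1:
            raise ValueError("x_um, z_um, r must be 1-D arrays of equal length")
        if np.any(r < 0):
            raise ValueError("reflectivities must be non-negative")
        if x.size:
            if x.min() < self.x_extent[0] - 1e-9 or x.max() > self.x_extent[1] + 1e-9:
                raise ValueError("scatterer outside lateral extent")
            if z.min() < self.z_extent[0] - 1e-9 or z.max() > self.z_extent[1] + 1e-9:
                raise ValueError("scatterer outside axial extent")
        object.__setattr__(self, "x_um", x)
        object.__setattr__(self, "z_um", z)
        object.__setattr__(self, "r", r)

    def __len__(self) -> int:
        return self.x_um.size

    def check_in_range(self, system: OCTSystem) -> None:
        lo, hi = self.z_extent
        if lo < system.guard_um or hi > system.depth_range_um - system.guard_um:
            raise ValueError(
                "field axial extent "
                f"({lo:.2f}, {hi:.2f}) um violates the guarded span "
                f"({system.guard_um:.2f}, {system.depth_range_um - system.guard_um:.2f}) um"
            )


@dataclass
class SpectralFrame:
    """Complex interferogram, shape (m_x, n_k); ``analytic`` or ``real`` detector."""

    data: np.ndarray
    system: OCTSystem
    detector: str = "analytic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != (self.system.m_x, self.system.n_k):
            raise ValueError(
                f"frame shape {self.data.shape} does not match system "
                f"({self.system.m_x}, {self.system.n_k})"
            )
        if self.detector not in ("analytic", "real"):
            raise ValueError("detector must be 'analytic' or 'real'")
        if self.detector == "real" and np.any(self.data.imag != 0):
            raise ValueError("real-detector frame must have zero imaginary part")


@dataclass
class ComplexImage:
    """Complex B-scan, shape (m_z, m_x), with an optional column-validity mask."""

    data: np.ndarray
    system: OCTSystem
    valid_columns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2 or self.data.shape[1] != self.system.m_x:
            raise ValueError(
                f"image shape {self.data.shape} does not match system m_x={self.system.m_x}"
            )
        if self.valid_columns is None:
            self.valid_columns = np.ones(self.data.shape[1], dtype=bool)
        else:
            self.valid_columns = np.asarray(self.valid_columns, dtype=bool)
            if self.valid_columns.shape != (self.data.shape[1],):
                raise ValueError("valid_columns must have one flag per A-line")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)

    @property
    def axial_pitch_um(self) -> float:
        """Depth pixel size; accounts for axial upsampling (rows > m_z)."""
        return self.system.depth_range_um / self.data.shape[0]


@dataclass
class ImageStack:
    """Time series of complex B-scans: ``data`` is (n_frames, m_z, m_x)."""

    data: np.ndarray
    system: OCTSystem
    timestamps: np.ndarray | None = None
    valid_columns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 3:
            raise ValueError("stack must be 3-D (frame, z, x)")
        if self.timestamps is None:
            self.timestamps = np.arange(self.data.shape[0], dtype=float)
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (self.data.shape[0],):
                raise ValueError("one timestamp per frame required")
        if self.valid_columns is None:
            self.valid_columns = np.ones(self.data.shape[2], dtype=bool)
        else:
            self.valid_columns = np.asarray(self.valid_columns, dtype=bool)

    def __len__(self) -> int:
        return self.data.shape[0]

    def frame(self, i: int) -> ComplexImage:
        return ComplexImage(self.data[i], self.system,
                            valid_columns=self.valid_columns.copy())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_scatterer_field(
    extent: tuple[tuple[float, float], tuple[float, float]],
    density_per_coherence_length: float,
    reflectivity: float,
    seed: int,
    system: OCTSystem | None = None,
) -> ScattererField:
    """Draw a uniform random scatterer field.

    ``extent`` is ((x_lo, x_hi), (z_lo, z_hi)) in um.  The scatterer count is
    round(density * area / L_c^2) with L_c the coherence length (axial
    intensity FWHM) of ``system`` (default system if omitted), which at the
    default density of 5 yields fully developed speckle.  All scatterers get
    equal reflectivity.  Deterministic given ``seed``.
    """
    (x_lo, x_hi), (z_lo, z_hi) = extent
    if x_hi <= x_lo or z_hi <= z_lo:
        raise ValueError("extent must be positive in both axes")
    if density_per_coherence_length <= 0:
        raise ValueError("density must be positive")
    sys_ = system if system is not None else OCTSystem()
    lc = sys_.coherence_length_um
    area = (x_hi - x_lo) * (z_hi - z_lo)
    count = int(round(density_per_coherence_length * area / lc**2))
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_lo, x_hi, size=count)
    z = rng.uniform(z_lo, z_hi, size=count)
    r = np.full(count, float(reflectivity))
    return ScattererField(x, z, r, (x_lo, x_hi), (z_lo, z_hi))


def translate_field(field: ScattererField, dx: float, dz: float,
                    system: OCTSystem | None = None) -> ScattererField:
    """Rigidly translate all scatterers by (dx, dz) um; reflectivities kept.

    If ``system`` is given, the translated axial extent is checked against
    its guarded depth span and an out-of-range error is raised on violation.
    """
    out = ScattererField(
        field.x_um + dx,
        field.z_um + dz,
        field.r.copy(),
        (field.x_extent[0] + dx, field.x_extent[1] + dx),
        (field.z_extent[0] + dz, field.z_extent[1] + dz),
    )
    if system is not None:
        out.check_in_range(system)
    return out


def _lateral_weights(field: ScattererField, system: OCTSystem) -> np.ndarray:
    """Gaussian beam weights, shape (n_scatterers, m_x)."""
    x = system.x_grid[np.newaxis, :]
    xj = field.x_um[:, np.newaxis]
    return np.exp(-2.0 * (x - xj) ** 2 / system.beam_radius_um**2)


def _k_phases(field: ScattererField, system: OCTSystem) -> np.ndarray:
    """exp(i 2 k z_j), shape (n_k, n_scatterers)."""
    k = system.k_grid[:, np.newaxis]
    return np.exp(2j * k * field.z_um[np.newaxis, :])


def image_noise_std(system: OCTSystem, noise_snr_db: float) -> float:
    """Per-quadrature image-domain noise std implied by a calibration SNR.

    The calibration is a unit reflector at the beam center: its image peak
    amplitude is sum_n S(k_n); the requested SNR (dB) is peak intensity
    over the noise variance per quadrature — the convention under which a
    pixel's phase noise is 1/sqrt(SNR) radians.
    """
    peak = float(np.sum(system.spectrum))
    return peak / np.sqrt(10.0 ** (noise_snr_db / 10.0))


def _spectral_noise_std(system: OCTSystem, noise_snr_db: float) -> float:
    # per-quadrature image variance after an unnormalized n_k-point DFT of
    # circular spectral noise with per-quadrature std s is n_k * s^2
    return image_noise_std(system, noise_snr_db) / np.sqrt(system.n_k)


def simulate_interferogram(
    field: ScattererField,
    system: OCTSystem,
    detector: str = "analytic",
    noise_snr_db: float | None = None,
    seed: int | None = None,
) -> SpectralFrame:
    """Synthesize the complex spectral interferogram of ``field``.

    ``analytic`` mode evaluates the one-sided model directly; ``real`` mode
    returns twice its real part (what a spectrometer with a real-valued
    detector would record, up to reference-arm DC terms that carry no
    sample information).  Optional circular complex Gaussian detector noise
    is calibrated so a unit reflector reconstructs at ``noise_snr_db`` peak
    SNR.
    """
    field.check_in_range(system)
    if len(field):
        phases = _k_phases(field, system)          # (n_k, J)
        weights = _lateral_weights(field, system)  # (J, m_x)
        raw = (phases * field.r[np.newaxis, :]) @ weights  # (n_k, m_x)
        data = (system.spectrum[:, np.newaxis] * raw).T    # (m_x, n_k)
    else:
        data = np.zeros((system.m_x, system.n_k), dtype=complex)
    if detector == "real":
        data = 2.0 * data.real
    if noise_snr_db is not None:
        rng = np.random.default_rng(seed)
        sigma = _spectral_noise_std(system, noise_snr_db)
        if detector == "real":
            data = data + rng.normal(0.0, sigma * np.sqrt(2.0), size=data.shape)
        else:
            noise = rng.normal(0.0, sigma, size=(*data.shape, 2))
            data = data + noise[..., 0] + 1j * noise[..., 1]
    if detector == "real":
        data = data.astype(complex)
    return SpectralFrame(data, system, detector=detector)


def reconstruct_image(frame: SpectralFrame) -> ComplexImage:
    """DFT along k onto depth pixels z_m = m*dz; keep the positive-OPD half.

    The transform is A(x, z_m) = sum_n I(x, k_n) exp(-i 2 k_n z_m), so a
    single scatterer at a pixel-centered z_j peaks at row round(z_j/dz) with
    zero phase, and the local phase slope along z is -2 k0.
    """
    system = frame.system
    spec = frame.data  # (m_x, n_k)
    # k_n = k_min + n dk and z_m = m dz with 2 dk dz = 2 pi / n_k, so the
    # inner sum is a plain FFT followed by a row-dependent phase for k_min.
    full = np.fft.fft(spec, axis=1)  # (m_x, n_k) over m index
    m = np.arange(system.n_k)
    k_min = system.k_grid[0]
    phase = np.exp(-2j * k_min * m * system.axial_pitch_um)
    full = full * phase[np.newaxis, :]
    kept = full[:, : system.m_z].T  # (m_z, m_x)
    return ComplexImage(kept, system)


def _axial_envelope(system: OCTSystem, dz: np.ndarray) -> np.ndarray:
    """Discrete coherence envelope gamma(dz) = sum_n S(k_n) e^{i 2(k_n-k0) dz}.

    Computed on the same k grid the simulator uses, so the analytic
    superposition matches the interferogram->DFT pipeline to rounding.
    """
    k = system.k_grid
    dz = np.asarray(dz, dtype=float)
    phases = np.exp(2j * np.multiply.outer(dz, k - system.k0))  # (..., n_k)
    return phases @ system.spectrum


def analytic_image(field: ScattererField, system: OCTSystem) -> ComplexImage:
    """Direct superposition oracle for the simulate->reconstruct pipeline.

    A(x, z) = sum_j r_j g(x - x_j) gamma(z - z_j) exp[-i 2 k0 (z - z_j)],
    with g the lateral beam Gaussian and gamma the discrete coherence
    envelope of S(k).  Must agree with the DFT pipeline to float tolerance.
    """
    field.check_in_range(system)
    img = np.zeros((system.m_z, system.m_x), dtype=complex)
    z = system.z_grid[:, np.newaxis]  # (m_z, 1)
    # chunk over scatterers: the (m_z, J, n_k) envelope tensor is otherwise large
    chunk = max(1, int(2e7 // (system.m_z * system.n_k)))
    for j0 in range(0, len(field), chunk):
        sl = slice(j0, min(j0 + chunk, len(field)))
        sub = ScattererField(field.x_um[sl], field.z_um[sl], field.r[sl],
                             field.x_extent, field.z_extent)
        dzs = z - sub.z_um[np.newaxis, :]                 # (m_z, j)
        gamma = _axial_envelope(system, dzs)              # (m_z, j), complex
        carrier = np.exp(-2j * system.k0 * dzs)
        weights = _lateral_weights(sub, system)           # (j, m_x)
        img += (gamma * carrier * sub.r[np.newaxis, :]) @ weights
    return ComplexImage(img, system)


def _fwhm_of_profile(coord: np.ndarray, intensity: np.ndarray) -> float:
    """FWHM by linear interpolation around the discrete peak."""
    i = int(np.argmax(intensity))
    half = intensity[i] / 2.0
    # walk left
    li = i
    while li > 0 and intensity[li] > half:
        li -= 1
    ri = i
    while ri < intensity.size - 1 and intensity[ri] > half:
        ri += 1
    if li == i or ri == i:
        raise ValueError("profile does not fall to half maximum within range")
    xl = np.interp(half, [intensity[li], intensity[li + 1]], [coord[li], coord[li + 1]])
    xr = np.interp(half, [intensity[ri], intensity[ri - 1]], [coord[ri], coord[ri - 1]])
    return float(xr - xl)


def system_psf_fwhm(system: OCTSystem, oversample: int = 64) -> tuple[float, float]:
    """(axial, lateral) intensity-PSF FWHM in um, measured on a fine grid.

    The axial PSF is |gamma(z)|^2 evaluated from the discrete spectrum; the
    lateral PSF is the beam Gaussian exp(-4 x^2 / w_l^2).
    """
    dz_fine = np.linspace(-4 * system.axial_fwhm_um, 4 * system.axial_fwhm_um,
                          oversample * 64 + 1)
    gamma = np.abs(_axial_envelope(system, dz_fine)) ** 2
    axial = _fwhm_of_profile(dz_fine, gamma)
    lateral = system.beam_radius_um * np.sqrt(np.log(2.0))
    return axial, float(lateral)
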