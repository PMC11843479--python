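"""Phase-restoring subpixel registration operators for complex OCT B-scans.

Axial and lateral translations are handled differently because the OCT
signal forms differently along the two axes.  Axially, every scatterer at
OPL z_j contributes exp(i 2 k z_j) to the spectral interferogram, so a bulk
OPL shift dz is *exactly* exp(i 2 k dz) in the k domain — no interpolation,
no band-limit assumption.  The axial corrector therefore returns to the k
domain (zero-pad the M_z-row image to full range, inverse DFT) and applies

    full mode:       I_c(x,k) = I_T(x,k) exp(-i 2 k0 dz) exp(-i 2 (k-k0) dz)
    error-only mode: I_c(x,k) = I_T(x,k) exp(-i 2 (k-k0) dz)

Full mode shifts the image back as if the sample had physically returned;
error-only removes only the sampling-point mismatch, retaining the bulk
2 k0 dz phase so the OPL change itself stays measurable.

Laterally the image is an ordinary band-limited digital image (the beam
Gaussian is the PSF), so a subpixel lateral shift is a Fourier-domain phase
ramp, valid under lateral oversampling; wrapped edge columns are flagged in
the image's validity mask.

Two conventional correctors are included as baselines: a whole-image 2-D
Fourier shift that ignores the k0 carrier (``ft_shift_baseline``) and
nearest-integer pixel rolling (``pixel_shift_baseline``).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .forward_model import ComplexImage, OCTSystem, SpectralFrame

__all__ = [
    "ShiftVector",
    "CorrectionMode",
    "image_to_spectrum",
    "spectrum_to_image",
    "axial_shift",
    "lateral_shift",
    "presir_register",
    "ft_shift_baseline",
    "pixel_shift_baseline",
    "axial_upsample",
]


@dataclass(frozen=True)
class ShiftVector:
    """Displacement FROM the reference TO the target, in physical units.

    ``dx_um`` is lateral (um), ``dz_um`` axial (OPL um).  Correctors apply
    the opposite shift, returning the target to the reference position.
    """

    dx_um: float = 0.0
    dz_um: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dx_um) and np.isfinite(self.dz_um)):
            raise ValueError("shift components must be finite")

    def validate_against(self, system: OCTSystem) -> None:
        if abs(self.dx_um) > system.m_x * system.lateral_pitch_um / 2:
            raise ValueError("lateral shift exceeds half the image extent")
        if abs(self.dz_um) > system.depth_range_um / 2:
            raise ValueError("axial shift exceeds half the depth range")


class CorrectionMode(str, Enum):
    """``full`` removes bulk phase too; ``error_only`` keeps the OPL change."""

    FULL = "full"
    ERROR_ONLY = "error_only"


# ---------------------------------------------------------------------------
# image <-> spectrum
# ---------------------------------------------------------------------------

def image_to_spectrum(image: ComplexImage) -> SpectralFrame:
    """Zero-pad the B-scan to full range and invert the depth DFT.

    Rows M_z..2M_z-1 (the discarded negative-OPD half) are appended as
    zeros; the result is the complex interferogram I(x, k) on the system's
    n_k-point k grid.  Exact inverse of :func:`spectrum_to_image`.
    """
    system = image.system
    if image.data.shape[0] != system.m_z:
        raise ValueError("image must have m_z rows (not axially upsampled)")
    full = np.concatenate(
        [image.data, np.zeros_like(image.data)], axis=0
    ).T  # (m_x, n_k) over depth index m
    m = np.arange(system.n_k)
    k_min = system.k_grid[0]
    # undo the k_min phase applied in reconstruction, then an inverse FFT
    full = full * np.exp(2j * k_min * m * system.axial_pitch_um)[np.newaxis, :]
    spec = np.fft.ifft(full, axis=1)
    return SpectralFrame(spec, image.system, detector="analytic")


def spectrum_to_image(frame: SpectralFrame) -> ComplexImage:
    """DFT along k and keep the positive-OPD half (rows 0..M_z-1)."""
    from .forward_model import reconstruct_image

    return reconstruct_image(frame)


# ---------------------------------------------------------------------------
# elementary correctors
# ---------------------------------------------------------------------------

def axial_shift(frame: SpectralFrame, dz_um: float,
                mode: CorrectionMode | str = CorrectionMode.FULL) -> SpectralFrame:
    """Correct an axial displacement ``dz_um`` (reference -> target) in k.

    Multiplies elementwise by exp(-i 2 k dz) in full mode or
    exp(-i 2 (k - k0) dz) in error-only mode; every element's modulus is
    preserved exactly.
    """
    mode = CorrectionMode(mode)
    system = frame.system
    k = system.k_grid
    if mode is CorrectionMode.FULL:
        ramp = np.exp(-2j * k * dz_um)
    else:
        ramp = np.exp(-2j * (k - system.k0) * dz_um)
    return SpectralFrame(frame.data * ramp[np.newaxis, :], system, detector="analytic")


def lateral_shift(image: ComplexImage, dx_um: float,
                  taper_columns: int | None = None) -> ComplexImage:
    """Correct a lateral displacement ``dx_um`` via a spatial-frequency ramp.

    A target displaced by +dx returns to the reference: A_c(x) = A_T(x+dx).
    Unlike the axial k-domain ramp this is only as exact as the signal is
    band-limited *and* circular; speckle is not periodic, and the wrap-around
    discontinuity of a plain FFT shift leaks error deep into the image (it
    decays only like 1/distance).  The edges are therefore tapered with a
    raised-cosine over ``taper_columns`` (default: one beam radius, capped
    at a quarter of the image) before the shift, which confines the error
    to the tapered columns; those plus the ceil(|dx|/pitch) wrapped columns
    are invalidated in the output mask.  With ``taper_columns=0`` the shift
    is the exactly invertible circular operator.
    """
    system = image.system
    pitch = system.lateral_pitch_um
    m_x = system.m_x
    if taper_columns is None:
        taper_columns = min(int(np.ceil(system.beam_radius_um / pitch)), m_x // 4)

    data_in = image.data
    if taper_columns > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(taper_columns) + 0.5)
                                   / taper_columns))
        window = np.ones(m_x)
        window[:taper_columns] = ramp
        window[m_x - taper_columns:] = ramp[::-1]
        data_in = data_in * window[np.newaxis, :]

    u = 2.0 * np.pi * np.fft.fftfreq(m_x, d=pitch)
    spec = np.fft.fft(data_in, axis=1) * np.exp(1j * u * dx_um)[np.newaxis, :]
    data = np.fft.ifft(spec, axis=1)

    n_bad = int(np.ceil(abs(dx_um) / pitch)) + taper_columns
    valid = image.valid_columns.copy()
    if n_bad:
        valid[:n_bad] = False
        valid[max(0, m_x - n_bad):] = False
    return ComplexImage(data, system, valid_columns=valid)


def presir_register(image: ComplexImage, shift: ShiftVector,
                    mode: CorrectionMode | str = CorrectionMode.FULL,
                    taper_columns: int | None = None) -> ComplexImage:
    """Register ``image`` (the target) back onto the reference position.

    Composition: image -> k domain -> axial phase correction -> image ->
    lateral spatial-frequency correction.  ``shift`` is the estimated
    reference-to-target displacement; the validity mask is carried through.
    ``taper_columns`` is forwarded to :func:`lateral_shift` (0 selects the
    exactly invertible circular variant).
    """
    shift.validate_against(image.system)
    valid = image.valid_columns
    frame = image_to_spectrum(image)
    frame = axial_shift(frame, shift.dz_um, mode)
    out = spectrum_to_image(frame)
    out.valid_columns &= valid
    if shift.dx_um != 0.0:
        out = lateral_shift(out, shift.dx_um, taper_columns=taper_columns)
    return out


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def ft_shift_baseline(image: ComplexImage, shift: ShiftVector) -> ComplexImage:
    """Whole-image 2-D Fourier shift treating the B-scan as a digital image.

    Ignores the k0 carrier along depth, so it translates the speckle
    envelope without restoring physically meaningful phase — the reference
    behaviour PRESIR is compared against.
    """
    system = image.system
    m_z_eff = image.data.shape[0]
    dz_pitch = image.axial_pitch_um
    u = 2.0 * np.pi * np.fft.fftfreq(system.m_x, d=system.lateral_pitch_um)
    v = 2.0 * np.pi * np.fft.fftfreq(m_z_eff, d=dz_pitch)
    spec = np.fft.fft2(image.data)
    spec = spec * np.exp(1j * v * shift.dz_um)[:, np.newaxis]
    spec = spec * np.exp(1j * u * shift.dx_um)[np.newaxis, :]
    data = np.fft.ifft2(spec)
    n_bad = int(np.ceil(abs(shift.dx_um) / system.lateral_pitch_um))
    valid = image.valid_columns.copy()
    if n_bad:
        if shift.dx_um > 0:
            valid[max(0, system.m_x - n_bad):] = False
        else:
            valid[:n_bad] = False
    return ComplexImage(data, system, valid_columns=valid)


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def pixel_shift_baseline(image: ComplexImage, shift: ShiftVector) -> ComplexImage:
    """Nearest-integer circular roll (ties round away from zero)."""
    system = image.system
    dz_px = _round_half_away(shift.dz_um / image.axial_pitch_um)
    dx_px = _round_half_away(shift.dx_um / system.lateral_pitch_um)
    data = np.roll(image.data, shift=(-dz_px, -dx_px), axis=(0, 1))
    valid = np.roll(image.valid_columns, -dx_px)
    if dx_px > 0:
        valid[max(0, system.m_x - dx_px):] = False
    elif dx_px < 0:
        valid[: -dx_px] = False
    return ComplexImage(data, system, valid_columns=valid)


def axial_upsample(image: ComplexImage, factor: int) -> ComplexImage:
    """Increase axial sampling ``factor``-fold by zero-extending the k support.

    The k grid is padded symmetrically on both sides, which divides the
    depth pixel size by ``factor`` while leaving the sampled values of the
    underlying continuous A-scan unchanged (pointwise, the added spectral
    samples are zero).  Total physical image energy (sum |A|^2 dz) is
    preserved.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return ComplexImage(image.data.copy(), image.system,
                            valid_columns=image.valid_columns.copy())
    system = image.system
    frame = image_to_spectrum(image)
    pad = (factor - 1) * system.n_k // 2
    spec = np.concatenate(
        [
            np.zeros((system.m_x, pad), dtype=complex),
            frame.data,
            np.zeros((system.m_x, factor * system.n_k - system.n_k - pad), dtype=complex),
        ],
        axis=1,
    )
    n_k_new = factor * system.n_k
    dz_new = system.axial_pitch_um / factor
    k_min_new = system.k_grid[0] - pad * system.dk
    # reconstruct on the finer depth grid (same transform as the forward DFT)
    full = np.fft.fft(spec, axis=1)
    m = np.arange(n_k_new)
    full = full * np.exp(-2j * k_min_new * m * dz_new)[np.newaxis, :]
    kept = full[:, : factor * system.m_z].T
    return ComplexImage(kept, system, valid_columns=image.valid_columns.copy())
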