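"""Subpixel translational motion estimation between complex B-scans.

The workhorse is the single-step upsampled cross-correlation estimator: a
coarse peak is found on a 2x zero-padded correlation grid, then refined on a
kappa-fold upsampled grid restricted to a 1.5 x 1.5 pixel neighbourhood via
explicit small DFT matrix products (upsampling only where it matters, which
is orders of magnitude cheaper than a global kappa-fold FFT).  kappa = 1000
resolves shifts to a thousandth of a pixel on well-oversampled speckle.

Axial motion of a sample with a strong specular surface can instead be read
directly from the surface phase: dz = arg(sum A_T A_R*) / (2 k0), the
amplitude-weighted circular mean of the inter-frame phase change.  Repeated
volumes are handled coarse-to-fine: integer scan-direction (y) offsets from
3-D amplitude correlation of sparse sub-volumes, interpolated per B-scan,
then refined in-plane with the single-step estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .forward_model import ComplexImage
from .registration import CorrectionMode, ShiftVector, presir_register

__all__ = [
    "ShiftEstimate",
    "VolumeStack",
    "estimate_shift_2d",
    "ncc_map_bruteforce",
    "estimate_axial_from_surface",
    "cumulative_surface_motion",
    "register_volume_coarse_to_fine",
]


@dataclass(frozen=True)
class ShiftEstimate:
    """Estimated reference-to-target displacement.

    ``dz_px``/``dx_px`` are in (depth, A-line) pixels, with physical
    equivalents in um; ``dy_scans`` is the scan-direction offset for
    volumetric registration (0 for 2-D pairs); ``ncc_peak`` is the
    normalized correlation magnitude at the refined peak.
    """

    dx_px: float
    dz_px: float
    dx_um: float
    dz_um: float
    ncc_peak: float
    kappa: int
    dy_scans: int = 0

    def __post_init__(self) -> None:
        if self.ncc_peak > 1.0 + 1e-9:
            raise ValueError("normalized correlation cannot exceed 1")

    @property
    def shift_vector(self) -> ShiftVector:
        return ShiftVector(dx_um=self.dx_um, dz_um=self.dz_um)


@dataclass
class VolumeStack:
    """Repeated volumes: array (n_volumes, n_bscans, m_z, m_x) + geometry."""

    data: np.ndarray
    system: object
    scan_pitch_um: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 4:
            raise ValueError("volume stack must be 4-D (volume, bscan, z, x)")


# ---------------------------------------------------------------------------
# single-step upsampled cross-correlation
# ---------------------------------------------------------------------------

def _upsampled_dft(cross_power: np.ndarray, n_out: tuple[int, int],
                   upsample: float, offset: tuple[float, float]) -> np.ndarray:
    """Evaluate the inverse DFT of ``cross_power`` on a local fine grid.

    Returns correlation values at shifts offset + j/upsample (j = 0..n_out-1)
    along each axis, computed as two small matrix products.
    """
    n_z, n_x = cross_power.shape
    out = cross_power
    for axis, (n_o, off) in enumerate(zip(n_out, offset)):
        n = cross_power.shape[axis]
        freqs = np.fft.fftfreq(n)  # cycles per pixel
        shifts = off + np.arange(n_o) / upsample
        kernel = np.exp(2j * np.pi * np.outer(shifts, freqs))  # (n_o, n)
        out = np.tensordot(kernel, out, axes=(1, axis))
        # tensordot puts the new axis first; after both passes the order is
        # (x_axis, z_axis) -> transpose back at the end
    return out.T  # (n_out_z, n_out_x)


def _prep(data: np.ndarray, amplitude_only: bool) -> np.ndarray:
    a = np.abs(data) if amplitude_only else data
    a = a - a.mean()
    if not np.any(a):
        raise ValueError("flat image: correlation undefined")
    return a


def estimate_shift_2d(reference: ComplexImage, target: ComplexImage,
                      kappa: int = 1000, amplitude_only: bool = False,
                      axial_oversample: int = 2) -> ShiftEstimate:
    """Estimate the subpixel (dx, dz) displacement from reference to target.

    Stage 1 locates the correlation peak to half a pixel on a 2x zero-padded
    Fourier grid; stage 2 upsamples a 1.5 x 1.5 px neighbourhood of that
    peak kappa-fold with matrix-multiply DFTs.  By default the complex
    cross-correlation is used; ``amplitude_only`` correlates |A| instead.

    The kept positive-OPD image half is critically sampled along depth (its
    folded spectrum fills every axial frequency bin), which biases a
    correlation peak computed directly on it.  Both images are therefore
    axially oversampled ``axial_oversample``-fold by k-domain zero padding
    first — after which a bulk axial shift is an exact circular subpixel
    shift of the image — and the result is reported in *original* pixels.
    """
    if reference.data.shape != target.data.shape:
        raise ValueError("reference and target must share dimensions")
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    for img in (reference, target):
        a = np.abs(img.data) if amplitude_only else img.data
        if not np.any(a - a.mean()):
            raise ValueError("flat image: correlation undefined")
    axial_scale = 1
    if axial_oversample > 1 and reference.data.shape[0] == reference.system.m_z:
        from .registration import axial_upsample

        reference = axial_upsample(reference, axial_oversample)
        target = axial_upsample(target, axial_oversample)
        axial_scale = axial_oversample
    ref = _prep(reference.data, amplitude_only)
    tgt = _prep(target.data, amplitude_only)
    n_z, n_x = ref.shape
    fr = np.fft.fft2(ref)
    ft = np.fft.fft2(tgt)
    cross = ft * np.conj(fr)
    norm = np.sqrt(np.sum(np.abs(ref) ** 2) * np.sum(np.abs(tgt) ** 2))

    # stage 1: 2x upsampled correlation by zero-padding the spectrum
    pad = np.zeros((2 * n_z, 2 * n_x), dtype=complex)
    pad[n_z // 2: n_z // 2 + n_z, n_x // 2: n_x // 2 + n_x] = np.fft.fftshift(cross)
    cc2 = np.fft.ifft2(np.fft.ifftshift(pad))
    peak = np.unravel_index(np.argmax(np.abs(cc2)), cc2.shape)
    dz0 = peak[0] / 2.0 if peak[0] <= n_z else (peak[0] - 2 * n_z) / 2.0
    dx0 = peak[1] / 2.0 if peak[1] <= n_x else (peak[1] - 2 * n_x) / 2.0

    # stage 2: kappa-fold refinement in a 1.5 x 1.5 px window
    if kappa > 1:
        half = 0.75
        n_win = int(np.ceil(1.5 * kappa)) + 1
        cc = _upsampled_dft(cross, (n_win, n_win), kappa, (dz0 - half, dx0 - half))
        pz, px = np.unravel_index(np.argmax(np.abs(cc)), cc.shape)
        dz = dz0 - half + pz / kappa
        dx = dx0 - half + px / kappa
        peak_val = np.abs(cc[pz, px]) / (norm * cross.size)
    else:
        dz, dx = dz0, dx0
        # ifft2 on the 4x grid carries 1/(4 M N); undo it and the 1/(M N)
        # of the correlation theorem cancels against it up to the factor 4
        peak_val = 4.0 * np.abs(cc2[peak]) / norm

    system = reference.system
    dz /= axial_scale  # back to pre-oversampling pixels
    return ShiftEstimate(
        dx_px=float(dx),
        dz_px=float(dz),
        dx_um=float(dx) * system.lateral_pitch_um,
        dz_um=float(dz) * reference.axial_pitch_um * axial_scale,
        ncc_peak=float(min(peak_val, 1.0 + 1e-12)),
        kappa=int(kappa),
    )


def ncc_map_bruteforce(reference: ComplexImage, target: ComplexImage,
                       candidate_shifts: list[ShiftVector],
                       taper_columns: int | None = None) -> np.ndarray:
    """Normalized correlation of the reference with the registered target.

    Independent oracle for :func:`estimate_shift_2d`: each candidate shift is
    applied with the full phase-restoring corrector and the masked complex
    correlation magnitude is recorded.
    """
    out = np.empty(len(candidate_shifts))
    for i, s in enumerate(candidate_shifts):
        reg = presir_register(target, s, CorrectionMode.FULL,
                              taper_columns=taper_columns)
        m = reg.valid_columns & reference.valid_columns
        a = reference.data[:, m]
        b = reg.data[:, m]
        num = np.abs(np.vdot(a, b))
        den = np.sqrt(np.vdot(a, a).real * np.vdot(b, b).real)
        out[i] = num / den if den else np.nan
    return out


# ---------------------------------------------------------------------------
# surface-phase axial estimation
# ---------------------------------------------------------------------------

def estimate_axial_from_surface(reference: ComplexImage, target: ComplexImage,
                                surface_pixels: np.ndarray) -> float:
    """Axial displacement (um OPL) from the surface phase change.

    dz = arg( sum_surface A_T conj(A_R) ) / (2 k0): the amplitude-weighted
    circular mean of the wrapped phase change over the bright surface
    pixels.  Unambiguous only for |dz| < lambda0/4 per step; track larger
    motions with :func:`cumulative_surface_motion`.
    """
    surface_pixels = np.asarray(surface_pixels, dtype=bool)
    if not surface_pixels.any():
        raise ValueError("empty surface mask")
    prod = np.sum(target.data[surface_pixels] * np.conj(reference.data[surface_pixels]))
    return float(np.angle(prod) / (2.0 * reference.system.k0))


def cumulative_surface_motion(stack: np.ndarray, system, surface_pixels: np.ndarray) -> np.ndarray:
    """Per-frame axial motion vs frame 0 by summing per-step surface phases.

    Each consecutive step is assumed below lambda0/4 so its wrapped phase is
    unambiguous; the cumulative sum then tracks arbitrarily large motion.
    ``stack`` is (n_frames, m_z, m_x) complex.
    """
    surface_pixels = np.asarray(surface_pixels, dtype=bool)
    if not surface_pixels.any():
        raise ValueError("empty surface mask")
    sel = stack[:, surface_pixels]
    prod = np.sum(sel[1:] * np.conj(sel[:-1]), axis=1)
    steps = np.angle(prod) / (2.0 * system.k0)
    return np.concatenate([[0.0], np.cumsum(steps)])


# ---------------------------------------------------------------------------
# coarse-to-fine volumetric registration
# ---------------------------------------------------------------------------

def _ncc3d_integer_offset(ref: np.ndarray, sub: np.ndarray) -> tuple[int, int, int]:
    """Integer position of amplitude sub-volume ``sub`` inside ``ref``.

    3-D cross-correlation of zero-mean amplitudes (valid mode); returns the
    (y, z, x) offset of the best match.
    """
    a = ref - ref.mean()
    b = sub - sub.mean()
    corr = signal.fftconvolve(a, b[::-1, ::-1, ::-1], mode="valid")
    idx = np.unravel_index(np.argmax(corr), corr.shape)
    return tuple(int(i) for i in idx)


def register_volume_coarse_to_fine(
    reference: np.ndarray,
    target: np.ndarray,
    system,
    subvolume_size: int = 20,
    stride: int = 50,
    kappa: int = 1000,
    fine_halfwidth: int | None = None,
) -> list[ShiftEstimate]:
    """Per-B-scan (dx, dy, dz) of ``target`` volume against ``reference``.

    Coarse stage: sub-volumes of ``subvolume_size`` consecutive target
    B-scans, sampled every ``stride`` scans, are located in the reference
    volume by 3-D amplitude NCC, giving sparse integer scan-direction (y)
    offsets that are linearly interpolated to every B-scan.  Fine stage:
    each target B-scan is compared by the single-step estimator against the
    reference B-scans within ``fine_halfwidth`` scans of its interpolated
    position, keeping the candidate with the highest correlation.
    """
    reference = np.asarray(reference)
    target = np.asarray(target)
    if reference.shape != target.shape:
        raise ValueError("volumes must share geometry")
    n_b = target.shape[0]
    if subvolume_size > n_b:
        raise ValueError("sub-volume larger than volume")
    if fine_halfwidth is None:
        fine_halfwidth = max(1, subvolume_size // 2)

    ref_amp = np.abs(reference)
    starts = list(range(0, n_b - subvolume_size + 1, max(1, stride)))
    if starts[-1] != n_b - subvolume_size:
        starts.append(n_b - subvolume_size)
    centers, y_shifts = [], []
    for s in starts:
        sub = np.abs(target[s: s + subvolume_size])
        y_pos, _, _ = _ncc3d_integer_offset(ref_amp, sub)
        centers.append(s + (subvolume_size - 1) / 2.0)
        y_shifts.append(s - y_pos)  # displacement reference -> target in scans
    per_scan_y = np.interp(np.arange(n_b), centers, y_shifts)

    results: list[ShiftEstimate] = []
    for i in range(n_b):
        y0 = int(round(i - per_scan_y[i]))  # predicted matching ref scan
        best: ShiftEstimate | None = None
        best_j = y0
        for j in range(max(0, y0 - fine_halfwidth), min(n_b, y0 + fine_halfwidth + 1)):
            est = estimate_shift_2d(
                ComplexImage(reference[j], system),
                ComplexImage(target[i], system),
                kappa=kappa,
            )
            if best is None or est.ncc_peak > best.ncc_peak:
                best, best_j = est, j
        assert best is not None
        results.append(ShiftEstimate(
            dx_px=best.dx_px, dz_px=best.dz_px,
            dx_um=best.dx_um, dz_um=best.dz_um,
            ncc_peak=best.ncc_peak, kappa=best.kappa,
            dy_scans=i - best_j,
        ))
    return results
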