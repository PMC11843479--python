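"""Phase-difference extraction and stability metrics for OCT image stacks.

The measured quantity in phase-sensitive OCT is the per-pixel phase of
A_T conj(A_R) between a target and a reference frame; for a bulk axial OPL
shift dz it equals 2 k0 dz plus a pixel-specific displacement-induced error
term.  Phase converts to optical path length as OPL = phi / (2 k0).

Two standard deviations summarize performance: sigma_s, the spatial SD of
the per-pixel OPL change at one time point (accuracy — how tightly the
pixels agree on the motion), and sigma_t, the temporal SD of one pixel's
OPL trace (sensitivity — the detectable-motion floor).  Both use the
population (1/N) normalization.  The shot-noise-limited phase noise of a
pixel with intensity SNR is about 1/sqrt(SNR) radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhaseSeries",
    "phase_difference_series",
    "unwrap_temporal",
    "phase_to_opl",
    "spatial_sd",
    "temporal_sd",
    "snr_limited_sensitivity",
    "self_referenced_phase",
    "outlier_mask",
]

_NM_PER_UM = 1e3


@dataclass
class PhaseSeries:
    """Per-pixel phase traces over frames.

    ``phase`` has shape (n_frames, ...pixels); ``wrapped`` records whether
    values are still confined to (-pi, pi].  ``k0`` (rad/um) enables OPL
    conversion; ``reliable`` flags pixels whose temporal unwrapping is
    trustworthy (per-step jumps well below pi).
    """

    phase: np.ndarray
    k0: float
    wrapped: bool = True
    timestamps: np.ndarray | None = None
    reliable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.reliable is None:
            self.reliable = np.ones(self.phase.shape[1:], dtype=bool)

    @property
    def opl_nm(self) -> np.ndarray:
        return phase_to_opl(self.phase, self.k0)


def phase_difference_series(stack: np.ndarray, k0: float,
                            reference_index: int = 0) -> PhaseSeries:
    """Wrapped per-pixel phase of target x conj(reference) for every frame.

    ``stack`` is (n_frames, m_z, m_x) complex; the reference frame itself
    yields zeros exactly.
    """
    stack = np.asarray(stack)
    ref = stack[reference_index]
    phase = np.angle(stack * np.conj(ref)[np.newaxis])
    phase[reference_index] = 0.0
    return PhaseSeries(phase, k0=k0, wrapped=True)


def unwrap_temporal(series: PhaseSeries, flag_threshold: float = 0.75 * np.pi) -> PhaseSeries:
    """1-D unwrap of every pixel's trace along time.

    Idempotent on already-unwrapped input.  Pixels whose largest wrapped
    per-step jump exceeds ``flag_threshold`` are marked unreliable in the
    output (aliasing cannot be excluded there); their values are still the
    standard unwrap result.
    """
    unwrapped = np.unwrap(series.phase, axis=0)
    steps = np.diff(unwrapped, axis=0)
    reliable = series.reliable.copy()
    if steps.size:
        reliable &= np.max(np.abs(steps), axis=0) <= flag_threshold
    return PhaseSeries(unwrapped, k0=series.k0, wrapped=False,
                       timestamps=series.timestamps, reliable=reliable)


def phase_to_opl(phase_rad: np.ndarray | float, k0: float) -> np.ndarray | float:
    """OPL (nm) corresponding to a phase difference: OPL = phi / (2 k0)."""
    return phase_rad / (2.0 * k0) * _NM_PER_UM


def spatial_sd(series: PhaseSeries, frame: int,
               mask: np.ndarray | None = None) -> float:
    """Population SD (nm) of the OPL change across masked pixels at ``frame``."""
    opl = series.opl_nm[frame]
    if mask is not None:
        opl = opl[np.asarray(mask, dtype=bool)]
    return float(np.std(opl))


def temporal_sd(series: PhaseSeries, pixel: tuple | np.ndarray | None = None) -> np.ndarray | float:
    """Population SD (nm) over time of one pixel's (or every pixel's) OPL trace.

    ``pixel`` may be an index tuple, a boolean mask, or None for the full
    per-pixel map.
    """
    opl = series.opl_nm
    if pixel is None:
        return np.std(opl, axis=0)
    if isinstance(pixel, tuple):
        return float(np.std(opl[(slice(None), *pixel)]))
    mask = np.asarray(pixel, dtype=bool)
    return np.std(opl[:, mask], axis=0)


def snr_limited_sensitivity(snr_linear: float | np.ndarray, k0: float,
                            self_referenced: bool = False,
                            snr_linear_b: float | np.ndarray | None = None):
    """Shot-noise floor of the OPL measurement, in nm.

    A single pixel with intensity SNR has phase noise ~1/sqrt(SNR) rad; the
    difference of two independent pixels adds in quadrature,
    sqrt(1/SNR_a + 1/SNR_b).
    """
    snr = np.asarray(snr_linear, dtype=float)
    if np.any(snr <= 0):
        raise ValueError("SNR must be positive")
    var = 1.0 / snr
    if self_referenced:
        snr_b = snr if snr_linear_b is None else np.asarray(snr_linear_b, dtype=float)
        var = var + 1.0 / snr_b
    sigma_phi = np.sqrt(var)
    out = phase_to_opl(sigma_phi, k0)
    return float(out) if np.isscalar(snr_linear) and snr_linear_b is None else out


def self_referenced_phase(stack: np.ndarray, k0: float,
                          pixels_a: np.ndarray,
                          pixels_b: np.ndarray | tuple) -> PhaseSeries:
    """Phase of measurement pixels relative to a reference pixel group.

    Per frame, the series is arg(A(b) * conj(sum_a A(a))): the reference
    group is collapsed to its complex (hence amplitude-weighted) sum, so any
    global per-frame phase drift cancels.  ``pixels_b`` may be a boolean
    mask (traces returned per masked pixel) or an index tuple.
    """
    stack = np.asarray(stack)
    a_mask = np.asarray(pixels_a, dtype=bool)
    if not a_mask.any():
        raise ValueError("empty reference pixel set")
    ref_trace = np.sum(stack[:, a_mask], axis=1)  # (n_frames,)
    if isinstance(pixels_b, tuple):
        b = stack[(slice(None), *pixels_b)]
    else:
        b = stack[:, np.asarray(pixels_b, dtype=bool)]
    shape = (stack.shape[0],) + (1,) * (b.ndim - 1)
    phase = np.angle(b * np.conj(ref_trace).reshape(shape))
    return PhaseSeries(phase, k0=k0, wrapped=True)


def outlier_mask(stack: np.ndarray, series: PhaseSeries,
                 noise_std: float | None = None,
                 snr_threshold_db: float = 10.0,
                 mad_multiple: float = 5.0) -> np.ndarray:
    """Pixels trustworthy for phase statistics.

    Excludes (a) pixels whose mean intensity SNR is below
    ``snr_threshold_db`` — the noise power is taken from ``noise_std`` or,
    absent that, estimated from the dimmest decile of pixels — and (b)
    pixels whose OPL trace strays from the per-frame spatial median by more
    than ``mad_multiple`` scaled MADs (median absolute deviations).
    """
    stack = np.asarray(stack)
    mean_power = np.mean(np.abs(stack) ** 2, axis=0)
    if noise_std is None:
        flat = np.sort(mean_power.ravel())
        noise_power = float(np.mean(flat[: max(1, flat.size // 10)]))
    else:
        noise_power = float(noise_std) ** 2
    snr = mean_power / noise_power
    bright = snr >= 10.0 ** (snr_threshold_db / 10.0)

    opl = series.opl_nm
    # center each trace first: a pixel is an outlier for how it fluctuates,
    # not for the static offset inherited from reference-frame noise
    centered = opl - np.median(opl, axis=0, keepdims=True)
    med = np.median(centered.reshape(opl.shape[0], -1), axis=1).reshape(
        (-1,) + (1,) * (opl.ndim - 1))
    dev = np.median(np.abs(centered - med), axis=0)
    mad = np.median(np.abs(dev - np.median(dev))) * 1.4826
    floor = max(mad, 1e-12)
    consistent = dev <= np.median(dev) + mad_multiple * floor
    return bright & consistent
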