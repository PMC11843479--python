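"""Reproduction drivers: translation sweeps and sinusoidal-vibration runs.

These tie the simulator, the correctors and the metrics into the two study
designs used to characterize displacement-induced phase error:

* a quasi-static translation sweep — the sample is moved in 0.01 um steps
  up to 3 um (axially, laterally, or both) and the spatial SD of the
  per-pixel measured OPL change (sigma_s) is tracked versus displacement;
* a sinusoidal vibration — a 1 Hz, ~2.7 um peak-to-peak axial oscillation
  recorded as 600 repeated B-scans at 200 Hz, after which per-pixel
  temporal stability (sigma_t) is compared across correction methods and
  against a static acquisition.

Frames along a trajectory reuse the factorized forward model: the
wavenumber phase matrix exp(i 2 k z_j) is built once, lateral beam weights
are rebuilt only when the lateral position changes, and axial steps enter
as exact exp(i 2 k dz) spectral ramps.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .forward_model import (
    ImageStack,
    OCTSystem,
    ScattererField,
    _k_phases,
    _lateral_weights,
    _spectral_noise_std,
    generate_scatterer_field,
    reconstruct_image,
    SpectralFrame,
)
from .motion import cumulative_surface_motion
from .phase_analysis import (
    phase_difference_series,
    self_referenced_phase,
    spatial_sd,
    unwrap_temporal,
)
from .registration import (
    CorrectionMode,
    ShiftVector,
    ft_shift_baseline,
    pixel_shift_baseline,
    presir_register,
)

__all__ = [
    "ExperimentConfig",
    "SweepResult",
    "SinusoidResult",
    "build_sweep_system",
    "build_speckle_sample",
    "simulate_stack",
    "apply_correction",
    "run_translation_sweep",
    "run_sinusoid_experiment",
]

_CORRECTIONS = ("none", "pixel", "ft", "presir_full", "presir_error_only")


@dataclass
class ExperimentConfig:
    """Resolved parameters of a simulation experiment.

    Optical defaults match the phantom-grade point-scan system (axial /
    lateral FWHM 1.9 / 19.5 um, A-scan pitch = lateral FWHM / 10, scatterer
    density 5 per coherence length); extents are desk-scale.
    """

    # system
    lambda0_um: float = 0.84
    axial_fwhm_um: float = 1.9
    lateral_fwhm_um: float = 19.5
    n_k: int = 256
    m_x: int = 64
    # sample
    density_per_coherence_length: float = 5.0
    reflectivity: float = 1.0
    slab_depth_um: float = 30.0
    surface_line: bool = False
    surface_reflectivity: float = 1.0
    # motion
    motion: str = "sweep"              # "sweep" | "sinusoid"
    axial_range_um: float = 3.0
    lateral_range_um: float = 0.0
    step_um: float = 0.01
    amplitude_pp_um: float = 2.7
    frequency_hz: float = 1.0
    frame_rate_hz: float = 200.0
    n_frames: int = 600
    # processing
    correction: str = "none"
    motion_source: str = "ground_truth"  # "ground_truth" | "surface"
    noise_snr_db: float | None = None
    kappa: int = 1000
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.motion not in ("sweep", "sinusoid"):
            raise ValueError("motion must be 'sweep' or 'sinusoid'")
        if self.correction not in _CORRECTIONS:
            raise ValueError(f"correction must be one of {_CORRECTIONS}")
        if self.motion_source not in ("ground_truth", "surface"):
            raise ValueError("motion_source must be 'ground_truth' or 'surface'")
        if self.motion == "sweep" and self.step_um <= 0:
            raise ValueError("step_um must be positive")
        if min(self.axial_range_um, self.lateral_range_um) < 0:
            raise ValueError("sweep ranges must be non-negative")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def build_sweep_system(config: ExperimentConfig) -> OCTSystem:
    return OCTSystem(
        lambda0_um=config.lambda0_um,
        axial_fwhm_um=config.axial_fwhm_um,
        lateral_fwhm_um=config.lateral_fwhm_um,
        n_k=config.n_k,
        m_x=config.m_x,
    )


def build_speckle_sample(
    config: ExperimentConfig, system: OCTSystem
) -> tuple[ScattererField, dict]:
    """Scatterer slab (plus optional bright surface line) for a driver run.

    The slab spans the full imaged lateral extent with margins wide enough
    that every image column keeps full beam support throughout the largest
    programmed lateral excursion; axially it sits above the guard band with
    room for the largest axial excursion.  Returns the field and a geometry
    dict (slab bounds, margins, surface depth).
    """
    if config.motion == "sweep":
        travel_up, travel_down = config.axial_range_um, 0.0
        lateral_travel = config.lateral_range_um
    else:
        travel_up = travel_down = config.amplitude_pp_um / 2.0
        lateral_travel = 0.0
    axial_travel = max(travel_up, travel_down)
    x_img = system.m_x * system.lateral_pitch_um
    x_margin = 4.0 * system.beam_radius_um + lateral_travel
    z0 = system.guard_um + 2.0 + travel_down + (4.0 if config.surface_line else 0.0)
    z1 = z0 + config.slab_depth_um
    if z1 + travel_up > system.depth_range_um - system.guard_um:
        raise ValueError("slab plus motion range exceeds the guarded depth span")
    field = generate_scatterer_field(
        ((-x_margin, x_img + x_margin), (z0, z1)),
        config.density_per_coherence_length,
        config.reflectivity,
        seed=config.seed,
        system=system,
    )
    geometry = {"z0": z0, "z1": z1, "x_margin": x_margin,
                "axial_travel": axial_travel, "travel_up": travel_up,
                "travel_down": travel_down, "lateral_travel": lateral_travel,
                "surface_z": None}
    if config.surface_line:
        # dense specular line 4 um above the slab: the phantom surface used
        # for phase-based bulk-motion estimation
        z_s = z0 - 4.0
        spacing = system.lateral_pitch_um / 4.0
        xs = np.arange(-x_margin, x_img + x_margin, spacing)
        field = ScattererField(
            np.concatenate([field.x_um, xs]),
            np.concatenate([field.z_um, np.full(xs.size, z_s)]),
            np.concatenate([field.r, np.full(xs.size, config.surface_reflectivity)]),
            field.x_extent,
            (z_s, field.z_extent[1]),
        )
        geometry["surface_z"] = z_s
    return field, geometry


def simulate_stack(
    field: ScattererField,
    system: OCTSystem,
    dx_um: np.ndarray,
    dz_um: np.ndarray,
    noise_snr_db: float | None = None,
    seed: int | None = None,
) -> ImageStack:
    """B-scan stack of ``field`` rigidly translated along a trajectory.

    Exactly equivalent to translate-field-and-resimulate for every frame,
    but factorized: axial steps are exp(i 2 k dz) ramps on the cached
    interferogram and lateral weights are rebuilt only when dx changes.
    """
    dx_um = np.asarray(dx_um, dtype=float)
    dz_um = np.asarray(dz_um, dtype=float)
    if dx_um.shape != dz_um.shape or dx_um.ndim != 1:
        raise ValueError("dx_um and dz_um must be matching 1-D arrays")
    lo, hi = field.z_extent
    if np.any(lo + dz_um < system.guard_um) or \
       np.any(hi + dz_um > system.depth_range_um - system.guard_um):
        raise ValueError("axial trajectory leaves the guarded depth span")

    n_frames = dx_um.size
    phases = _k_phases(field, system) * field.r[np.newaxis, :]  # (n_k, J)
    spectrum = system.spectrum[:, np.newaxis]
    k = system.k_grid
    rng = np.random.default_rng(seed)
    sigma = (_spectral_noise_std(system, noise_snr_db)
             if noise_snr_db is not None else 0.0)

    stack = np.empty((n_frames, system.m_z, system.m_x), dtype=complex)
    base = None
    last_dx = None
    for t in range(n_frames):
        if base is None or dx_um[t] != last_dx:
            shifted = ScattererField(
                field.x_um + dx_um[t], field.z_um, field.r,
                (field.x_extent[0] + dx_um[t], field.x_extent[1] + dx_um[t]),
                field.z_extent)
            weights = _lateral_weights(shifted, system)     # (J, m_x)
            base = spectrum * (phases @ weights)            # (n_k, m_x)
            last_dx = dx_um[t]
        data = (base * np.exp(2j * k * dz_um[t])[:, np.newaxis]).T
        if sigma:
            noise = rng.normal(0.0, sigma, size=(*data.shape, 2))
            data = data + noise[..., 0] + 1j * noise[..., 1]
        frame = SpectralFrame(data, system, detector="analytic")
        stack[t] = reconstruct_image(frame).data
    timestamps = np.arange(n_frames, dtype=float)
    return ImageStack(stack, system, timestamps=timestamps)


def apply_correction(
    stack: ImageStack,
    dx_um: np.ndarray,
    dz_um: np.ndarray,
    method: str,
) -> ImageStack:
    """Register every frame back by its (dx, dz) with the chosen corrector."""
    if method not in _CORRECTIONS:
        raise ValueError(f"unknown correction {method!r}")
    if method == "none":
        return stack
    out = np.empty_like(stack.data)
    valid = np.ones(stack.data.shape[2], dtype=bool)
    for t in range(len(stack)):
        img = stack.frame(t)
        shift = ShiftVector(dx_um=float(dx_um[t]), dz_um=float(dz_um[t]))
        if method == "pixel":
            reg = pixel_shift_baseline(img, shift)
        elif method == "ft":
            reg = ft_shift_baseline(img, shift)
        elif method == "presir_full":
            reg = presir_register(img, shift, CorrectionMode.FULL)
        else:
            reg = presir_register(img, shift, CorrectionMode.ERROR_ONLY)
        out[t] = reg.data
        valid &= reg.valid_columns
    return ImageStack(out, stack.system, timestamps=stack.timestamps,
                      valid_columns=valid)


def _analysis_mask(system: OCTSystem, geometry: dict,
                   stack_valid: np.ndarray) -> np.ndarray:
    """Speckle pixels that stay inside the slab for the whole trajectory."""
    margin = 2.0 * system.axial_fwhm_um
    z_lo = geometry["z0"] + margin + geometry["travel_up"]
    z_hi = geometry["z1"] - margin - geometry["travel_down"]
    rows = (system.z_grid >= z_lo) & (system.z_grid <= z_hi)
    n_edge = int(np.ceil(geometry["lateral_travel"] / system.lateral_pitch_um)) + 1
    cols = stack_valid.copy()
    cols[:n_edge] = False
    cols[-n_edge:] = False
    mask = np.zeros((system.m_z, system.m_x), dtype=bool)
    mask[np.ix_(rows, cols)] = True
    return mask


@dataclass
class SweepResult:
    config: ExperimentConfig
    displacement_um: np.ndarray     # total commanded displacement per frame
    dx_um: np.ndarray
    dz_um: np.ndarray
    sigma_s_nm: np.ndarray          # spatial SD of measured OPL per frame
    endpoint_sigma_s_nm: float
    endpoint_opl_nm: np.ndarray     # per-pixel OPL change at the last frame
    mask: np.ndarray

    def save(self, output_dir: str | Path) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({
            "frame": np.arange(self.displacement_um.size),
            "displacement_um": self.displacement_um,
            "dx_um": self.dx_um,
            "dz_um": self.dz_um,
            "sigma_s_nm": self.sigma_s_nm,
        }).to_csv(out / "sweep_sigma_s.csv", index=False)
        self.config.to_yaml(out / "config.yaml")


def run_translation_sweep(config: ExperimentConfig) -> SweepResult:
    """Step the sample to its maximum excursion and track sigma_s.

    Each frame's per-pixel phase difference with the initial frame is
    unwrapped along time and converted to OPL; sigma_s(t) is the spatial SD
    over speckle pixels that remain inside the slab throughout.  With
    ``correction`` set, every frame is first registered back using the
    ground-truth commanded shift (the sweep is the corrector's oracle).
    """
    if config.motion != "sweep":
        raise ValueError("config.motion must be 'sweep'")
    system = build_sweep_system(config)
    field, geometry = build_speckle_sample(config, system)

    total = float(np.hypot(config.axial_range_um, config.lateral_range_um))
    n_steps = int(round(total / config.step_um))
    if n_steps == 0:
        # a zero-amplitude "sweep": repeated static frames (noise floor run)
        frac = np.zeros(max(config.n_frames, 2))
    else:
        frac = np.arange(n_steps + 1) / n_steps
    dx = frac * config.lateral_range_um
    dz = frac * config.axial_range_um
    noise_seed = (config.seed + 1) * 7919 % (2**31)
    stack = simulate_stack(field, system, dx, dz,
                           noise_snr_db=config.noise_snr_db, seed=noise_seed)
    corrected = apply_correction(stack, dx, dz, config.correction)

    series = unwrap_temporal(
        phase_difference_series(corrected.data, k0=system.k0, reference_index=0))
    mask = _analysis_mask(system, geometry, corrected.valid_columns)
    sigma_s = np.array([spatial_sd(series, t, mask) for t in range(len(corrected))])
    endpoint_opl = series.opl_nm[-1][mask]
    result = SweepResult(
        config=config,
        displacement_um=frac * total,
        dx_um=dx,
        dz_um=dz,
        sigma_s_nm=sigma_s,
        endpoint_sigma_s_nm=float(sigma_s[-1]),
        endpoint_opl_nm=endpoint_opl,
        mask=mask,
    )
    if config.output_dir is not None:
        result.save(config.output_dir)
    return result


@dataclass
class SinusoidResult:
    config: ExperimentConfig
    time_s: np.ndarray
    dz_true_um: np.ndarray
    dz_est_um: np.ndarray
    sigma_t_nm: dict                 # method -> per-pixel sigma_t array
    static_sigma_t_nm: np.ndarray    # noise floor from a static acquisition
    mask: np.ndarray

    def save(self, output_dir: str | Path) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table = {m: v for m, v in self.sigma_t_nm.items()}
        table["static"] = self.static_sigma_t_nm
        pd.DataFrame(table).to_csv(out / "sinusoid_sigma_t.csv", index=False)
        pd.DataFrame({
            "time_s": self.time_s,
            "dz_true_um": self.dz_true_um,
            "dz_est_um": self.dz_est_um,
        }).to_csv(out / "sinusoid_motion.csv", index=False)
        self.config.to_yaml(out / "config.yaml")


def run_sinusoid_experiment(
    config: ExperimentConfig,
    methods: tuple[str, ...] = ("pixel", "ft", "presir_full"),
    include_static: bool = True,
) -> SinusoidResult:
    """Vibrate the sample axially and compare per-pixel phase stability.

    The bulk trajectory is a sinusoid (frequency, peak-to-peak amplitude and
    frame rate from the config); axial motion is estimated per frame from
    the surface phase (or taken as ground truth), each corrector registers
    the stack, the speckle phase is self-referenced against the surface, and
    sigma_t is computed per speckle pixel.  A static acquisition with
    identical noise statistics provides the sensitivity floor.
    """
    if config.motion != "sinusoid":
        raise ValueError("config.motion must be 'sinusoid'")
    cfg = config
    system = build_sweep_system(cfg)
    if not cfg.surface_line:
        raise ValueError("sinusoid driver requires surface_line=True "
                         "(the surface provides motion and phase reference)")
    field, geometry = build_speckle_sample(cfg, system)

    t = np.arange(cfg.n_frames) / cfg.frame_rate_hz
    dz_true = cfg.amplitude_pp_um / 2.0 * np.sin(2.0 * np.pi * cfg.frequency_hz * t)
    dx = np.zeros_like(dz_true)
    noise_seed = (cfg.seed + 1) * 104729 % (2**31)
    stack = simulate_stack(field, system, dx, dz_true,
                           noise_snr_db=cfg.noise_snr_db, seed=noise_seed)

    surf_row = int(round(geometry["surface_z"] / system.axial_pitch_um))
    surface = np.zeros((system.m_z, system.m_x), dtype=bool)
    surface[surf_row - 1: surf_row + 2, :] = True

    if cfg.motion_source == "surface":
        dz_est = cumulative_surface_motion(stack.data, system, surface)
    else:
        dz_est = dz_true.copy()

    mask = _analysis_mask(system, geometry, stack.valid_columns)

    def _sigma_t(images: ImageStack) -> np.ndarray:
        series = unwrap_temporal(
            self_referenced_phase(images.data, system.k0, surface, mask))
        return np.std(series.opl_nm, axis=0)

    sigma_t: dict[str, np.ndarray] = {}
    for method in methods:
        corrected = apply_correction(stack, dx, dz_est, method)
        sigma_t[method] = _sigma_t(corrected)

    if include_static:
        static_stack = simulate_stack(
            field, system, dx, np.zeros_like(dz_true),
            noise_snr_db=cfg.noise_snr_db,
            seed=(cfg.seed + 2) * 104729 % (2**31))
        static_sigma = _sigma_t(static_stack)
    else:
        static_sigma = np.full(int(mask.sum()), np.nan)

    result = SinusoidResult(
        config=cfg,
        time_s=t,
        dz_true_um=dz_true,
        dz_est_um=np.asarray(dz_est),
        sigma_t_nm=sigma_t,
        static_sigma_t_nm=static_sigma,
        mask=mask,
    )
    if cfg.output_dir is not None:
        result.save(cfg.output_dir)
    return result
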