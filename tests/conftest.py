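"""Shared fixtures: a compact OCT system and fully developed speckle scenes.

Everything is generated at test time from seeds; session scope keeps the
forward-model work (the expensive part) to one evaluation per object.
"""

from __future__ import annotations

import numpy as np
import pytest

from presir import (
    ComplexImage,
    OCTSystem,
    generate_scatterer_field,
    reconstruct_image,
    simulate_interferogram,
)
from presir.registration import (
    axial_shift,
    image_to_spectrum,
    lateral_shift,
    spectrum_to_image,
)


@pytest.fixture(scope="session")
def system() -> OCTSystem:
    """Phantom-grade optics (1.9 / 19.5 um FWHM) on a compact grid."""
    return OCTSystem(n_k=256, m_x=48)


@pytest.fixture(scope="session")
def speckle_field(system):
    """Dense scatterer slab covering the image plus beam-support margins."""
    g = system.guard_um
    x_hi = system.m_x * system.lateral_pitch_um
    margin = 4.0 * system.beam_radius_um + 5.0
    return generate_scatterer_field(
        ((-margin, x_hi + margin), (g + 5.0, g + 25.0)),
        density_per_coherence_length=5.0,
        reflectivity=1.0,
        seed=11,
        system=system,
    )


@pytest.fixture(scope="session")
def speckle_image(system, speckle_field) -> ComplexImage:
    return reconstruct_image(simulate_interferogram(speckle_field, system))


@pytest.fixture(scope="session")
def tiny_field(system):
    """Sparse field small enough for the analytic superposition oracle."""
    g = system.guard_um
    return generate_scatterer_field(
        ((10.0, 50.0), (g + 6.0, g + 16.0)),
        density_per_coherence_length=5.0,
        reflectivity=1.0,
        seed=7,
        system=system,
    )


def make_planted_target(image: ComplexImage, dx_px: float, dz_px: float) -> ComplexImage:
    """Target displaced from ``image`` by an exact (circular) translation.

    Applies the inverse phase-restoring operators with the untapered
    (exactly invertible) lateral variant, so the pair is related by a true
    band-limited shift — the construction under which subpixel estimators
    are meaningfully benchmarked against ground truth.
    """
    system = image.system
    dz_um = dz_px * system.axial_pitch_um
    dx_um = dx_px * system.lateral_pitch_um
    frame = axial_shift(image_to_spectrum(image), -dz_um, "full")
    out = spectrum_to_image(frame)
    out = lateral_shift(out, -dx_um, taper_columns=0)
    return ComplexImage(out.data, system)
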