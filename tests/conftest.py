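"""Shared fixtures: small phantoms and protocols that keep the suite fast."""

from __future__ import annotations

import numpy as np
import pytest

from dwiphantom.acquisition import AcquisitionProtocol, simulate_scan, simulate_series
from dwiphantom.phantom import PhantomSpec, build_phantom, compact_phantom


def clean_protocol(n_repeats: int = 1, **overrides) -> AcquisitionProtocol:
    """Noiseless, undistorted, temperature-stable protocol at 20 °C."""
    kwargs = dict(
        noise_sigma=0.0,
        blur_fwhm=0.0,
        pe_shift=0.0,
        n_repeats=n_repeats,
        temperature_schedule=(20.0,) * n_repeats,
        couple_adc_to_temperature=False,
    )
    kwargs.update(overrides)
    return AcquisitionProtocol(**kwargs)


@pytest.fixture(scope="session")
def compact_grids():
    """Compact six-lesion phantom at its 1.0 mm native pixel."""
    return build_phantom(compact_phantom(), "lesion_insert")


@pytest.fixture(scope="session")
def compact_grids_05():
    """Compact six-lesion phantom rasterized at the 0.5 mm analysis pixel."""
    return build_phantom(compact_phantom(pixel_size_native=0.5), "lesion_insert")


@pytest.fixture(scope="session")
def clean_scan_05(compact_grids_05):
    """One noiseless, undistorted (b0, b1000) pair on the analysis grid."""
    return simulate_scan(compact_grids_05, clean_protocol(), repeat_index=0, seed=0)


@pytest.fixture(scope="session")
def uniform_grids():
    """Small homogeneous gray-matter disk for noise statistics."""
    spec = PhantomSpec(cylinder_diameter=40.0, lesions=(), pixel_size_native=1.0)
    return build_phantom(spec, "GM_control")


@pytest.fixture(scope="session")
def noisy_series(compact_grids):
    """A short noisy series with all imperfections enabled."""
    protocol = AcquisitionProtocol(
        sequence_id="custom", noise_sigma=15.0, blur_fwhm=1.0, pe_shift=0.3,
        n_repeats=4, temperature_schedule=(21.0, 21.5, 22.0, 22.5),
    )
    return simulate_series(compact_grids, protocol, master_seed=11)
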