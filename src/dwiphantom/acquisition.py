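"""Acquisition simulator: two-b-value magnitude images with sequence-style imperfections.

The forward model per repeat is

    S_b = S0 * exp(-b * ADC_true),   S0 = proton_density * exp(-TE / T2)

followed, in order, by Gaussian blur (T2*/PSF blurring surrogate), a smooth
sinusoidal phase-encode displacement field (susceptibility-distortion
surrogate), an off-resonance amplitude loss in lesion-adjacent bands
(blade-style signal loss), and Rician noise (magnitude of complex Gaussian
noise with per-channel SD ``noise_sigma``).  High-b images may be averaged
over several independent noise draws, mirroring on-scanner averaging of
repeated excitations.

Diffusivity is optionally coupled to the phantom temperature as
ADC_eff = ADC_true * exp(c * (T - 20 °C)) with the compartment-specific
coefficient c, so the downstream temperature correction is testable
end-to-end.

The per-sequence imperfection presets (ss-EPI / rs-EPI / TGSE-BLADE) are
plausibility calibrations of these knobs, NOT fits to any particular
scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from dwiphantom.phantom import (
    LABEL_BACKGROUND,
    LABEL_LESION_BASE,
    LABEL_MATRIX,
    PhantomGrids,
)

C_RD = 0.0315  # per-°C ADC temperature coefficient, cytotoxic-edema mimic
C_GM = 0.0297  # per-°C, gray-matter mimic
T_REF = 20.0  # °C


def _default_temperatures(n_repeats: int) -> tuple[float, ...]:
    """Phantom warming across a session: 21 °C at the first scan, 22.5 °C at the last."""
    if n_repeats == 1:
        return (21.0,)
    return tuple(np.round(np.linspace(21.0, 22.5, n_repeats), 3))


@dataclass(frozen=True)
class AcquisitionProtocol:
    """One sequence's acquisition settings and imperfection model."""

    sequence_id: str = "custom"
    b_values: tuple[float, ...] = (0.0, 1000.0)
    te: float = 80.0  # ms
    n_averages_b1000: int = 1
    noise_sigma: float = 0.0  # per-channel complex-Gaussian SD, signal units
    blur_fwhm: float = 0.0  # mm
    pe_shift: float = 0.0  # mm, displacement-field amplitude along phase encode
    amplitude_loss: float = 0.0  # fractional loss in lesion-adjacent bands
    n_repeats: int = 10
    temperature_schedule: tuple[float, ...] | None = None
    couple_adc_to_temperature: bool = True

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_averages_b1000 < 1:
            raise ValueError("n_averages_b1000 must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0.0 <= self.amplitude_loss < 1.0:
            raise ValueError("amplitude_loss must be in [0, 1)")
        if len(self.b_values) < 2:
            raise ValueError("need at least two b-values")
        sched = self.temperature_schedule
        if sched is None:
            object.__setattr__(
                self, "temperature_schedule", _default_temperatures(self.n_repeats)
            )
        elif len(sched) != self.n_repeats:
            raise ValueError(
                f"temperature_schedule has {len(sched)} entries for {self.n_repeats} repeats"
            )
        else:
            object.__setattr__(self, "temperature_schedule", tuple(float(t) for t in sched))


_PRESETS = {
    # Imperfection magnitudes ordered by the sequences' known artifact
    # behavior: ss-EPI worst distortion/blur (12 high-b averages to match scan
    # time), rs-EPI small distortion, TGSE-BLADE smallest shift but local
    # amplitude loss.  Echo times follow the protocol table; noise scales are
    # chosen to land repeat-series SNR in the tens.
    "ssEPI": dict(te=85.0, n_averages_b1000=12, noise_sigma=55.0, blur_fwhm=2.0,
                  pe_shift=1.0, amplitude_loss=0.0,
                  temperature_schedule=None),
    "rsEPI": dict(te=60.0, n_averages_b1000=1, noise_sigma=16.0, blur_fwhm=1.2,
                  pe_shift=0.3, amplitude_loss=0.0,
                  temperature_schedule=None),
    "TGSE_BLADE": dict(te=48.0, n_averages_b1000=1, noise_sigma=18.0, blur_fwhm=1.5,
                       pe_shift=0.1, amplitude_loss=0.12,
                       temperature_schedule=None),
}

# Session temperature windows per sequence (scanned back-to-back, warming phantom).
_PRESET_TEMPS = {
    "ssEPI": (21.0, 22.0),
    "rsEPI": (22.0, 22.5),
    "TGSE_BLADE": (22.5, 22.5),
}


def sequence_preset(sequence_id: str, n_repeats: int = 10, **overrides) -> AcquisitionProtocol:
    """Named imperfection preset for one of the three compared sequences."""
    if sequence_id not in _PRESETS:
        raise KeyError(f"unknown sequence preset {sequence_id!r}; have {sorted(_PRESETS)}")
    kwargs = dict(_PRESETS[sequence_id])
    lo, hi = _PRESET_TEMPS[sequence_id]
    kwargs["temperature_schedule"] = tuple(
        np.round(np.linspace(lo, hi, n_repeats), 3)
    ) if n_repeats > 1 else (lo,)
    kwargs.update(overrides)
    return AcquisitionProtocol(sequence_id=sequence_id, n_repeats=n_repeats, **kwargs)


@dataclass(frozen=True)
class ImageVolume:
    """One magnitude image (single slice)."""

    pixels: np.ndarray  # 2-D, nonnegative
    pixel_size: float  # mm
    b_value: float  # s/mm²
    repeat_index: int = 0
    temperature: float = T_REF  # °C

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if np.any(self.pixels < 0):
            raise ValueError("magnitude pixels must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass(frozen=True)
class ScanSeries:
    """n_repeats acquisitions of (b0, b1000) pairs plus ground truth."""

    protocol: AcquisitionProtocol
    repeats: tuple[tuple[ImageVolume, ImageVolume], ...]
    ground_truth: PhantomGrids

    def __post_init__(self) -> None:
        if len(self.repeats) != self.protocol.n_repeats:
            raise ValueError("series length does not match protocol.n_repeats")

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    def b0_stack(self) -> np.ndarray:
        return np.stack([pair[0].pixels for pair in self.repeats])

    def b1000_stack(self) -> np.ndarray:
        return np.stack([pair[1].pixels for pair in self.repeats])

    @property
    def temperatures(self) -> tuple[float, ...]:
        return tuple(pair[1].temperature for pair in self.repeats)


def _temperature_coefficient_map(grids: PhantomGrids) -> np.ndarray:
    """Per-pixel ADC temperature coefficient: c_rd in lesions/RD, c_gm in GM matrix."""
    c = np.zeros_like(grids.adc)
    if grids.compartment_kind == "RD_control":
        c[grids.labels == LABEL_MATRIX] = C_RD
    else:
        c[grids.labels == LABEL_MATRIX] = C_GM
    c[grids.labels >= LABEL_LESION_BASE] = C_RD
    return c


def _pe_displacement_field(shape: tuple[int, int], amplitude_mm: float,
                           pixel_size: float) -> np.ndarray:
    """Smooth sinusoidal displacement (pixels) along the phase-encode (row) axis.

    The displacement varies with the frequency-encode coordinate so that round
    objects shear/stretch the way susceptibility distortion deforms them,
    without simulating field-map physics.
    """
    n_rows, n_cols = shape
    cols = np.arange(n_cols)
    disp_px = (amplitude_mm / pixel_size) * np.sin(2 * np.pi * cols / max(n_cols - 1, 1))
    return np.broadcast_to(disp_px, shape)


def _apply_pe_shift(image: np.ndarray, amplitude_mm: float, pixel_size: float) -> np.ndarray:
    if amplitude_mm == 0:
        return image
    rows, cols = np.indices(image.shape, dtype=float)
    disp = _pe_displacement_field(image.shape, amplitude_mm, pixel_size)
    return ndimage.map_coordinates(image, [rows + disp, cols], order=1, mode="nearest")


def _lesion_adjacent_band(grids: PhantomGrids, width_mm: float = 2.0) -> np.ndarray:
    """Ring around each lesion where blade-style off-resonance loss applies."""
    lesion_mask = grids.labels >= LABEL_LESION_BASE
    if not lesion_mask.any():
        return np.zeros(grids.shape, dtype=bool)
    width_px = max(int(round(width_mm / grids.pixel_size)), 1)
    dilated = ndimage.binary_dilation(lesion_mask, iterations=width_px)
    return dilated  # lesion + surrounding band

def _rician(rng: np.random.Generator, signal: np.ndarray, sigma: float) -> np.ndarray:
    """Magnitude of (signal + n_re) + i*n_im with n ~ N(0, sigma) per channel."""
    if sigma == 0:
        return signal.copy()
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def noiseless_signal(grids: PhantomGrids, protocol: AcquisitionProtocol,
                     b_value: float, temperature: float) -> np.ndarray:
    """Distortion-free, noise-free magnitude signal at one b-value."""
    adc = grids.adc
    if protocol.couple_adc_to_temperature and temperature != T_REF:
        c = _temperature_coefficient_map(grids)
        adc = adc * np.exp(c * (temperature - T_REF))
    with np.errstate(divide="ignore", invalid="ignore"):
        s0 = np.where(grids.t2 > 0,
                      grids.proton_density * np.exp(-protocol.te / np.maximum(grids.t2, 1e-12)),
                      0.0)
    return s0 * np.exp(-b_value * adc)


def simulate_scan(
    grids: PhantomGrids,
    protocol: AcquisitionProtocol,
    repeat_index: int = 0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[ImageVolume, ImageVolume]:
    """Simulate one repeat: a (b0, b_high) magnitude image pair.

    The high-b image is the mean of ``n_averages_b1000`` independent Rician
    noise draws of the same distorted noiseless image.  Deterministic given
    the seed.
    """
    if not 0 <= repeat_index < protocol.n_repeats:
        raise ValueError(f"repeat_index {repeat_index} outside 0..{protocol.n_repeats - 1}")
    temperature = protocol.temperature_schedule[repeat_index]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    b_low, b_high = min(protocol.b_values), max(protocol.b_values)
    volumes: list[ImageVolume] = []
    for b in (b_low, b_high):
        clean = noiseless_signal(grids, protocol, b, temperature)
        if protocol.blur_fwhm > 0:
            sigma_px = protocol.blur_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / grids.pixel_size
            clean = ndimage.gaussian_filter(clean, sigma_px, mode="nearest")
        clean = _apply_pe_shift(clean, protocol.pe_shift, grids.pixel_size)
        if protocol.amplitude_loss > 0:
            band = _lesion_adjacent_band(grids)
            clean = np.where(band, clean * (1.0 - protocol.amplitude_loss), clean)
        n_avg = protocol.n_averages_b1000 if b == b_high else 1
        acc = np.zeros_like(clean)
        for _ in range(n_avg):
            acc += _rician(rng, clean, protocol.noise_sigma)
        volumes.append(
            ImageVolume(
                pixels=acc / n_avg,
                pixel_size=grids.pixel_size,
                b_value=b,
                repeat_index=repeat_index,
                temperature=temperature,
            )
        )
    return volumes[0], volumes[1]


def simulate_series(
    grids: PhantomGrids,
    protocol: AcquisitionProtocol,
    master_seed: int = 0,
) -> ScanSeries:
    """Simulate the full repeat series with deterministically derived per-repeat seeds."""
    children = np.random.SeedSequence(master_seed).spawn(protocol.n_repeats)
    repeats = tuple(
        simulate_scan(grids, protocol, repeat_index=i, seed=children[i])
        for i in range(protocol.n_repeats)
    )
    return ScanSeries(protocol=protocol, repeats=repeats, ground_truth=grids)
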