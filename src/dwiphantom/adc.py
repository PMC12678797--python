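"""ADC mapping from a two-b-value pair and temperature correction to 20 °C.

The mono-exponential model S_b = S0 * exp(-b * ADC) inverts to

    ADC = ln(S_low / S_high) / (b_high - b_low)

Diffusion in aqueous PVP speeds up with temperature, so a measured ADC is
referred back to 20 °C via

    ADC_20 = ADC_measured / exp(c * (T_measured - 20 °C))

with compartment-specific per-°C coefficients (0.0315 for the
cytotoxic-edema mimic, 0.0297 for the gray-matter mimic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dwiphantom.acquisition import C_GM, C_RD, T_REF, ImageVolume
from dwiphantom.roi import ROISpec, rasterize_roi


@dataclass(frozen=True)
class CorrectionConstants:
    """Temperature-correction coefficients (per °C) and reference temperature."""

    c_rd: float = C_RD
    c_gm: float = C_GM
    t_ref: float = T_REF

    def __post_init__(self) -> None:
        if self.c_rd <= 0 or self.c_gm <= 0:
            raise ValueError("correction coefficients must be > 0")

    def for_compartment(self, kind: str) -> float:
        """Coefficient by ROI compartment: lesions and RD control use c_rd, GM uses c_gm."""
        if kind in ("lesion", "RD_control"):
            return self.c_rd
        if kind in ("GM_control", "GM_background"):
            return self.c_gm
        raise KeyError(f"unknown compartment kind {kind!r}")


@dataclass(frozen=True)
class ADCMap:
    values: np.ndarray  # mm²/s; NaN where signal was invalid
    valid: np.ndarray  # bool, False where S <= 0 at either b-value
    pixel_size: float  # mm
    b_pair: tuple[float, float]
    temperature: float  # °C at acquisition
    corrected: bool = False

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())


def compute_adc_map(b_low: ImageVolume, b_high: ImageVolume) -> ADCMap:
    """Per-pixel ADC from a low/high b-value magnitude pair.

    Pixels where either magnitude is <= 0 are flagged invalid (NaN): the log
    signal model is undefined there (air background, noise floor zeros).
    """
    if b_low.pixels.shape != b_high.pixels.shape:
        raise ValueError("b-value images must share the same grid")
    if not np.isclose(b_low.pixel_size, b_high.pixel_size):
        raise ValueError("b-value images must share pixel size")
    if not b_low.b_value < b_high.b_value:
        raise ValueError(
            f"need b_low < b_high, got {b_low.b_value} and {b_high.b_value}"
        )
    delta_b = b_high.b_value - b_low.b_value
    valid = (b_low.pixels > 0) & (b_high.pixels > 0)
    values = np.full(b_low.pixels.shape, np.nan)
    values[valid] = np.log(b_low.pixels[valid] / b_high.pixels[valid]) / delta_b
    return ADCMap(
        values=values,
        valid=valid,
        pixel_size=b_low.pixel_size,
        b_pair=(b_low.b_value, b_high.b_value),
        temperature=b_high.temperature,
    )


def correct_adc_temperature(adc, t_measured: float, c: float):
    """ADC referred to 20 °C: adc / exp(c * (T - 20)).  Accepts scalars or arrays."""
    if c <= 0:
        raise ValueError("correction coefficient c must be > 0")
    return adc / np.exp(c * (t_measured - T_REF))


@dataclass(frozen=True)
class ROIADCSummary:
    """Temperature-corrected ADC statistics over a repeat series, in 1e-3 mm²/s."""

    roi_label: str
    per_repeat_mean: tuple[float, ...]  # corrected, 1e-3 mm²/s
    mean: float
    sd: float
    min: float
    max: float
    n_invalid_pixels: int


def adc_roi_summary(
    adc_maps: list[ADCMap],
    roi: ROISpec,
    constants: CorrectionConstants | None = None,
    compartment_kind: str = "lesion",
) -> ROIADCSummary:
    """Corrected ROI-mean ADC per repeat, summarized over the series.

    Each repeat's ROI mean is corrected with that repeat's temperature and the
    compartment's coefficient, then aggregated.  Values are reported in units
    of 1e-3 mm²/s.  Invalid pixels are excluded and counted.
    """
    if not adc_maps:
        raise ValueError("need at least one ADC map")
    constants = constants or CorrectionConstants()
    c = constants.for_compartment(compartment_kind)

    first = adc_maps[0]
    rows, cols = rasterize_roi(roi, first.values.shape, first.pixel_size)
    per_repeat = []
    n_invalid = 0
    for amap in adc_maps:
        vals = amap.values[rows, cols]
        ok = np.isfinite(vals)
        n_invalid += int((~ok).sum())
        if not ok.any():
            raise ValueError(f"ROI {roi.label!r} has no valid pixels in one repeat")
        mean_raw = float(vals[ok].mean())
        corrected = correct_adc_temperature(mean_raw, amap.temperature, c)
        per_repeat.append(corrected * 1e3)

    arr = np.asarray(per_repeat)
    return ROIADCSummary(
        roi_label=roi.label,
        per_repeat_mean=tuple(arr.tolist()),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        min=float(arr.min()),
        max=float(arr.max()),
        n_invalid_pixels=n_invalid,
    )
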