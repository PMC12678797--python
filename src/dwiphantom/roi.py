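"""Circular ROI machinery and the repeat-series intensity metrics.

The noise term of both SNR and CNR is the *temporal* standard deviation:
each ROI pixel's SD across the repeated scans, averaged over the ROI.  This
avoids the bias of background-region noise estimates under multi-channel
coils with parallel imaging, where noise is spatially non-uniform.

    SNR_mult = mean_i [ SI_ROI(i) / SD_ROI(mult) ]
    CNR_mult = mean_i [ (SI_ROI(i) - SI_GM(i)) / SD_GM(mult) ]
    ReCon    = (SI_ROI - SI_GM) / (SI_ROI + SI_GM)

where i indexes repeats, SI_ROI(i) is the ROI mean in repeat i, and SD_* is
the mean voxel-wise temporal SD (sample SD, n-1 denominator).  The four
background (GM) ROIs are pooled at the pixel level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from dwiphantom.phantom import PhantomGrids

# analysis defaults: in-paper ROI volumes (mm³) per lesion diameter (mm)
LESION_ROI_VOLUMES = {10.0: 74.0, 7.0: 36.0, 5.0: 21.0, 4.0: 12.0, 3.0: 5.0, 2.0: 4.0}
CONTROL_ROI_VOLUME = 74.0
BACKGROUND_ROI_VOLUME = 170.0


class DegenerateSeriesError(ValueError):
    """Raised when a noise metric is undefined (zero temporal SD: noiseless input)."""


@dataclass(frozen=True)
class ROISpec:
    """Circular ROI given by its center (mm) and through-slice volume (mm³).

    The in-plane disk area is volume / slice_thickness; radius = sqrt(area/pi).
    """

    label: str
    center: tuple[float, float]
    volume: float  # mm³
    slice_thickness: float = 3.0  # mm

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("ROI volume must be > 0")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be > 0")

    @property
    def area(self) -> float:
        return self.volume / self.slice_thickness

    @property
    def radius(self) -> float:
        return float(np.sqrt(self.area / np.pi))


def rasterize_roi(
    roi: ROISpec, shape: tuple[int, int], pixel_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices (rows, cols) whose centers fall inside the ROI disk.

    The grid shares the package-wide convention: physical origin at the
    center of the field of view, column -> +x, row -> +y.
    """
    n_rows, n_cols = shape
    cx, cy = roi.center
    row_c = cy / pixel_size + (n_rows - 1) / 2.0
    col_c = cx / pixel_size + (n_cols - 1) / 2.0
    if not (0 <= row_c <= n_rows - 1 and 0 <= col_c <= n_cols - 1):
        raise ValueError(f"ROI {roi.label!r} center {roi.center} lies outside the grid")
    r_px = roi.radius / pixel_size
    rows, cols = np.indices(shape)
    mask = (rows - row_c) ** 2 + (cols - col_c) ** 2 <= r_px**2
    if not mask.any():
        raise ValueError(
            f"ROI {roi.label!r} rasterizes to zero pixels at {pixel_size} mm spacing"
        )
    idx = np.nonzero(mask)
    return idx


@dataclass(frozen=True)
class ROISampleSeries:
    """Per-repeat pixel samples of one ROI: values shaped (n_repeats, n_pixels)."""

    roi: ROISpec
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be (n_repeats, n_pixels)")

    @property
    def n_repeats(self) -> int:
        return self.values.shape[0]

    def per_repeat_mean(self) -> np.ndarray:
        return self.values.mean(axis=1)


def extract_roi_series(stack: np.ndarray, roi: ROISpec, pixel_size: float) -> ROISampleSeries:
    """Sample a (n_repeats, H, W) image stack at the ROI pixel set."""
    rows, cols = rasterize_roi(roi, stack.shape[1:], pixel_size)
    return ROISampleSeries(roi=roi, values=stack[:, rows, cols])


def temporal_sd(series: ROISampleSeries) -> float:
    """Mean voxel-wise sample SD across repeats."""
    if series.n_repeats < 2:
        raise ValueError("temporal SD needs at least 2 repeats")
    return float(series.values.std(axis=0, ddof=1).mean())


def _pooled(background: Sequence[ROISampleSeries]) -> ROISampleSeries:
    if not background:
        raise ValueError("need at least one background ROI")
    values = np.concatenate([b.values for b in background], axis=1)
    return ROISampleSeries(roi=background[0].roi, values=values)


def snr_mult(series: ROISampleSeries, per_repeat: bool = False):
    """Repeat-series SNR: per-repeat ROI mean over the mean temporal SD, averaged.

    Raises DegenerateSeriesError for a noiseless (zero temporal SD) series.
    """
    sd = temporal_sd(series)
    if sd == 0:
        raise DegenerateSeriesError("temporal SD is zero: noiseless or duplicated repeats")
    values = series.per_repeat_mean() / sd
    return values if per_repeat else float(values.mean())


def cnr_mult(
    lesion: ROISampleSeries,
    background: Sequence[ROISampleSeries],
    per_repeat: bool = False,
):
    """Repeat-series CNR against pixel-pooled background ROIs."""
    pool = _pooled(background)
    if lesion.n_repeats != pool.n_repeats:
        raise ValueError("lesion and background series must share repeat count")
    sd_gm = temporal_sd(pool)
    if sd_gm == 0:
        raise DegenerateSeriesError("background temporal SD is zero")
    values = (lesion.per_repeat_mean() - pool.per_repeat_mean()) / sd_gm
    return values if per_repeat else float(values.mean())


def recon(si_roi: float, si_gm: float) -> float:
    """Relative contrast (SI_ROI - SI_GM) / (SI_ROI + SI_GM), in [-1, 1]."""
    denom = si_roi + si_gm
    if denom <= 0:
        raise ValueError("SI_ROI + SI_GM must be > 0")
    return (si_roi - si_gm) / denom


def recon_series(
    lesion: ROISampleSeries,
    background: Sequence[ROISampleSeries],
    per_repeat: bool = False,
):
    """Per-repeat ReCon from ROI means; series value = mean over repeats."""
    pool = _pooled(background)
    values = np.array(
        [recon(a, b) for a, b in zip(lesion.per_repeat_mean(), pool.per_repeat_mean())]
    )
    return values if per_repeat else float(values.mean())


@dataclass(frozen=True)
class MetricResult:
    """One metric for one sequence x lesion label, with per-repeat values."""

    metric: str  # ADC20 | SNR | CNR | ReCon | GDR
    sequence_id: str
    lesion_label: str
    per_repeat_values: tuple[float, ...]
    mean: float
    sd: float
    min: float
    max: float

    @classmethod
    def from_values(cls, metric: str, sequence_id: str, lesion_label: str,
                    values: Iterable[float]) -> "MetricResult":
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0 or not np.isfinite(arr).all():
            return cls(metric, sequence_id, lesion_label, tuple(arr.tolist()),
                       float("nan"), float("nan"), float("nan"), float("nan"))
        return cls(
            metric, sequence_id, lesion_label, tuple(arr.tolist()),
            mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            min=float(arr.min()),
            max=float(arr.max()),
        )


def default_rois(grids: PhantomGrids, include_2mm: bool = False) -> dict:
    """Analysis ROI set for a lesion-insert slice.

    Lesion ROIs sit at the ground-truth lesion centers with the standard
    per-diameter volumes; a 74 mm³ GM control ROI sits in lesion-free matrix;
    four ~170 mm³ GM background ROIs flank the lesion row (their exact
    placement is a free choice of the analysis, kept clear of every lesion).
    """
    t = grids.slice_thickness
    lesion_rois = []
    for lesion in grids.lesions:
        if lesion.diameter == 2.0 and not include_2mm:
            continue
        volume = LESION_ROI_VOLUMES.get(lesion.diameter, np.pi * lesion.radius**2 * t * 0.75)
        lesion_rois.append(
            ROISpec(label=f"{lesion.diameter:g}mm", center=lesion.center,
                    volume=volume, slice_thickness=t)
        )
    gm_control = ROISpec("GM_control", (0.0, 20.0), CONTROL_ROI_VOLUME, t)
    background = [
        ROISpec(f"GM_background_{k}", center, BACKGROUND_ROI_VOLUME, t)
        for k, center in enumerate([(-12.0, -11.0), (12.0, -11.0),
                                    (-12.0, 11.0), (12.0, 11.0)], start=1)
    ]
    return {"lesions": lesion_rois, "gm_control": gm_control, "background": background}


def metric_table(
    series_by_sequence: dict,
    rois: dict | None = None,
    include_2mm: bool = False,
    gdr_sample_step: float | None = None,
) -> list[MetricResult]:
    """All five metrics for every sequence x lesion, plus pooled "all" rows.

    ``series_by_sequence`` maps sequence id -> ScanSeries (b1000 analysis on
    the high-b stack; ADC from each b0/b1000 pair).  Degenerate noise metrics
    (noiseless series) yield NaN summaries rather than failing the table.
    """
    from dwiphantom.adc import CorrectionConstants, adc_roi_summary, compute_adc_map
    from dwiphantom.gdr import estimate_diameter, gdr as gdr_rate, radial_mean_profile

    results: list[MetricResult] = []
    for seq_id, series in series_by_sequence.items():
        grids = series.ground_truth
        roi_set = rois or default_rois(grids, include_2mm=include_2mm)
        first_pixel = series.repeats[0][1].pixel_size
        stack = series.b1000_stack()
        bg_series = [extract_roi_series(stack, b, first_pixel) for b in roi_set["background"]]
        adc_maps = [compute_adc_map(b0, b1000) for b0, b1000 in series.repeats]
        constants = CorrectionConstants()

        by_lesion: dict[str, dict[str, list[float]]] = {}
        lesion_by_label = {f"{l.diameter:g}mm": l for l in grids.lesions}
        for roi in roi_set["lesions"]:
            lesion = lesion_by_label[roi.label]
            roi_series = extract_roi_series(stack, roi, first_pixel)
            vals: dict[str, list[float]] = {}

            adc_summary = adc_roi_summary(adc_maps, roi, constants, "lesion")
            vals["ADC20"] = list(adc_summary.per_repeat_mean)
            try:
                vals["SNR"] = list(snr_mult(roi_series, per_repeat=True))
            except DegenerateSeriesError:
                vals["SNR"] = [float("nan")]
            try:
                vals["CNR"] = list(cnr_mult(roi_series, bg_series, per_repeat=True))
            except DegenerateSeriesError:
                vals["CNR"] = [float("nan")]
            vals["ReCon"] = list(recon_series(roi_series, bg_series, per_repeat=True))

            step = gdr_sample_step if gdr_sample_step is not None else first_pixel / 2.0
            gdr_vals = []
            for _, b1000 in series.repeats:
                profile = radial_mean_profile(
                    b1000, lesion.center,
                    profile_halflength=1.5 * lesion.diameter,
                    sample_step=step,
                )
                est = estimate_diameter(profile)
                gdr_vals.append(gdr_rate(est.d_dwi, lesion.diameter))
            vals["GDR"] = gdr_vals

            by_lesion[roi.label] = vals
            for metric, v in vals.items():
                results.append(MetricResult.from_values(metric, seq_id, roi.label, v))

        # pooled "all" row per metric (all lesion sizes, all repeats)
        for metric in ("ADC20", "SNR", "CNR", "ReCon", "GDR"):
            pooled: list[float] = []
            for vals in by_lesion.values():
                pooled.extend(vals[metric])
            results.append(MetricResult.from_values(metric, seq_id, "all", pooled))
    return results


def metrics_to_frame(results: Sequence[MetricResult]) -> pd.DataFrame:
    """Tidy long-format table: one row per metric x sequence x lesion x repeat."""
    rows = []
    for r in results:
        for i, v in enumerate(r.per_repeat_values):
            rows.append(dict(metric=r.metric, sequence=r.sequence_id,
                             lesion=r.lesion_label, repeat=i, value=v))
    return pd.DataFrame(rows)


def summary_to_frame(results: Sequence[MetricResult]) -> pd.DataFrame:
    rows = [dict(metric=r.metric, sequence=r.sequence_id, lesion=r.lesion_label,
                 mean=r.mean, sd=r.sd, min=r.min, max=r.max) for r in results]
    return pd.DataFrame(rows)
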