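"""NIfTI-1 serialization of image volumes and ADC maps with JSON sidecars.

Each 2-D volume is written as a single-slice NIfTI with the in-plane pixel
size and slice thickness on the affine diagonal; acquisition metadata that
NIfTI cannot carry (b-value, repeat index, temperature, correction state)
goes into a sidecar JSON next to the image file.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from dwiphantom.acquisition import AcquisitionProtocol, ImageVolume, ScanSeries
from dwiphantom.adc import ADCMap


def _affine(pixel_size: float, slice_thickness: float = 3.0) -> np.ndarray:
    return np.diag([pixel_size, pixel_size, slice_thickness, 1.0])


def write_volume(vol: ImageVolume, path: Path, slice_thickness: float = 3.0) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(vol.pixels[:, :, None].astype(np.float32),
                          _affine(vol.pixel_size, slice_thickness))
    nib.save(img, str(path))
    sidecar = {
        "b_value": vol.b_value,
        "repeat_index": vol.repeat_index,
        "temperature_celsius": vol.temperature,
        "pixel_size_mm": vol.pixel_size,
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return path


def read_volume(path: Path) -> ImageVolume:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise ValueError("expected a single-slice volume")
        data = data[:, :, 0]
    pixel_size = float(img.affine[0, 0])
    meta = {}
    sidecar = path.with_suffix("").with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ImageVolume(
        pixels=np.maximum(data, 0.0),
        pixel_size=meta.get("pixel_size_mm", pixel_size),
        b_value=meta.get("b_value", 0.0),
        repeat_index=meta.get("repeat_index", 0),
        temperature=meta.get("temperature_celsius", 20.0),
    )


def write_adc_map(amap: ADCMap, path: Path, slice_thickness: float = 3.0) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(amap.values[:, :, None].astype(np.float32),
                          _affine(amap.pixel_size, slice_thickness))
    nib.save(img, str(path))
    sidecar = {
        "b_pair": list(amap.b_pair),
        "temperature_celsius": amap.temperature,
        "corrected": amap.corrected,
        "units": "mm^2/s",
        "n_invalid_pixels": amap.n_invalid,
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return path


def write_series(series: ScanSeries, out_dir: Path, name: str,
                 master_seed: int | None = None) -> Path:
    """One NIfTI per repeat per b-value plus a series-level sidecar.

    The sidecar records the protocol, the per-repeat temperatures, the master
    seed, and the ground-truth lesion table so a saved series is
    self-describing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    proto = series.protocol
    for i, (b0, b1000) in enumerate(series.repeats):
        write_volume(b0, out_dir / f"{name}_rep{i:02d}_b0.nii",
                     series.ground_truth.slice_thickness)
        write_volume(b1000, out_dir / f"{name}_rep{i:02d}_b{int(b1000.b_value)}.nii",
                     series.ground_truth.slice_thickness)
    sidecar = {
        "sequence_id": proto.sequence_id,
        "b_values": list(proto.b_values),
        "te_ms": proto.te,
        "n_averages_b1000": proto.n_averages_b1000,
        "noise_sigma": proto.noise_sigma,
        "blur_fwhm_mm": proto.blur_fwhm,
        "pe_shift_mm": proto.pe_shift,
        "amplitude_loss": proto.amplitude_loss,
        "n_repeats": proto.n_repeats,
        "temperature_schedule_celsius": list(proto.temperature_schedule),
        "master_seed": master_seed,
        "lesions": [
            {"diameter_mm": l.diameter, "center_mm": list(l.center),
             "adc_true_mm2_per_s": l.adc_true}
            for l in series.ground_truth.lesions
        ],
    }
    sidecar_path = out_dir / f"{name}_series.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return sidecar_path
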