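"""Geometry and ground truth of the digital DWI phantom.

The physical object being emulated is a cylindrical phantom (height 170 mm,
diameter 150 mm) whose lesion insert embeds six circular low-ADC lesions
(cytotoxic-edema mimic, 0.5e-3 mm²/s) in a gray-matter-like PVP matrix
(0.8e-3 mm²/s).  Two further compartments are homogeneous quality-control
regions at the matrix and lesion diffusivities.  All analysis metrics are
computed on a single slice, so the phantom is rasterized as a 2-D
cross-section; slice thickness is carried as metadata for ROI volume->area
conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

# compartment label codes in the rasterized label grid
LABEL_BACKGROUND = 0
LABEL_MATRIX = 1
LABEL_LESION_BASE = 10  # lesion k -> LABEL_LESION_BASE + k

ADC_GM = 0.8e-3  # mm²/s, gray-matter mimic (31% PVP)
ADC_RD = 0.5e-3  # mm²/s, restricted-diffusion mimic (42% PVP)
T2_GM = 730.0  # ms, reported for 31% PVP
T2_RD = 544.0  # ms, reported for 42% PVP


@dataclass(frozen=True)
class LesionSpec:
    """A circular lesion in the insert.

    diameter and center are in mm (in-plane, origin at the phantom axis);
    adc_true in mm²/s.
    """

    diameter: float
    center: tuple[float, float]
    adc_true: float = ADC_RD

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"lesion diameter must be > 0, got {self.diameter}")
        if self.adc_true <= 0:
            raise ValueError("lesion ADC must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class CompartmentSpec:
    """One axial compartment of the cylinder.

    kind selects which cross-section a simulated slice shows:
    ``lesion_insert`` (matrix + lesions), ``GM_control`` / ``RD_control``
    (homogeneous disks).  The resolution insert is geometry-only here and
    rasterizes like a homogeneous matrix disk.
    """

    kind: str = "lesion_insert"
    adc_matrix: float = ADC_GM
    t2: float = T2_GM
    proton_density: float = 1000.0

    _KINDS = ("GM_control", "lesion_insert", "RD_control", "resolution_insert")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown compartment kind {self.kind!r}")
        if self.adc_matrix <= 0 or self.t2 <= 0:
            raise ValueError("adc_matrix and t2 must be > 0")


def _default_lesions() -> tuple[LesionSpec, ...]:
    """Six lesions on a horizontal line through the insert.

    The in-plane layout is not a property of the physical phantom we rely on;
    centers are spaced 1.5x the larger of each adjacent diameter pair so no
    two lesions approach each other, and the row is centered on the axis.
    """
    diameters = [10.0, 7.0, 5.0, 4.0, 3.0, 2.0]
    xs = [0.0]
    for d_prev, d_next in zip(diameters[:-1], diameters[1:]):
        xs.append(xs[-1] + 1.5 * max(d_prev, d_next))
    shift = (xs[0] + xs[-1]) / 2.0
    return tuple(
        LesionSpec(diameter=d, center=(x - shift, 0.0), adc_true=ADC_RD)
        for d, x in zip(diameters, xs)
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description; defaults reproduce the reference design."""

    cylinder_height: float = 170.0
    cylinder_diameter: float = 150.0
    compartments: tuple[CompartmentSpec, ...] = (
        CompartmentSpec("GM_control", ADC_GM, T2_GM),
        CompartmentSpec("lesion_insert", ADC_GM, T2_GM),
        CompartmentSpec("RD_control", ADC_RD, T2_RD),
        CompartmentSpec("resolution_insert", ADC_GM, T2_GM),
    )
    lesions: tuple[LesionSpec, ...] = field(default_factory=_default_lesions)
    pixel_size_native: float = 1.1
    slice_thickness: float = 3.0
    # lesion-insert compartment properties for lesion pixels' T2
    lesion_t2: float = T2_RD

    def __post_init__(self) -> None:
        if self.cylinder_diameter <= 0 or self.cylinder_height <= 0:
            raise ValueError("cylinder dimensions must be > 0")
        if self.pixel_size_native <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel size and slice thickness must be > 0")

    def compartment(self, kind: str) -> CompartmentSpec:
        for c in self.compartments:
            if c.kind == kind:
                return c
        raise KeyError(f"phantom has no {kind!r} compartment")


@dataclass(frozen=True)
class PhantomGrids:
    """Rasterized ground truth of one slice.

    Arrays are indexed [row, col]; row 0 is the most negative y.  Physical
    coordinates are in mm with the origin at the cylinder axis; column index
    maps to +x, row index to +y.  The phase-encode axis used by the
    acquisition simulator is the row (y) axis.
    """

    labels: np.ndarray  # int compartment/lesion codes
    adc: np.ndarray  # mm²/s, 0 outside the cylinder
    t2: np.ndarray  # ms, 0 outside
    proton_density: np.ndarray  # baseline, 0 outside
    pixel_size: float  # mm
    slice_thickness: float  # mm
    lesions: tuple[LesionSpec, ...]
    compartment_kind: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(y, x) physical coordinates of pixel centers, each shaped like grids."""
        n_rows, n_cols = self.labels.shape
        ys = (np.arange(n_rows) - (n_rows - 1) / 2.0) * self.pixel_size
        xs = (np.arange(n_cols) - (n_cols - 1) / 2.0) * self.pixel_size
        return np.meshgrid(ys, xs, indexing="ij")

    def mm_to_index(self, point: tuple[float, float]) -> tuple[float, float]:
        """Physical (x, y) mm -> fractional (row, col) index."""
        n_rows, n_cols = self.labels.shape
        x, y = point
        row = y / self.pixel_size + (n_rows - 1) / 2.0
        col = x / self.pixel_size + (n_cols - 1) / 2.0
        return row, col

    def lesion_mask(self, index: int) -> np.ndarray:
        return self.labels == LABEL_LESION_BASE + index


def default_phantom() -> PhantomSpec:
    """The reference six-lesion phantom."""
    return PhantomSpec()


def compact_phantom(pixel_size_native: float = 1.0) -> PhantomSpec:
    """A reduced-footprint variant for fast runs: same six lesions, 80 mm cylinder.

    The lesion layout, diffusivities and ROI geometry are unchanged; only the
    surrounding matrix is trimmed, so every metric's ground truth is identical
    to the full phantom's while grids stay small.
    """
    return PhantomSpec(cylinder_diameter=80.0, pixel_size_native=pixel_size_native)


def _check_lesions(spec: PhantomSpec) -> None:
    radius_insert = spec.cylinder_diameter / 2.0
    for i, lesion in enumerate(spec.lesions):
        cx, cy = lesion.center
        if np.hypot(cx, cy) + lesion.radius > radius_insert:
            raise ValueError(
                f"lesion {i} (d={lesion.diameter} mm at {lesion.center}) "
                "extends outside the insert"
            )
    for i, a in enumerate(spec.lesions):
        for j, b in enumerate(spec.lesions[i + 1:], start=i + 1):
            dist = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if dist < a.radius + b.radius:
                raise ValueError(f"lesions {i} and {j} overlap (center distance {dist:.2f} mm)")


def build_phantom(
    spec: PhantomSpec,
    compartment: str = "lesion_insert",
    pixel_size: float | None = None,
) -> PhantomGrids:
    """Rasterize one slice of the phantom onto a square pixel grid.

    Parameters
    ----------
    spec : phantom description.
    compartment : which axial compartment the slice cuts through.  The
        lesion insert shows matrix + lesions; control compartments are
        homogeneous disks at their own diffusivity.
    pixel_size : grid spacing in mm; defaults to ``spec.pixel_size_native``.

    Returns
    -------
    PhantomGrids with per-pixel label, true ADC, T2 and proton density.
    A pixel belongs to a lesion when its center falls inside the lesion
    circle; otherwise to the matrix if inside the cylinder cross-section.
    """
    comp = spec.compartment(compartment)
    if compartment == "lesion_insert":
        _check_lesions(spec)
        lesions = spec.lesions
    else:
        lesions = ()

    px = spec.pixel_size_native if pixel_size is None else float(pixel_size)
    if px <= 0:
        raise ValueError("pixel_size must be > 0")
    radius = spec.cylinder_diameter / 2.0
    # field of view: cylinder plus a small air margin, odd pixel count so the
    # axis lands on a pixel center
    n = int(np.ceil((spec.cylinder_diameter + 4 * px) / px))
    if n % 2 == 0:
        n += 1

    ys = (np.arange(n) - (n - 1) / 2.0) * px
    yy, xx = np.meshgrid(ys, ys, indexing="ij")

    labels = np.zeros((n, n), dtype=np.int32)
    inside = xx**2 + yy**2 <= radius**2
    labels[inside] = LABEL_MATRIX

    adc = np.where(inside, comp.adc_matrix, 0.0)
    t2 = np.where(inside, comp.t2, 0.0)
    pd = np.where(inside, comp.proton_density, 0.0)

    for k, lesion in enumerate(lesions):
        cx, cy = lesion.center
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= lesion.radius**2
        mask &= inside
        labels[mask] = LABEL_LESION_BASE + k
        adc[mask] = lesion.adc_true
        t2[mask] = spec.lesion_t2

    return PhantomGrids(
        labels=labels,
        adc=adc,
        t2=t2,
        proton_density=pd,
        pixel_size=px,
        slice_thickness=spec.slice_thickness,
        lesions=lesions,
        compartment_kind=compartment,
    )
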