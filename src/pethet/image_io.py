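"""PET volume and mask containers, NIfTI I/O and SUV conversion.

Conventions used throughout the package:

* voxel indices are 0-based and follow the array axis order ``(i, j, k)``;
* ``voxel_spacing`` is in millimetres per axis, in the same axis order;
* world coordinates follow the NIfTI affine stored on the volume;
* SUV is body-weight normalised and dimensionless;
* masks are voxel-aligned to their PET grid — geometry mismatches are
  errors, never silently resampled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "SUVVolume",
    "TumourMask",
    "AcquisitionMeta",
    "GeometryError",
    "F18_HALF_LIFE_MIN",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "activity_to_suv",
]

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77

#: Absolute spacing tolerance (mm) when checking mask/volume alignment.
SPACING_ATOL_MM = 1e-3


class GeometryError(ValueError):
    """Raised when a mask and volume do not share the same voxel grid."""


@dataclass(frozen=True)
class SUVVolume:
    """A 3D grid of SUV values with physical voxel spacing.

    Parameters
    ----------
    values
        3D float array of SUV values (dimensionless, body-weight
        normalised). Must be non-negative.
    voxel_spacing
        Voxel edge lengths in mm, one per axis.
    affine
        4x4 voxel-to-world affine. Defaults to a diagonal affine built
        from the spacing with the origin at voxel (0, 0, 0).
    """

    values: np.ndarray
    voxel_spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"SUV volume must be 3D, got {values.ndim}D")
        if np.any(values < 0):
            raise ValueError("SUV values must be non-negative")
        spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"voxel_spacing must be 3 positive values, got {self.voxel_spacing}")
        affine = self.affine
        if affine is None:
            affine = np.diag([*spacing, 1.0])
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "voxel_spacing", spacing)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.voxel_spacing)) / 1000.0


@dataclass(frozen=True)
class TumourMask:
    """Binary voxel mask sharing the grid of a :class:`SUVVolume`.

    ``label`` records which delineation the mask represents:
    ``"total_lesion"`` for the manually drawn outline, ``"threshold_40"``
    for the 40 %-of-SUVmax threshold region.
    """

    values: np.ndarray
    voxel_spacing: tuple[float, float, float]
    label: str = "total_lesion"

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"mask must be 3D, got {values.ndim}D")
        values = values != 0
        if not values.any():
            raise ValueError("mask is empty: no voxel inside the lesion")
        spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"voxel_spacing must be 3 positive values, got {self.voxel_spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "voxel_spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def check_alignment(self, volume: SUVVolume) -> None:
        """Raise :class:`GeometryError` unless this mask matches ``volume``'s grid."""
        if self.shape != volume.shape:
            raise GeometryError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )
        spacing_diff = np.abs(np.subtract(self.voxel_spacing, volume.voxel_spacing))
        if np.any(spacing_diff > SPACING_ATOL_MM):
            raise GeometryError(
                f"mask spacing {self.voxel_spacing} differs from volume spacing "
                f"{volume.voxel_spacing} by more than {SPACING_ATOL_MM} mm"
            )


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata needed to convert activity concentration to SUV.

    Attributes
    ----------
    injected_dose_mbq
        Injected activity at injection time, in MBq.
    body_weight_kg
        Patient body weight in kg.
    injection_time, scan_time
        Timestamps (ISO-8601 strings or :class:`datetime.datetime`).
    isotope_half_life_min
        Physical half-life in minutes; defaults to fluorine-18.
    """

    injected_dose_mbq: float
    body_weight_kg: float
    injection_time: datetime
    scan_time: datetime
    isotope_half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        for name in ("injection_time", "scan_time"):
            value = getattr(self, name)
            if isinstance(value, str):
                object.__setattr__(self, name, datetime.fromisoformat(value))
        if self.injected_dose_mbq <= 0:
            raise ValueError("injected dose must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")
        if self.isotope_half_life_min <= 0:
            raise ValueError("half-life must be positive")
        if self.scan_time < self.injection_time:
            raise ValueError("scan_time must not precede injection_time")

    @property
    def uptake_minutes(self) -> float:
        return (self.scan_time - self.injection_time).total_seconds() / 60.0

    @property
    def decay_factor(self) -> float:
        """Fraction of the injected activity remaining at scan time."""
        return float(2.0 ** (-self.uptake_minutes / self.isotope_half_life_min))

    @property
    def decayed_dose_kbq(self) -> float:
        return self.injected_dose_mbq * 1000.0 * self.decay_factor

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionMeta":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


def _nifti_spacing(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_volume(path: str | Path) -> SUVVolume:
    """Read a 3D SUV volume from a NIfTI file.

    Raises
    ------
    ValueError
        If the image is not 3D or contains negative values.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D scalar image, got shape {data.shape}")
    if np.any(data < 0):
        raise ValueError(f"{path}: volume contains negative SUV values")
    return SUVVolume(data, _nifti_spacing(img), affine=np.asarray(img.affine))


def read_mask(path: str | Path, volume: SUVVolume, label: str = "total_lesion") -> TumourMask:
    """Read a mask and validate its geometry against ``volume``.

    Nonzero voxels are inside the lesion. Shape or spacing mismatch with
    the paired volume raises :class:`GeometryError`; an all-zero mask
    raises ``ValueError``.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got shape {data.shape}")
    if not np.any(data):
        raise ValueError(f"{path}: mask is empty")
    mask = TumourMask(data, _nifti_spacing(img), label=label)
    mask.check_alignment(volume)
    return mask


def write_volume(volume: SUVVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float64), volume.affine)
    img.header.set_zooms(volume.voxel_spacing)
    nib.save(img, str(path))


def write_mask(mask: TumourMask, path: str | Path, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.diag([*mask.voxel_spacing, 1.0])
    img = nib.Nifti1Image(mask.values.astype(np.uint8), affine)
    img.header.set_zooms(mask.voxel_spacing)
    nib.save(img, str(path))


def activity_to_suv(concentration_kbq_ml: np.ndarray | SUVVolume,
                    meta: AcquisitionMeta,
                    voxel_spacing: tuple[float, float, float] | None = None) -> SUVVolume:
    """Convert an activity-concentration volume (kBq/mL) to body-weight SUV.

    SUV = concentration / (decayed dose / body mass), with the injected
    dose decayed from injection to scan time by ``2**(-dt / half_life)``,
    body mass in grams and 1 mL of tissue taken as 1 g.

    Parameters
    ----------
    concentration_kbq_ml
        3D array of activity concentration in kBq/mL (or an
        :class:`SUVVolume`-like carrier whose values are concentrations).
    meta
        Acquisition metadata (dose, weight, times).
    voxel_spacing
        Required when passing a bare array.
    """
    if isinstance(concentration_kbq_ml, SUVVolume):
        values = concentration_kbq_ml.values
        spacing = concentration_kbq_ml.voxel_spacing
        affine = concentration_kbq_ml.affine
    else:
        if voxel_spacing is None:
            raise ValueError("voxel_spacing is required when passing a bare array")
        values = np.asarray(concentration_kbq_ml, dtype=float)
        spacing = voxel_spacing
        affine = None
    body_mass_g = meta.body_weight_kg * 1000.0
    normalisation = meta.decayed_dose_kbq / body_mass_g  # kBq per gram
    return SUVVolume(values / normalisation, spacing, affine=affine)
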