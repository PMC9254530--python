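"""Semi-quantitative PET metabolic parameters of a segmented lesion.

For a lesion under a given delineation the profile holds SUVmax, SUVmean,
SUVpeak, the metabolic tumour volume MTV (mL) and the total lesion
glycolysis TLG = MTV x SUVmean. Each delineation uses its own region
mean, so TLG of the 40 %-threshold region is MTV_40 x SUVmean_40.

SUVpeak is the maximal mean SUV over a 1.0 cm^3 sphere whose centre is
constrained to the lesion; sphere membership is decided by
voxel-centre-in-sphere with no partial-volume weighting. By default the
sphere may average voxels outside the mask (the common fixed-volume
definition); ``restrict_to_mask=True`` confines the average to lesion
voxels instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import SUVVolume, TumourMask

__all__ = ["MetabolicProfile", "compute_profile", "suv_peak", "sphere_kernel"]


@dataclass(frozen=True)
class MetabolicProfile:
    """SUV statistics and volumetric burden of one lesion delineation."""

    suv_max: float
    suv_mean: float
    suv_peak: float
    mtv_ml: float
    tlg: float
    segmentation_label: str = "total_lesion"

    def __post_init__(self) -> None:
        if self.mtv_ml <= 0:
            raise ValueError("MTV must be positive")
        # small numerical slack for the averaged quantities
        if self.suv_mean > self.suv_max * (1 + 1e-12) + 1e-12:
            raise ValueError("SUVmean cannot exceed SUVmax")


def sphere_kernel(voxel_spacing: tuple[float, float, float],
                  sphere_volume_cm3: float = 1.0) -> np.ndarray:
    """Boolean stencil of voxel offsets whose centres lie within the sphere.

    The sphere radius is ``(3 V / 4 pi)^(1/3)`` — 6.2035 mm for 1 cm^3.
    Raises ``ValueError`` if the radius is smaller than half the largest
    voxel edge, in which case the sphere would contain no voxel centre
    beyond pathological grids.
    """
    radius_mm = (3.0 * sphere_volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    spacing = np.asarray(voxel_spacing, dtype=float)
    if radius_mm < spacing.max() / 2.0:
        raise ValueError(
            f"sphere radius {radius_mm:.3f} mm is smaller than half the largest "
            f"voxel dimension {spacing.max():.3f} mm"
        )
    half_extent = np.floor(radius_mm / spacing).astype(int)
    grids = np.meshgrid(*[np.arange(-h, h + 1) for h in half_extent], indexing="ij")
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, spacing))
    return dist2 <= radius_mm**2


def suv_peak(volume: SUVVolume,
             mask: TumourMask,
             sphere_volume_cm3: float = 1.0,
             restrict_to_mask: bool = False) -> float:
    """Maximal sphere-averaged SUV with the sphere centre inside the mask.

    For every candidate centre voxel in the mask, average the SUV of all
    voxels whose centres fall within the sphere radius of the candidate
    centre; return the maximum such average. Voxels outside the image
    grid are excluded from the average (the sphere is clipped at the
    border). With ``restrict_to_mask`` the average runs over lesion
    voxels only.
    """
    mask.check_alignment(volume)
    kernel = sphere_kernel(volume.voxel_spacing, sphere_volume_cm3).astype(float)

    if restrict_to_mask:
        weights = mask.values.astype(float)
        values = volume.values * weights
    else:
        weights = np.ones_like(volume.values)
        values = volume.values

    sums = ndimage.convolve(values, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(weights, kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, -np.inf)
    return float(means[mask.values].max())


def compute_profile(volume: SUVVolume,
                    mask: TumourMask,
                    sphere_volume_cm3: float = 1.0,
                    restrict_peak_to_mask: bool = False) -> MetabolicProfile:
    """Compute SUVmax/SUVmean/SUVpeak, MTV and TLG over ``mask``.

    MTV is the voxel count times the physical voxel volume, in mL;
    TLG is MTV times the SUVmean of the same region.
    """
    mask.check_alignment(volume)
    region = volume.values[mask.values]
    s_max = float(region.max())
    s_mean = float(region.mean())
    mtv = mask.n_voxels * volume.voxel_volume_ml
    peak = suv_peak(volume, mask, sphere_volume_cm3, restrict_to_mask=restrict_peak_to_mask)
    return MetabolicProfile(
        suv_max=s_max,
        suv_mean=s_mean,
        suv_peak=peak,
        mtv_ml=mtv,
        tlg=mtv * s_mean,
        segmentation_label=mask.label,
    )
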