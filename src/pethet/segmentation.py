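"""Threshold-based lesion delineation.

The manually drawn total-lesion outline is an *input*; this module derives
the second delineation used throughout the package: the region of voxels,
inside the manual outline, whose SUV is at least a fixed fraction
(default 40 %) of the lesion SUVmax.

Conventions (documented tie rules):

* the comparison at the threshold is inclusive (``>=``), so the maximal
  voxel always survives and the region is never empty;
* every supra-threshold voxel is kept — no connected-component pruning;
* the threshold is applied only within the manual mask, never to the
  whole field of view (an unrestricted threshold would pick up
  physiologic uptake outside the tumour).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import SUVVolume, TumourMask

__all__ = ["SegmentationResult", "threshold_segment"]


@dataclass(frozen=True)
class SegmentationResult:
    """The paired delineations of one lesion.

    ``threshold_mask`` is always a subset of ``total_mask`` and contains
    at least the voxel attaining ``suv_max_used``.
    """

    total_mask: TumourMask
    threshold_mask: TumourMask
    threshold_fraction: float
    suv_max_used: float


def threshold_segment(volume: SUVVolume,
                      total_mask: TumourMask,
                      fraction: float = 0.40) -> SegmentationResult:
    """Derive the ``fraction``-of-SUVmax region inside the manual outline.

    Parameters
    ----------
    volume
        SUV volume.
    total_mask
        Manually drawn total-lesion mask (non-empty, same grid).
    fraction
        Threshold as a fraction of the lesion SUVmax, in (0, 1).

    Returns
    -------
    SegmentationResult
        With ``threshold_mask`` = voxels of ``total_mask`` whose SUV is
        ``>= fraction * SUVmax`` (SUVmax taken over the total mask).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    total_mask.check_alignment(volume)
    inside = total_mask.values
    suv_max = float(volume.values[inside].max())
    threshold = fraction * suv_max
    keep = inside & (volume.values >= threshold)
    threshold_mask = TumourMask(keep, total_mask.voxel_spacing, label="threshold_40")
    return SegmentationResult(
        total_mask=total_mask,
        threshold_mask=threshold_mask,
        threshold_fraction=float(fraction),
        suv_max_used=suv_max,
    )
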