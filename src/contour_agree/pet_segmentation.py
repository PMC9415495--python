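"""Automatic amino-acid PET tumor segmentation by TBR thresholding.

The gross tumor volume on FET-PET is defined semi-quantitatively: a voxel
belongs to the tumor when its uptake divided by the mean uptake of a
normal-brain background VOI (the tumor-to-brain ratio, TBR) reaches a
threshold, by default 1.6. The search is restricted to a margin (default
30 mm, Euclidean, anisotropy-aware) around a reference MRI gross tumor
volume, and regions of known physiological uptake (skin, vessels) can be
subtracted.

The background VOI is the crescent-shaped "banana" of the clinical
procedure: the union of six spherical ROIs of 20-25 mm diameter placed in
normal contralateral brain. Placement is the operator's responsibility;
this module only rasterizes the spheres and averages the uptake.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io_masks import BinaryMask, ImageVolume

#: Diameter range (mm) of the clinical background ROIs; values outside
#: this range are accepted with a warning.
ROI_DIAMETER_RANGE = (20.0, 25.0)

N_BACKGROUND_ROIS = 6


class DegenerateVOIError(ValueError):
    """Background VOI contains no voxels (or is being averaged while empty)."""


@dataclass(frozen=True)
class BackgroundVOI:
    """The "banana" background VOI: union of six spherical ROIs.

    ``mean_uptake`` is the arithmetic mean of the PET values over the VOI
    voxels and is the denominator of every TBR.
    """

    roi_centers: np.ndarray          # (6, 3) world mm
    roi_diameter_mm: float
    mask: BinaryMask
    mean_uptake: float


@dataclass
class TBRSegmentationParams:
    """Parameters of the TBR segmentation.

    Attributes
    ----------
    reference_mask : BinaryMask
        The MRI gross tumor volume anchoring the margin constraint.
    tbr_threshold : float
        Inclusive uptake-ratio threshold (voxels with TBR >= threshold kept).
    margin_mm : float
        Maximum Euclidean distance (mm) from the reference mask.
    exclusion_mask : BinaryMask or None
        Physiological-uptake regions removed from the result.
    keep_largest_component : bool
        If true, keep only the largest 26-connected component. Off by
        default: multifocal tumors are common in this disease and the
        clinical procedure does not filter by connectivity.
    """

    reference_mask: BinaryMask
    tbr_threshold: float = 1.6
    margin_mm: float = 30.0
    exclusion_mask: BinaryMask | None = None
    keep_largest_component: bool = False

    def __post_init__(self) -> None:
        if self.tbr_threshold <= 0:
            raise ValueError("tbr_threshold must be positive")
        if self.margin_mm < 0:
            raise ValueError("margin_mm must be non-negative")


def _world_to_index(grid: ImageVolume, points: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(grid.affine)
    pts = np.atleast_2d(np.asarray(points, float))
    homo = np.column_stack([pts, np.ones(len(pts))])
    return (homo @ inv.T)[:, :3]


def build_background_voi(
    pet: ImageVolume,
    roi_centers: Sequence[Sequence[float]],
    roi_diameter_mm: float = 20.0,
) -> BackgroundVOI:
    """Rasterize the six-sphere background VOI and average the uptake over it.

    Each ROI is the ball of the given diameter around its world-coordinate
    centre; a voxel belongs to the ROI when its centre lies inside the ball.
    Spheres are clipped at the grid boundary; coincident or overlapping
    spheres contribute once (set union).
    """
    centers = np.asarray(roi_centers, dtype=float)
    if centers.shape != (N_BACKGROUND_ROIS, 3):
        raise ValueError(
            f"expected {N_BACKGROUND_ROIS} world-coordinate centers, "
            f"got array of shape {centers.shape}"
        )
    lo, hi = ROI_DIAMETER_RANGE
    if not lo <= roi_diameter_mm <= hi:
        warnings.warn(
            f"ROI diameter {roi_diameter_mm} mm outside the clinical "
            f"{lo}-{hi} mm range",
            stacklevel=2,
        )

    idx = _world_to_index(pet, centers)
    shape = np.array(pet.shape)
    if np.any(idx < -0.5) or np.any(idx > shape - 0.5):
        raise ValueError("background ROI center outside the PET grid")

    coords = pet.world_coordinates()
    radius = roi_diameter_mm / 2.0
    mask = np.zeros(pet.shape, dtype=bool)
    for c in centers:
        d2 = np.sum((coords - c) ** 2, axis=-1)
        mask |= d2 <= radius * radius
    if not mask.any():
        raise DegenerateVOIError("background VOI rasterized to zero voxels")

    voi_mask = BinaryMask(data=mask, grid=pet, label=("", "background", ""))
    mean_uptake = float(np.asarray(pet.data, float)[mask].mean())
    return BackgroundVOI(
        roi_centers=centers,
        roi_diameter_mm=float(roi_diameter_mm),
        mask=voi_mask,
        mean_uptake=mean_uptake,
    )


def background_mean(voi: BackgroundVOI, pet: ImageVolume) -> float:
    """Mean PET uptake over the VOI voxels (the TBR denominator)."""
    if not voi.mask.grid.same_grid(pet):
        raise ValueError("background VOI is not aligned to the PET grid")
    if voi.mask.is_empty:
        raise DegenerateVOIError("background VOI is empty")
    return float(np.asarray(pet.data, float)[voi.mask.data].mean())


def margin_region(reference_mask: BinaryMask, margin_mm: float) -> BinaryMask:
    """Voxels within ``margin_mm`` (Euclidean, mm) of the reference mask.

    The distance is measured between voxel centres with the grid spacing as
    the metric, so anisotropic voxels expand correctly. The reference is
    always a subset of the result (its own voxels are at distance 0).
    """
    if reference_mask.is_empty:
        raise ValueError("reference mask is empty")
    if margin_mm < 0:
        raise ValueError("margin_mm must be non-negative")
    dist = ndimage.distance_transform_edt(
        ~reference_mask.data, sampling=reference_mask.grid.spacing
    )
    return BinaryMask(
        data=dist <= margin_mm,
        grid=reference_mask.grid,
        label=reference_mask.label,
    )


def segment_tbr(
    pet: ImageVolume,
    background: BackgroundVOI,
    params: TBRSegmentationParams,
) -> BinaryMask:
    """TBR-threshold segmentation of the PET gross tumor volume.

    result = {v : pet(v) / background_mean >= threshold}
             intersected with the margin region around the reference mask,
             minus the exclusion mask.

    The output is scale-invariant in the PET image (TBR is a ratio) and is
    always contained in the margin region.
    """
    if not params.reference_mask.grid.same_grid(pet):
        raise ValueError("reference mask is not aligned to the PET grid")
    if params.exclusion_mask is not None and not params.exclusion_mask.grid.same_grid(pet):
        raise ValueError("exclusion mask is not aligned to the PET grid")
    if background.mean_uptake <= 0:
        raise ValueError(
            f"background mean uptake must be positive, got {background.mean_uptake}"
        )

    tbr = np.asarray(pet.data, float) / background.mean_uptake
    result = tbr >= params.tbr_threshold
    result &= margin_region(params.reference_mask, params.margin_mm).data
    if params.exclusion_mask is not None:
        result &= ~params.exclusion_mask.data
    if params.keep_largest_component and result.any():
        labels, n = ndimage.label(result, structure=np.ones((3, 3, 3), dtype=int))
        sizes = ndimage.sum_labels(result, labels, index=np.arange(1, n + 1))
        result = labels == (1 + int(np.argmax(sizes)))
    return BinaryMask(data=result, grid=pet, label=("", "FET-PET", "auto"))
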