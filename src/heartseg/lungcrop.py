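"""Automatic lung segmentation and the heart volume of interest (VOI).

Before any registration, every image is cropped to a VOI surrounding the
heart, derived from an intensity-based segmentation of the lungs: voxels
below a HU threshold are grouped into six-connected components, components
in contact with the lateral borders of the axial slices are discarded as
exterior air, small components are removed, and the largest one or two
survivors are the lungs.  The VOI is the bounding box of the lung mask plus
a configurable margin — the heart sits in the mediastinum between the lungs,
so the lung bounding box always encloses it.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image import BinaryMask, Image3D, VoxelBox, crop, mask_bounding_box

__all__ = ["segment_lungs", "heart_voi", "crop_case", "NoLungsFoundError"]

DEFAULT_HU_THRESHOLD = -320.0
DEFAULT_MIN_COMPONENT_MM3 = 50_000.0  # 50 cm^3
DEFAULT_VOI_MARGIN_MM = 10.0


class NoLungsFoundError(ValueError):
    """No candidate lung component survived thresholding and filtering."""


def segment_lungs(
    image: Image3D,
    hu_threshold: float = DEFAULT_HU_THRESHOLD,
    min_component_mm3: float = DEFAULT_MIN_COMPONENT_MM3,
) -> BinaryMask:
    """Intensity-based lung segmentation.

    Keeps the largest one or two six-connected components of
    {voxels < hu_threshold} that neither touch the lateral (x/y) borders of
    the axial slices (which excludes the air surrounding the patient) nor
    fall below ``min_component_mm3``.
    """
    low = image.values < hu_threshold
    if not low.any():
        raise NoLungsFoundError(
            f"no voxels below {hu_threshold} HU; no lungs found"
        )
    labels, n = ndimage.label(low)  # default structure = six-connectivity
    if n == 0:
        raise NoLungsFoundError("no lungs found")

    border = np.zeros(image.dims, dtype=bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border_labels = set(np.unique(labels[border])) - {0}

    voxel_mm3 = image.voxel_volume_mm3()
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    candidates = [
        (int(sizes[lab - 1]), lab)
        for lab in range(1, n + 1)
        if lab not in border_labels and sizes[lab - 1] * voxel_mm3 >= min_component_mm3
    ]
    if not candidates:
        raise NoLungsFoundError(
            "no lungs found: every low-intensity component touches the image "
            "border or is below the minimum volume"
        )
    candidates.sort(reverse=True)
    keep = {lab for _, lab in candidates[:2]}
    mask = np.isin(labels, list(keep))
    return BinaryMask(
        values=mask.astype(np.uint8),
        spacing=image.spacing,
        origin=image.origin,
        direction=image.direction.copy(),
        role="lungs",
    )


def heart_voi(lungs: BinaryMask, margin_mm: float = DEFAULT_VOI_MARGIN_MM) -> VoxelBox:
    """Heart volume of interest: the lung bounding box expanded by a margin."""
    if lungs.is_empty():
        raise ValueError("lung mask is empty; cannot derive the heart VOI")
    return mask_bounding_box(lungs, margin_mm)


def crop_case(
    image: Image3D, masks: list[BinaryMask], box: VoxelBox
) -> tuple[Image3D, list[BinaryMask]]:
    """Crop an image and its masks consistently to one VOI box."""
    return crop(image, box), [crop(m, box) for m in masks]
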