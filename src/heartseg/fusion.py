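"""Multi-atlas machinery: propagation, consensus, discordant-atlas rejection
and local-weighted label fusion.

Given a target image and a set of atlases (previously delineated image/mask
pairs), each atlas is registered to the target (rigid, then demons) and its
mask carried along.  Atlases whose propagated surface deviates strongly from
a consensus delineation — voxelwise majority vote — are rejected by a robust
fence on the mean absolute surface distance (MASD) to the consensus:
``deviation > median + k * IQR``.  No manual contouring of the target enters
this step.  The surviving atlases are combined by local-weighted label
fusion: at every voxel each atlas votes with weight inversely proportional
to the local mean absolute intensity difference between its warped image and
the target, so atlases that locally resemble the target dominate locally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import BinaryMask, GeometryError, Image3D, same_grid
from .metrics import masd
from .registration import (
    DeformationField,
    RegistrationConfig,
    RegistrationError,
    apply_to_image,
    apply_to_mask,
    demons_register,
    rigid_register,
)

__all__ = [
    "AtlasEntry",
    "PropagatedAtlas",
    "FusionConfig",
    "SegmentationResult",
    "propagate_atlases",
    "consensus_mask",
    "atlas_deviation_scores",
    "select_atlases",
    "local_weight",
    "fuse_labels",
    "segment_target",
]

MIN_ATLASES = 3


@dataclass
class AtlasEntry:
    """A delineated image/mask pair used to segment new images."""

    id: str
    image: Image3D
    mask: BinaryMask

    def __post_init__(self) -> None:
        same_grid(self.image, self.mask)


@dataclass
class PropagatedAtlas:
    """An atlas after registration to the target grid."""

    id: str
    warped_image: Image3D
    warped_mask: BinaryMask
    deviation_mm: float | None = None
    field: DeformationField | None = None

    def __post_init__(self) -> None:
        same_grid(self.warped_image, self.warped_mask)


@dataclass(frozen=True)
class FusionConfig:
    """Atlas selection and label-fusion parameters.

    selection_k_iqr / min_retained:
        robust rejection fence (median + k*IQR of the deviation scores) and
        the floor on how many atlases survive selection.
    patch_radius_mm / epsilon:
        cubic patch half-width for the local intensity-difference weighting
        and the additive guard keeping weights finite (in HU).
    probability_threshold:
        fused-probability cut defining the final binary segmentation
        (>= threshold; 0.5 reduces to weighted majority).
    """

    selection_k_iqr: float = 1.5
    min_retained: int = 3
    patch_radius_mm: float = 5.0
    epsilon: float = 1.0
    probability_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.min_retained < MIN_ATLASES:
            raise ValueError(f"min_retained must be >= {MIN_ATLASES}")
        if not self.patch_radius_mm > 0:
            raise ValueError("patch_radius_mm must be > 0")
        if not (0.0 < self.probability_threshold < 1.0):
            raise ValueError("probability_threshold must be in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def _unique_ids(atlases) -> None:
    ids = [a.id for a in atlases]
    if len(set(ids)) != len(ids):
        raise ValueError("atlas ids must be unique within a set")


def propagate_atlases(
    target: Image3D,
    atlases: list[AtlasEntry],
    reg_cfg: RegistrationConfig | None = None,
    log: list | None = None,
) -> list[PropagatedAtlas]:
    """Register every atlas to the target (rigid then demons, composed into
    one field) and warp its image and mask onto the target grid.

    Individual registration failures are logged and the atlas dropped; the
    call fails only if fewer than three atlases survive.
    """
    if len(atlases) < MIN_ATLASES:
        raise ValueError(f"need at least {MIN_ATLASES} atlases, got {len(atlases)}")
    _unique_ids(atlases)
    reg_cfg = reg_cfg or RegistrationConfig()
    out: list[PropagatedAtlas] = []
    for atlas in atlases:
        try:
            rigid = rigid_register(target, atlas.image, reg_cfg)
            fld = demons_register(target, atlas.image, init=rigid, cfg=reg_cfg)
            out.append(
                PropagatedAtlas(
                    id=atlas.id,
                    warped_image=apply_to_image(fld, atlas.image, target),
                    warped_mask=apply_to_mask(fld, atlas.mask, target),
                    field=fld,
                )
            )
            if log is not None:
                log.append({"atlas": atlas.id, "status": "ok", **fld.log})
        except RegistrationError as exc:
            if log is not None:
                log.append({"atlas": atlas.id, "status": "failed", "error": str(exc)})
    if len(out) < MIN_ATLASES:
        raise RegistrationError(
            f"only {len(out)} of {len(atlases)} atlas registrations succeeded "
            f"(need {MIN_ATLASES})"
        )
    return out


def consensus_mask(propagated: list[PropagatedAtlas]) -> BinaryMask:
    """Voxelwise majority vote: 1 where strictly more than half of the
    propagated atlases label 1 (exact-half ties resolve to 0)."""
    if not propagated:
        raise ValueError("cannot build a consensus from no atlases")
    ref = propagated[0].warped_mask
    votes = np.zeros(ref.dims, dtype=np.int32)
    for p in propagated:
        same_grid(ref, p.warped_mask)
        votes += p.warped_mask.values
    return BinaryMask(
        values=(votes * 2 > len(propagated)).astype(np.uint8),
        spacing=ref.spacing,
        origin=ref.origin,
        direction=ref.direction.copy(),
        role="other",
    )


def atlas_deviation_scores(
    propagated: list[PropagatedAtlas], consensus: BinaryMask
) -> list[float]:
    """MASD (mm) of each propagated mask to the consensus; an empty warped
    mask scores infinite deviation (a guaranteed rejection candidate).
    Scores are also stored on the entries."""
    if consensus.is_empty():
        raise ValueError("consensus mask is empty")
    scores = []
    for p in propagated:
        dev = math.inf if p.warped_mask.is_empty() else masd(p.warped_mask, consensus)
        p.deviation_mm = dev
        scores.append(dev)
    return scores


def select_atlases(
    propagated: list[PropagatedAtlas],
    cfg: FusionConfig | None = None,
    log: list | None = None,
) -> list[PropagatedAtlas]:
    """Reject discordant atlases: deviation above ``median + k*IQR`` of the
    deviation scores.  If the fence would leave fewer than ``min_retained``
    atlases, the ``min_retained`` lowest-deviation atlases are kept instead.
    Input order is preserved among the retained."""
    cfg = cfg or FusionConfig()
    if len(propagated) < cfg.min_retained:
        raise ValueError(
            f"need at least {cfg.min_retained} atlases to select from, got {len(propagated)}"
        )
    dev = np.asarray([p.deviation_mm for p in propagated], dtype=float)
    if np.any(np.isnan(dev)):
        raise ValueError("deviation scores missing; run atlas_deviation_scores first")
    finite = dev[np.isfinite(dev)]
    if finite.size == 0:
        raise ValueError("all deviation scores are infinite")
    median = float(np.median(dev)) if np.isfinite(np.median(dev)) else float(np.median(finite))
    q1, q3 = np.percentile(finite, [25.0, 75.0])
    fence = median + cfg.selection_k_iqr * float(q3 - q1)
    keep = dev <= fence
    if keep.sum() < cfg.min_retained:
        order = np.argsort(dev, kind="stable")[: cfg.min_retained]
        keep = np.zeros_like(keep)
        keep[order] = True
    retained = [p for p, k in zip(propagated, keep) if k]
    if log is not None:
        for p, k in zip(propagated, keep):
            log.append(
                {
                    "atlas": p.id,
                    "deviation_mm": p.deviation_mm,
                    "fence_mm": fence,
                    "decision": "retained" if k else "rejected",
                }
            )
    return retained


def _patch_radius_voxels(spacing, patch_radius_mm: float) -> tuple[int, int, int]:
    return tuple(max(1, int(round(patch_radius_mm / s))) for s in spacing)


def local_weight(
    target: Image3D, warped_image: Image3D, cfg: FusionConfig | None = None
) -> np.ndarray:
    """Per-voxel fusion weight: inverse of (epsilon + mean absolute intensity
    difference over the cubic patch of radius ``patch_radius_mm``).  Patches
    are clipped at the grid boundary; weights are strictly positive and
    finite."""
    cfg = cfg or FusionConfig()
    same_grid(target, warped_image)
    r = _patch_radius_voxels(target.spacing, cfg.patch_radius_mm)
    size = tuple(2 * ri + 1 for ri in r)
    absdiff = np.abs(target.values.astype(float) - warped_image.values.astype(float))
    # clipped-patch mean: ratio of box sums so boundary patches average only
    # the voxels that exist
    num = ndimage.uniform_filter(absdiff, size=size, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(
        np.ones_like(absdiff), size=size, mode="constant", cval=0.0
    )
    mean_abs = num / den
    w = 1.0 / (cfg.epsilon + mean_abs)
    assert np.all(np.isfinite(w)) and np.all(w > 0)
    return w


def fuse_labels(
    retained: list[PropagatedAtlas],
    weights: list[np.ndarray],
    cfg: FusionConfig | None = None,
) -> tuple[Image3D, BinaryMask]:
    """Local-weighted label fusion: probability(v) = sum_i w_i(v) m_i(v) /
    sum_i w_i(v); the automatic heart is the >= threshold superlevel set."""
    cfg = cfg or FusionConfig()
    if not retained:
        raise ValueError("no atlases to fuse")
    if len(weights) != len(retained):
        raise ValueError("weights must align one-to-one with the retained atlases")
    ref = retained[0].warped_mask
    num = np.zeros(ref.dims, dtype=np.float64)
    den = np.zeros(ref.dims, dtype=np.float64)
    for p, w in zip(retained, weights):
        same_grid(ref, p.warped_mask)
        if w.shape != ref.dims:
            raise GeometryError("weight map shape does not match the target grid")
        num += w * p.warped_mask.values
        den += w
    assert np.all(den > 0), "fusion weights must be strictly positive"
    prob = num / den
    probability = Image3D(
        values=prob, spacing=ref.spacing, origin=ref.origin, direction=ref.direction.copy()
    )
    heart_auto = BinaryMask(
        values=(prob >= cfg.probability_threshold).astype(np.uint8),
        spacing=ref.spacing,
        origin=ref.origin,
        direction=ref.direction.copy(),
        role="heart_auto",
    )
    return probability, heart_auto


@dataclass
class SegmentationResult:
    """End product of multi-atlas segmentation of one target image."""

    heart_auto: BinaryMask
    probability: Image3D
    retained_ids: list[str]
    rejected_ids: list[str]
    log: dict = field(default_factory=dict)


def segment_target(
    target: Image3D,
    atlases: list[AtlasEntry],
    reg_cfg: RegistrationConfig | None = None,
    fusion_cfg: FusionConfig | None = None,
) -> SegmentationResult:
    """Full multi-atlas segmentation of one target: propagate all atlases,
    reject discordant ones against the majority-vote consensus, then fuse the
    survivors with local intensity weighting."""
    reg_cfg = reg_cfg or RegistrationConfig()
    fusion_cfg = fusion_cfg or FusionConfig()
    reg_log: list = []
    sel_log: list = []
    propagated = propagate_atlases(target, atlases, reg_cfg, log=reg_log)
    consensus = consensus_mask(propagated)
    if consensus.is_empty():
        raise RegistrationError("atlas consensus is empty; propagation failed broadly")
    atlas_deviation_scores(propagated, consensus)
    retained = select_atlases(propagated, fusion_cfg, log=sel_log)
    weights = [local_weight(target, p.warped_image, fusion_cfg) for p in retained]
    probability, heart_auto = fuse_labels(retained, weights, fusion_cfg)
    retained_ids = [p.id for p in retained]
    rejected_ids = [p.id for p in propagated if p.id not in set(retained_ids)]
    return SegmentationResult(
        heart_auto=heart_auto,
        probability=probability,
        retained_ids=retained_ids,
        rejected_ids=rejected_ids,
        log={"registrations": reg_log, "selection": sel_log},
    )
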