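"""Respiratory-phase propagation and the motion-encompassing PRV.

A 4D study is an ordered stack of phase volumes (0%–90% of the breathing
cycle, ten when complete) sharing one frame of reference.  The heart is
segmented once, on the 0% phase, by multi-atlas fusion; that delineation is
then carried to every other phase by a separate intra-patient demons
registration (no rigid step — same scanner frame — and identity
initialisation), registering the 0% image directly to each phase (star
topology, which avoids accumulating error along the phase chain).  The
planning organ-at-risk volume (PRV) is the voxelwise union of the per-phase
delineations, so it encloses the heart's full respiratory excursion.

The alternative, segmenting every phase independently with the full
multi-atlas machinery, is supported for comparison; propagation performs one
fusion plus nine registrations per study instead of ten fusions, which is
what makes it the cheaper clinical route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import BinaryMask, Image3D, resample, same_grid
from .fusion import (
    AtlasEntry,
    FusionConfig,
    SegmentationResult,
    segment_target,
)
from .registration import (
    RegistrationConfig,
    apply_to_mask,
    demons_register,
)

__all__ = [
    "PHASE_LABELS",
    "Phase4DStudy",
    "StudySegmentation",
    "propagate_to_phase",
    "build_prv",
    "segment_study",
]

PHASE_LABELS: tuple[str, ...] = tuple(f"{10 * p}%" for p in range(10))


@dataclass
class Phase4DStudy:
    """Ordered respiratory-phase image stack with optional truth masks.

    ``phases`` holds ``(phase_label, image, truth_mask_or_None)`` tuples; a
    complete study has the ten labels 0%–90% in order.
    """

    patient_id: str
    phases: list[tuple[str, Image3D, BinaryMask | None]]

    def __post_init__(self) -> None:
        labels = [p[0] for p in self.phases]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate phase labels in study {self.patient_id!r}")
        if not self.phases:
            raise ValueError("a study needs at least one phase")

    @property
    def labels(self) -> list[str]:
        return [p[0] for p in self.phases]

    @property
    def is_complete(self) -> bool:
        return tuple(self.labels) == PHASE_LABELS

    def image(self, label: str) -> Image3D:
        for lab, img, _ in self.phases:
            if lab == label:
                return img
        raise KeyError(f"no phase {label!r} in study {self.patient_id!r}")

    def truth(self, label: str) -> BinaryMask | None:
        for lab, _, tr in self.phases:
            if lab == label:
                return tr
        raise KeyError(f"no phase {label!r} in study {self.patient_id!r}")


def propagate_to_phase(
    phase0_image: Image3D,
    phase_image: Image3D,
    heart0: BinaryMask,
    reg_cfg: RegistrationConfig | None = None,
) -> BinaryMask:
    """Carry the 0%-phase heart delineation to another phase of the same
    study by demons registration (identity initialisation; the phases share
    the scanner frame of reference, so no rigid step)."""
    same_grid(phase0_image, heart0)
    fld = demons_register(phase_image, phase0_image, init=None, cfg=reg_cfg)
    out = apply_to_mask(fld, heart0, phase_image)
    out.role = "heart_auto"
    return out


def build_prv(phase_masks: list[BinaryMask]) -> BinaryMask:
    """Voxelwise union of the per-phase delineations.  Masks on a different
    grid are resampled (nearest) onto the first mask's grid; the result is a
    superset of every input."""
    if len(phase_masks) < 2:
        raise ValueError("the PRV is a union over at least two phase masks")
    ref = phase_masks[0]
    union = np.zeros(ref.dims, dtype=np.uint8)
    for m in phase_masks:
        if not m.same_geometry(ref):
            m = resample(m, ref, interp="nearest")
        union |= m.values
    return BinaryMask(
        values=union,
        spacing=ref.spacing,
        origin=ref.origin,
        direction=ref.direction.copy(),
        role="prv",
    )


@dataclass
class StudySegmentation:
    """Per-phase automatic heart masks and the PRV for one study."""

    patient_id: str
    mode: str
    phase_masks: dict[str, BinaryMask]
    prv: BinaryMask
    fusion_results: dict[str, SegmentationResult]
    log: dict = field(default_factory=dict)


def segment_study(
    study: Phase4DStudy,
    atlases: list[AtlasEntry],
    mode: str = "propagate",
    reg_cfg: RegistrationConfig | None = None,
    fusion_cfg: FusionConfig | None = None,
    atlases_by_phase: dict[str, list[AtlasEntry]] | None = None,
    require_complete: bool = True,
) -> StudySegmentation:
    """Segment a 4D study.

    mode="propagate" (the clinical route): multi-atlas fusion on the 0%
    phase, then one intra-patient propagation per remaining phase.
    mode="independent": full multi-atlas segmentation separately on every
    phase; per-phase atlas sets are taken from ``atlases_by_phase`` when the
    phase is present there, else the 0%-phase atlas set is reused.
    """
    if mode not in ("propagate", "independent"):
        raise ValueError(f"mode must be 'propagate' or 'independent', got {mode!r}")
    if require_complete and not study.is_complete:
        raise ValueError(
            f"study {study.patient_id!r} is incomplete: phases {study.labels}"
        )
    if len(atlases) < 3:
        raise ValueError("need at least 3 atlases")

    phase_masks: dict[str, BinaryMask] = {}
    fusion_results: dict[str, SegmentationResult] = {}
    n_fusions = 0
    n_propagations = 0
    labels = study.labels
    anchor = labels[0]

    if mode == "propagate":
        res0 = segment_target(study.image(anchor), atlases, reg_cfg, fusion_cfg)
        n_fusions += 1
        phase_masks[anchor] = res0.heart_auto
        fusion_results[anchor] = res0
        for lab in labels[1:]:
            phase_masks[lab] = propagate_to_phase(
                study.image(anchor), study.image(lab), res0.heart_auto, reg_cfg
            )
            n_propagations += 1
    else:
        for lab in labels:
            atlas_set = (atlases_by_phase or {}).get(lab, atlases)
            res = segment_target(study.image(lab), atlas_set, reg_cfg, fusion_cfg)
            n_fusions += 1
            phase_masks[lab] = res.heart_auto
            fusion_results[lab] = res

    prv = build_prv([phase_masks[lab] for lab in labels]) if len(labels) > 1 else None
    if prv is None:
        prv = BinaryMask(
            values=phase_masks[anchor].values.copy(),
            spacing=phase_masks[anchor].spacing,
            origin=phase_masks[anchor].origin,
            direction=phase_masks[anchor].direction.copy(),
            role="prv",
        )
    return StudySegmentation(
        patient_id=study.patient_id,
        mode=mode,
        phase_masks=phase_masks,
        prv=prv,
        fusion_results=fusion_results,
        log={"n_fusions": n_fusions, "n_propagations": n_propagations},
    )
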