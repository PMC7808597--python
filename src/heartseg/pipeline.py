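"""End-to-end orchestration: cropping, segmentation, evaluation and
leave-one-out experiments over a cohort.

A *case* is one patient: a (possibly single-phase) :class:`Phase4DStudy`
whose phases may carry reference masks (ground truth for phantoms, manual
contours for clinical data).  A leave-one-out experiment segments every case
using all the others as the atlas set, evaluates each result against the
references, and aggregates the comparisons into a per-phase mean +/- sd
table; per-case failures are logged and excluded from aggregation with the
failure count surfaced on the table.

Every run is fully determined by (cases, configuration, seed); the
configuration is echoed into the output directory alongside structured logs
of atlas rejections and registration metrics so results can be audited.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fourd import Phase4DStudy, StudySegmentation, build_prv, segment_study
from .fusion import AtlasEntry, FusionConfig
from .image import read_volume, write_volume
from .lungcrop import (
    DEFAULT_HU_THRESHOLD,
    DEFAULT_MIN_COMPONENT_MM3,
    DEFAULT_VOI_MARGIN_MM,
    crop_case,
    heart_voi,
    segment_lungs,
)
from .metrics import PRV_ROW, CohortTable, ComparisonResult, cohort_table, compare_masks
from .registration import RegistrationConfig

__all__ = [
    "PipelineConfig",
    "CaseRecord",
    "SingleResult",
    "LeaveOneOutResult",
    "prepare_case",
    "run_single",
    "run_leave_one_out",
    "load_manifest",
    "write_cohort",
    "cases_from_cohort",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of an end-to-end run, with provenance echo."""

    lung_threshold_hu: float = DEFAULT_HU_THRESHOLD
    lung_min_component_mm3: float = DEFAULT_MIN_COMPONENT_MM3
    voi_margin_mm: float = DEFAULT_VOI_MARGIN_MM
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    mode: str = "propagate"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("propagate", "independent"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "registration" in d and isinstance(d["registration"], dict):
            reg = dict(d["registration"])
            for k in ("shrink_factors", "smoothing_sigmas_mm"):
                if k in reg:
                    reg[k] = tuple(reg[k])
            d["registration"] = RegistrationConfig(**reg)
        if "fusion" in d and isinstance(d["fusion"], dict):
            d["fusion"] = FusionConfig(**d["fusion"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class CaseRecord:
    """One cohort member: a phase study whose phases may carry references."""

    patient_id: str
    study: Phase4DStudy


# ---------------------------------------------------------------------------
# cropping


def prepare_case(
    case: CaseRecord, cfg: PipelineConfig, margin_mm: float | None = None
) -> tuple[CaseRecord, object]:
    """Crop every phase (and reference mask) of a case to the heart VOI
    derived from the lungs on the anchor (first) phase."""
    anchor_img = case.study.phases[0][1]
    lungs = segment_lungs(anchor_img, cfg.lung_threshold_hu, cfg.lung_min_component_mm3)
    box = heart_voi(lungs, cfg.voi_margin_mm if margin_mm is None else margin_mm)
    new_phases = []
    for lab, img, truth in case.study.phases:
        masks = [truth] if truth is not None else []
        img_c, masks_c = crop_case(img, masks, box)
        new_phases.append((lab, img_c, masks_c[0] if masks_c else None))
    return (
        CaseRecord(case.patient_id, Phase4DStudy(case.patient_id, new_phases)),
        box,
    )


def _atlas_entries(
    atlas_cases: list[CaseRecord], cfg: PipelineConfig
) -> tuple[list[AtlasEntry], dict[str, list[AtlasEntry]]]:
    """Build per-phase atlas sets from cropped atlas cases.  The anchor-phase
    entries are the main atlas set; other phases feed independent mode."""
    anchor_entries: list[AtlasEntry] = []
    by_phase: dict[str, list[AtlasEntry]] = {}
    # atlases keep a wider margin than the target so that, once rigidly
    # aligned, their support covers the whole target VOI and the demons
    # forces never see out-of-support fill near the heart
    atlas_margin = cfg.voi_margin_mm + 15.0
    for case in atlas_cases:
        cropped, _ = prepare_case(case, cfg, margin_mm=atlas_margin)
        for i, (lab, img, truth) in enumerate(cropped.study.phases):
            if truth is None:
                continue
            entry = AtlasEntry(id=case.patient_id, image=img, mask=truth)
            if i == 0:
                anchor_entries.append(entry)
            by_phase.setdefault(lab, []).append(entry)
    return anchor_entries, by_phase


# ---------------------------------------------------------------------------
# single-case run


@dataclass
class SingleResult:
    patient_id: str
    segmentation: StudySegmentation
    comparisons: list[tuple[str, str, ComparisonResult]]  # (patient, phase, result)
    cropped_case: CaseRecord


def run_single(
    target: CaseRecord,
    atlas_cases: list[CaseRecord],
    cfg: PipelineConfig | None = None,
    out_dir=None,
) -> SingleResult:
    """Crop, segment (configured mode), build the PRV and — where reference
    masks are supplied — evaluate one case against them."""
    cfg = cfg or PipelineConfig()
    if len(atlas_cases) < 3:
        raise ValueError("need at least 3 atlas cases")
    cropped, _box = prepare_case(target, cfg)
    atlases, by_phase = _atlas_entries(atlas_cases, cfg)
    seg = segment_study(
        cropped.study,
        atlases,
        mode=cfg.mode,
        reg_cfg=cfg.registration,
        fusion_cfg=cfg.fusion,
        atlases_by_phase=by_phase if cfg.mode == "independent" else None,
        require_complete=False,
    )
    comparisons: list[tuple[str, str, ComparisonResult]] = []
    truth_masks = []
    for lab, _img, truth in cropped.study.phases:
        if truth is None:
            continue
        truth_masks.append(truth)
        comparisons.append(
            (
                target.patient_id,
                lab,
                compare_masks(seg.phase_masks[lab], truth, "heart_auto", "reference"),
            )
        )
    if len(truth_masks) == len(cropped.study.phases) and len(truth_masks) >= 2:
        prv_ref = build_prv(truth_masks)
        comparisons.append(
            (
                target.patient_id,
                PRV_ROW,
                compare_masks(seg.prv, prv_ref, "prv_auto", "prv_reference"),
            )
        )
    result = SingleResult(
        patient_id=target.patient_id,
        segmentation=seg,
        comparisons=comparisons,
        cropped_case=cropped,
    )
    if out_dir is not None:
        _write_single(result, cfg, Path(out_dir))
    return result


def _write_single(result: SingleResult, cfg: PipelineConfig, out_dir: Path) -> None:
    case_dir = out_dir / result.patient_id
    case_dir.mkdir(parents=True, exist_ok=True)
    for lab, mask in result.segmentation.phase_masks.items():
        write_volume(mask, case_dir / f"heart_auto_{lab.rstrip('%')}pct.nii.gz")
    write_volume(result.segmentation.prv, case_dir / "prv.nii.gz")
    for lab, res in result.segmentation.fusion_results.items():
        write_volume(res.probability, case_dir / f"probability_{lab.rstrip('%')}pct.nii.gz")
    cfg.to_yaml(case_dir / "config.yaml")
    log = {
        "patient_id": result.patient_id,
        "mode": result.segmentation.mode,
        **result.segmentation.log,
        "fusion": {
            lab: {
                "retained": res.retained_ids,
                "rejected": res.rejected_ids,
                "selection": res.log.get("selection", []),
            }
            for lab, res in result.segmentation.fusion_results.items()
        },
    }
    (case_dir / "log.yaml").write_text(yaml.safe_dump(log, sort_keys=False))


# ---------------------------------------------------------------------------
# leave-one-out


@dataclass
class LeaveOneOutResult:
    table: CohortTable
    per_case: dict[str, SingleResult]
    failures: dict[str, str]


def run_leave_one_out(
    cases: list[CaseRecord],
    cfg: PipelineConfig | None = None,
    out_dir=None,
) -> LeaveOneOutResult:
    """For every case, segment it with all the other cases as the atlas set
    and evaluate against its references; aggregate the comparisons into a
    cohort table.  Per-case failures are excluded and counted."""
    cfg = cfg or PipelineConfig()
    if len(cases) < 4:
        raise ValueError("leave-one-out needs at least 4 cases (target + 3 atlases)")
    ids = [c.patient_id for c in cases]
    if len(set(ids)) != len(ids):
        raise ValueError("case ids must be unique")
    per_case: dict[str, SingleResult] = {}
    failures: dict[str, str] = {}
    all_comparisons: list[tuple[str, str, ComparisonResult]] = []
    for i, target in enumerate(cases):
        atlas_cases = cases[:i] + cases[i + 1 :]
        try:
            res = run_single(target, atlas_cases, cfg, out_dir=out_dir)
        except Exception as exc:  # per-case failure must not sink the cohort
            failures[target.patient_id] = str(exc)
            continue
        per_case[target.patient_id] = res
        all_comparisons.extend(res.comparisons)
    if not all_comparisons:
        raise RuntimeError(f"every case failed: {failures}")
    table = cohort_table(all_comparisons, n_failed=len(failures))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "report.csv")
        cfg.to_yaml(out / "config.yaml")
        if failures:
            (out / "failures.yaml").write_text(yaml.safe_dump(failures))
    return LeaveOneOutResult(table=table, per_case=per_case, failures=failures)


# ---------------------------------------------------------------------------
# manifests and cohort I/O


def load_manifest(path) -> list[CaseRecord]:
    """Read a study manifest (YAML: patient id -> phase label -> image path,
    with optional reference masks) into case records.  Relative paths are
    resolved against the manifest's directory."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    root = path.parent
    cases: list[CaseRecord] = []
    seen = set()
    for entry in doc.get("patients", []):
        pid = str(entry["id"])
        if pid in seen:
            raise ValueError(f"duplicate patient id {pid!r} in manifest")
        seen.add(pid)
        truth_paths = entry.get("truth", {}) or {}
        phases = []
        for lab, img_path in entry["phases"].items():
            img = read_volume(root / img_path)
            truth = None
            if lab in truth_paths:
                truth = read_volume(root / truth_paths[lab], as_mask=True, role="truth")
            phases.append((str(lab), img, truth))
        cases.append(CaseRecord(pid, Phase4DStudy(pid, phases)))
    if not cases:
        raise ValueError(f"manifest {path} lists no patients")
    return cases


def write_cohort(cases: list[CaseRecord], out_dir) -> Path:
    """Write every case's phase images and reference masks as NIfTI plus a
    manifest.yaml listing them; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = {"patients": []}
    for case in cases:
        case_dir = out / case.patient_id
        entry = {"id": case.patient_id, "phases": {}, "truth": {}}
        for lab, img, truth in case.study.phases:
            tag = lab.rstrip("%") + "pct"
            rel = f"{case.patient_id}/image_{tag}.nii.gz"
            write_volume(img, out / rel)
            entry["phases"][lab] = rel
            if truth is not None:
                rel_t = f"{case.patient_id}/truth_{tag}.nii.gz"
                write_volume(truth, out / rel_t)
                entry["truth"][lab] = rel_t
        if not entry["truth"]:
            del entry["truth"]
        doc["patients"].append(entry)
    manifest = out / "manifest.yaml"
    manifest.write_text(yaml.safe_dump(doc, sort_keys=False))
    return manifest


def cases_from_cohort(cohort, motion=None) -> list[CaseRecord]:
    """Turn phantom cases into cohort case records: single-phase studies of
    the base phantoms, or full 4D studies when a motion spec is given."""
    from .phantom import make_4d_study  # deferred: phantom imports fourd

    cases = []
    for member in cohort:
        if motion is None:
            study = Phase4DStudy(
                member.case_id,
                [("0%", member.image, member.truth["heart"])],
            )
        else:
            study = make_4d_study(member, motion)
        cases.append(CaseRecord(member.case_id, study))
    return cases
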