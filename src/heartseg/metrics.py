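"""Delineation comparison metrics: DSC, MASD and Hausdorff distance.

Conventions
-----------
* The *surface* of a mask is the set of centres of mask voxels that have at
  least one six-connected background neighbour; voxels on the grid boundary
  count the outside of the grid as background.  This voxel-centre surface is
  deterministic and directly checkable against a brute-force neighbour scan,
  unlike a mesh extraction.
* MASD symmetrises the two directed mean nearest-surface distances by
  averaging them (one of several conventions in contouring QA; documented
  here because published values rarely state which is used).
* All distances are Euclidean in mm on the physical grid; nearest-surface
  distances are computed with an exact Euclidean distance transform.
* Cohort statistics use the sample standard deviation (n-1 denominator);
  a single observation reports sd 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import BinaryMask, same_grid

__all__ = [
    "SurfacePointSet",
    "ComparisonResult",
    "CohortTable",
    "surface_points",
    "surface_voxels",
    "dsc",
    "masd",
    "hd",
    "compare_masks",
    "cohort_table",
]


@dataclass(frozen=True)
class SurfacePointSet:
    """Physical-space (mm) centres of a mask's boundary voxels."""

    points: np.ndarray  # (n, 3)

    def __len__(self) -> int:
        return int(self.points.shape[0])


@dataclass(frozen=True)
class ComparisonResult:
    dsc: float
    masd_mm: float
    hd_mm: float
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self) -> None:
        if not (0.0 <= self.dsc <= 1.0):
            raise ValueError(f"DSC out of [0, 1]: {self.dsc}")
        if not (0.0 <= self.masd_mm <= self.hd_mm + 1e-9):
            raise ValueError(f"require 0 <= MASD <= HD, got {self.masd_mm}, {self.hd_mm}")


def surface_voxels(mask: BinaryMask) -> np.ndarray:
    """Boolean array marking mask voxels with a six-connected background
    neighbour (grid-boundary voxels count the outside as background)."""
    if mask.is_empty():
        raise ValueError("empty mask has no surface")
    m = mask.values.astype(bool)
    padded = np.pad(m, 1, mode="constant", constant_values=False)
    interior = np.ones_like(m)
    for ax in range(3):
        for off in (0, 2):
            sl = [slice(1, -1)] * 3
            sl[ax] = slice(off, padded.shape[ax] - 2 + off)
            interior &= padded[tuple(sl)]
    return m & ~interior


def surface_points(mask: BinaryMask) -> SurfacePointSet:
    idx = np.argwhere(surface_voxels(mask)).astype(float)
    pts = (
        np.asarray(mask.origin)
        + (idx * np.asarray(mask.spacing)) @ mask.direction.T
    )
    return SurfacePointSet(points=pts)


def dsc(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|)."""
    same_grid(a, b)
    na = int(a.values.sum())
    nb = int(b.values.sum())
    if na == 0 and nb == 0:
        raise ValueError("DSC is undefined for two empty masks")
    inter = int(np.count_nonzero(a.values & b.values))
    return 2.0 * inter / (na + nb)


def _directed_stats(src_surf: np.ndarray, dist_to_other: np.ndarray) -> tuple[float, float]:
    d = dist_to_other[src_surf]
    return float(d.mean()), float(d.max())


def _surface_distances(a: BinaryMask, b: BinaryMask):
    same_grid(a, b)
    if a.is_empty() or b.is_empty():
        raise ValueError("surface distances require two nonempty masks")
    sa = surface_voxels(a)
    sb = surface_voxels(b)
    # exact EDT on the index grid scaled by spacing; the orthonormal direction
    # matrix preserves Euclidean distances, so physical == grid distances
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=a.spacing)
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=a.spacing)
    mean_ab, max_ab = _directed_stats(sa, dist_to_b)
    mean_ba, max_ba = _directed_stats(sb, dist_to_a)
    return mean_ab, max_ab, mean_ba, max_ba


def masd(a: BinaryMask, b: BinaryMask) -> float:
    """Mean absolute surface-to-surface distance in mm (average of the two
    directed mean nearest-surface distances)."""
    mean_ab, _, mean_ba, _ = _surface_distances(a, b)
    return 0.5 * (mean_ab + mean_ba)


def hd(a: BinaryMask, b: BinaryMask) -> float:
    """Hausdorff (maximum surface-to-surface) distance in mm."""
    _, max_ab, _, max_ba = _surface_distances(a, b)
    return max(max_ab, max_ba)


def compare_masks(a: BinaryMask, b: BinaryMask, label_a: str = "a", label_b: str = "b") -> ComparisonResult:
    mean_ab, max_ab, mean_ba, max_ba = _surface_distances(a, b)
    return ComparisonResult(
        dsc=dsc(a, b),
        masd_mm=0.5 * (mean_ab + mean_ba),
        hd_mm=max(max_ab, max_ba),
        label_a=label_a,
        label_b=label_b,
    )


# ---------------------------------------------------------------------------
# Cohort aggregation


@dataclass
class CohortTable:
    """Per-phase (plus pooled and PRV) mean +/- sd of each metric."""

    table: pd.DataFrame
    n: int
    n_failed: int = 0

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def row(self, phase: str) -> pd.Series:
        match = self.table[self.table["phase"] == phase]
        if match.empty:
            raise KeyError(f"no row for phase {phase!r}")
        return match.iloc[0]


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd


ALL_PHASES_ROW = "Average (all phases)"
PRV_ROW = "PRV"


def cohort_table(results, n_failed: int = 0) -> CohortTable:
    """Aggregate per-patient, per-phase comparison results.

    Parameters
    ----------
    results:
        iterable of ``(patient_id, phase_label, ComparisonResult)``; phase
        labels are strings such as ``"0%"`` ... ``"90%"`` or ``"PRV"``.
    n_failed:
        count of cohort members excluded due to per-case failures, surfaced
        in the table metadata.

    Returns a table with one row per phase, a pooled all-phases row and, when
    PRV comparisons are supplied, a PRV row.
    """
    records = list(results)
    if not records:
        raise ValueError("no comparison results to aggregate")
    by_phase: dict[str, list[ComparisonResult]] = {}
    patients = set()
    for pid, phase, res in records:
        patients.add(pid)
        by_phase.setdefault(str(phase), []).append(res)

    def _percent_key(label: str):
        try:
            return (0, float(label.rstrip("%")))
        except ValueError:
            return (1, label)

    rows = []
    phase_labels = sorted((p for p in by_phase if p != PRV_ROW), key=_percent_key)
    pooled: list[ComparisonResult] = []
    for phase in phase_labels:
        res = by_phase[phase]
        pooled.extend(res)
        rows.append(_table_row(phase, res))
    if pooled:
        rows.append(_table_row(ALL_PHASES_ROW, pooled))
    if PRV_ROW in by_phase:
        rows.append(_table_row(PRV_ROW, by_phase[PRV_ROW]))
    return CohortTable(table=pd.DataFrame(rows), n=len(patients), n_failed=n_failed)


def _table_row(label: str, res: list[ComparisonResult]) -> dict:
    d_mean, d_sd = _mean_sd([r.dsc for r in res])
    m_mean, m_sd = _mean_sd([r.masd_mm for r in res])
    h_mean, h_sd = _mean_sd([r.hd_mm for r in res])
    return {
        "phase": label,
        "n": len(res),
        "dsc_mean": d_mean,
        "dsc_sd": d_sd,
        "masd_mm_mean": m_mean,
        "masd_mm_sd": m_sd,
        "hd_mm_mean": h_mean,
        "hd_mm_sd": h_sd,
    }
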