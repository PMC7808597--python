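"""Synthetic 4D thorax phantom cohort with ground-truth heart and lung masks.

The phantom emulates the data regime of respiratory-binned thoracic 4D-CT for
radiotherapy planning: a soft-tissue body with two low-density lungs and a
heart sitting in the mediastinum between them.  The heart/body boundary is
deliberately low-contrast (5 HU step under 10 HU noise by default), because
the difficulty of that boundary is precisely what makes automatic whole-heart
delineation on non-contrast CT hard; the lateral heart surface, in contrast,
abuts lung and is high-contrast, as in real anatomy.

A 4D study renders ten respiratory phases of one phantom.  The respiratory
trace is a cosine, with phase 0 fixed at full exhale: the superior-inferior
displacement of the heart (and of the lung floors, i.e. the diaphragm) at
phase ``p`` of ``n`` is ``amplitude * (1 - cos(2*pi*p/n)) / 2``, plus a
configurable anterior-posterior fraction.  Phases are regenerated
analytically from the displaced geometry, so the per-phase ground-truth
masks are exact voxelisations rather than interpolated warps.  The noise
realisation is shared across the phases of one study (so a zero-amplitude
study is bit-identical across phases), but differs between cohort members.

All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .image import BinaryMask, Image3D
from .fourd import Phase4DStudy, PHASE_LABELS

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "MotionSpec",
    "PhantomCase",
    "default_phantom_spec",
    "make_phantom",
    "make_cohort",
    "make_4d_study",
    "mip_image",
    "respiratory_displacement",
]


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid, optionally rotated about the z axis (degrees)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    angle_deg: float = 0.0

    def membership(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"degenerate ellipsoid radii {self.radii}")
        cx, cy, cz = self.center
        dx, dy, dz = x - cx, y - cy, z - cz
        if self.angle_deg:
            a = math.radians(self.angle_deg)
            dx, dy = math.cos(a) * dx + math.sin(a) * dy, -math.sin(a) * dx + math.cos(a) * dy
        rx, ry, rz = self.radii
        return (dx / rx) ** 2 + (dy / ry) ** 2 + (dz / rz) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise of one synthetic thorax."""

    dims: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    # body: elliptic cylinder — ellipse in the axial (x, y) plane, |z - cz| <= rz
    body: Ellipsoid = Ellipsoid(center=(0.0, 0.0, 0.0), radii=(70.0, 55.0, 200.0))
    lungs: tuple[Ellipsoid, Ellipsoid] = (
        Ellipsoid(center=(-34.0, 4.0, 6.0), radii=(22.0, 32.0, 48.0)),
        Ellipsoid(center=(34.0, 4.0, 6.0), radii=(22.0, 32.0, 48.0)),
    )
    heart: Ellipsoid = Ellipsoid(center=(2.0, -6.0, -8.0), radii=(26.0, 22.0, 30.0), angle_deg=20.0)
    intensities: dict = field(
        default_factory=lambda: {"air": -1000.0, "body": 40.0, "lung": -750.0, "heart": 45.0}
    )
    noise_sd: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for e in (self.body, self.heart, *self.lungs):
            if any(r <= 0 for r in e.radii):
                raise ValueError(f"degenerate geometry: radii {e.radii}")
        if self.intensities["lung"] >= self.intensities["body"]:
            raise ValueError("lung intensity must be below body intensity")
        lx = sorted(l.center[0] for l in self.lungs)
        if not (lx[0] < self.heart.center[0] < lx[1]):
            raise ValueError("heart must lie between the lungs")
        # heart inside the body cross-section (conservative axis check)
        hx, hy, _ = self.heart.center
        hr = max(self.heart.radii[:2])
        bx, by = self.body.radii[:2]
        if (abs(hx) + hr) > bx or (abs(hy) + hr) > by:
            raise ValueError("heart must lie inside the body")
        # lungs must keep a chest wall between themselves and the exterior
        # air, or intensity-based lung segmentation could not separate them
        for lung in self.lungs:
            if not self._inside_body(lung, wall_mm=3.0):
                raise ValueError("lung pierces the body wall")

    def _inside_body(self, e: Ellipsoid, wall_mm: float) -> bool:
        """Sampled check that an ellipsoid surface stays inside the body
        (elliptic cylinder) shrunk by ``wall_mm``."""
        u = np.linspace(0.0, np.pi, 13)
        v = np.linspace(0.0, 2.0 * np.pi, 25)
        uu, vv = np.meshgrid(u, v)
        rx, ry, rz = e.radii
        sx = rx * np.sin(uu) * np.cos(vv)
        sy = ry * np.sin(uu) * np.sin(vv)
        sz = rz * np.cos(uu)
        if e.angle_deg:
            a = math.radians(e.angle_deg)
            sx, sy = math.cos(a) * sx - math.sin(a) * sy, math.sin(a) * sx + math.cos(a) * sy
        px, py, pz = sx + e.center[0], sy + e.center[1], sz + e.center[2]
        bx, by = self.body.radii[0] - wall_mm, self.body.radii[1] - wall_mm
        bcx, bcy, bcz = self.body.center
        in_xy = ((px - bcx) / bx) ** 2 + ((py - bcy) / by) ** 2 <= 1.0
        in_z = np.abs(pz - bcz) <= self.body.radii[2] - wall_mm
        return bool(np.all(in_xy & in_z))

    def grid_origin(self) -> tuple[float, float, float]:
        # centre the grid on the body axis
        return tuple(-s * (n - 1) / 2.0 for s, n in zip(self.spacing, self.dims))


@dataclass(frozen=True)
class MotionSpec:
    """Parametric respiratory motion for a 4D study.

    ``amplitude_mm`` is the peak superior-inferior displacement of the heart
    and diaphragm over the breathing cycle; displacement of the heart
    measured in-treatment has been reported up to ~13 mm, and the 10 mm
    default sits inside that envelope.
    """

    amplitude_mm: float = 10.0
    ap_fraction: float = 0.3
    n_phases: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.amplitude_mm < 0:
            raise ValueError("amplitude_mm must be >= 0")
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")


@dataclass
class PhantomCase:
    """One synthetic patient: image plus exact truth masks."""

    case_id: str
    image: Image3D
    truth: dict[str, BinaryMask]
    spec: PhantomSpec


def default_phantom_spec(**overrides) -> PhantomSpec:
    return replace(PhantomSpec(), **overrides) if overrides else PhantomSpec()


def _coordinate_grids(spec: PhantomSpec):
    origin = spec.grid_origin()
    axes = [
        origin[ax] + np.arange(spec.dims[ax]) * spec.spacing[ax] for ax in range(3)
    ]
    return np.meshgrid(*axes, indexing="ij")


def make_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render one phantom: region membership (heart > lung > body > air
    innermost-first) plus additive Gaussian noise; truth masks are the exact
    membership sets before noise."""
    spec.validate()
    x, y, z = _coordinate_grids(spec)

    bx, by = spec.body.radii[:2]
    bcx, bcy, bcz = spec.body.center
    in_body = (((x - bcx) / bx) ** 2 + ((y - bcy) / by) ** 2 <= 1.0) & (
        np.abs(z - bcz) <= spec.body.radii[2]
    )
    in_lung = np.zeros(spec.dims, dtype=bool)
    for lung in spec.lungs:
        in_lung |= lung.membership(x, y, z)
    in_heart = spec.heart.membership(x, y, z)

    hu = spec.intensities
    values = np.full(spec.dims, hu["air"], dtype=np.float64)
    values[in_body] = hu["body"]
    values[in_lung & in_body] = hu["lung"]
    values[in_heart & in_body] = hu["heart"]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=spec.dims)

    origin = spec.grid_origin()
    image = Image3D(values=values, spacing=spec.spacing, origin=origin)
    heart_mask = BinaryMask(
        values=(in_heart & in_body).astype(np.uint8),
        spacing=spec.spacing,
        origin=origin,
        role="truth",
    )
    lungs_mask = BinaryMask(
        values=(in_lung & in_body & ~in_heart).astype(np.uint8),
        spacing=spec.spacing,
        origin=origin,
        role="lungs",
    )
    return PhantomCase(case_id="base", image=image, truth={"heart": heart_mask, "lungs": lungs_mask}, spec=spec)


def _perturbed_spec(base: PhantomSpec, variation: float, rng: np.random.Generator, seed: int) -> PhantomSpec:
    def jitter_ellipsoid(e: Ellipsoid, angle_sd: float = 0.0) -> Ellipsoid:
        radii = tuple(r * (1.0 + rng.normal(0.0, variation)) for r in e.radii)
        center = tuple(
            c + rng.normal(0.0, variation * r) for c, r in zip(e.center, e.radii)
        )
        angle = e.angle_deg + (rng.normal(0.0, angle_sd) if angle_sd else 0.0)
        return Ellipsoid(center=center, radii=radii, angle_deg=angle)

    return replace(
        base,
        body=jitter_ellipsoid(base.body),
        lungs=(jitter_ellipsoid(base.lungs[0]), jitter_ellipsoid(base.lungs[1])),
        heart=jitter_ellipsoid(base.heart, angle_sd=variation * 50.0),
        seed=seed,
    )


def make_cohort(
    n: int,
    base: PhantomSpec | None = None,
    variation: float = 0.08,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate ``n`` phantoms by fractional Gaussian perturbation of the base
    geometry (sd = ``variation`` of each radius, and of each centre coordinate
    scaled by the corresponding radius).  Members violating the phantom
    invariants are rejected and resampled.  Each member receives its own
    noise realisation drawn from the cohort seed.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 members")
    if base is None:
        base = default_phantom_spec()
    base.validate()
    rng = np.random.default_rng(seed)
    cohort = []
    for j in range(n):
        member_seed = int(rng.integers(0, 2**31 - 1))
        if variation == 0:
            spec = replace(base)
        else:
            for _attempt in range(100):
                spec = _perturbed_spec(base, variation, rng, member_seed)
                try:
                    spec.validate()
                    break
                except ValueError:
                    continue
            else:
                raise RuntimeError("could not draw a valid cohort member in 100 attempts")
        case = make_phantom(spec)
        case.case_id = f"case{j:02d}"
        cohort.append(case)
    return cohort


def respiratory_displacement(phase: int, motion: MotionSpec) -> float:
    """Superior-inferior displacement (mm) at an integer phase index; 0 at
    phase 0 (full exhale), peaking at mid-cycle (full inhale)."""
    return motion.amplitude_mm * (1.0 - math.cos(2.0 * math.pi * phase / motion.n_phases)) / 2.0


def _displaced_spec(spec: PhantomSpec, s_mm: float, ap_fraction: float) -> PhantomSpec:
    """Geometry at SI displacement ``s_mm``: heart translates inferiorly (-z)
    and anteriorly (+y, scaled); lung floors follow the diaphragm (inferior
    edge down by ``s_mm``) while the apices stay fixed."""
    h = spec.heart
    heart = replace(
        h,
        center=(h.center[0], h.center[1] + ap_fraction * s_mm, h.center[2] - s_mm),
    )
    lungs = tuple(
        replace(
            l,
            center=(l.center[0], l.center[1], l.center[2] - s_mm / 2.0),
            radii=(l.radii[0], l.radii[1], l.radii[2] + s_mm / 2.0),
        )
        for l in spec.lungs
    )
    return replace(spec, heart=heart, lungs=lungs)


def make_4d_study(base: PhantomCase, motion: MotionSpec) -> Phase4DStudy:
    """Render a respiratory-binned study of ``n_phases`` volumes from one
    phantom; phase 0 is bit-identical to the base phantom and every phase
    carries its exact truth heart mask."""
    motion.validate()
    spec = base.spec
    # peak displacement must keep the heart inside the grid
    z_lo = spec.grid_origin()[2]
    heart_floor = spec.heart.center[2] - spec.heart.radii[2] - motion.amplitude_mm
    if heart_floor < z_lo:
        raise ValueError(
            f"amplitude {motion.amplitude_mm} mm pushes the heart outside the grid"
        )
    labels = PHASE_LABELS if motion.n_phases == 10 else tuple(
        f"{round(100 * p / motion.n_phases)}%" for p in range(motion.n_phases)
    )
    phases = []
    for p in range(motion.n_phases):
        s = respiratory_displacement(p, motion)
        case_p = make_phantom(_displaced_spec(spec, s, motion.ap_fraction))
        phases.append((labels[p], case_p.image, case_p.truth["heart"]))
    return Phase4DStudy(patient_id=base.case_id, phases=phases)


def mip_image(study: Phase4DStudy) -> Image3D:
    """Maximum intensity projection across phases (voxelwise maximum), the
    image clinically used to contour motion-encompassing volumes."""
    ref = study.phases[0][1]
    stack = np.stack([img.values for _, img, _ in study.phases], axis=0)
    return Image3D(
        values=stack.max(axis=0),
        spacing=ref.spacing,
        origin=ref.origin,
        direction=ref.direction.copy(),
    )
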