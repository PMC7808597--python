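import numpy as np
import pytest

import heartseg as hs


@pytest.fixture(scope="session")
def default_case() -> hs.PhantomCase:
    """The default 64^3 thorax phantom (2.5 mm isotropic, 10 HU noise)."""
    return hs.make_phantom(hs.default_phantom_spec())


@pytest.fixture(scope="session")
def study_10mm(default_case) -> hs.Phase4DStudy:
    """Ten-phase study of the default phantom with 10 mm SI amplitude."""
    return hs.make_4d_study(default_case, hs.MotionSpec(amplitude_mm=10.0))


def random_mask(rng: np.random.Generator, dims, spacing=(1.0, 1.0, 1.0), p=0.3) -> hs.BinaryMask:
    """Random nonempty mask used by oracle-equivalence tests."""
    while True:
        vals = (rng.random(dims) < p).astype(np.uint8)
        if vals.any():
            return hs.BinaryMask(values=vals, spacing=spacing)


def blob_mask(rng: np.random.Generator, dims, spacing=(1.0, 1.0, 1.0)) -> hs.BinaryMask:
    """Random solid ellipsoid blob — a more contour-like mask."""
    center = rng.uniform(0.25, 0.75, 3) * np.asarray(dims)
    radii = rng.uniform(0.15, 0.35, 3) * np.asarray(dims)
    idx = np.stack(np.meshgrid(*(np.arange(n) for n in dims), indexing="ij"), axis=-1)
    vals = ((((idx - center) / radii) ** 2).sum(axis=-1) <= 1.0).astype(np.uint8)
    if not vals.any():
        vals[tuple(int(c) for c in center)] = 1
    return hs.BinaryMask(values=vals, spacing=spacing)
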