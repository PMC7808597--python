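"""Multi-atlas machinery: consensus, deviation scoring, discordant-atlas
rejection and local-weighted label fusion."""

import numpy as np
import pytest

import heartseg as hs
from heartseg.fusion import MIN_ATLASES, PropagatedAtlas
from heartseg.registration import RigidTransform

from conftest import blob_mask


def propagated_from_mask(pid: str, mask: hs.BinaryMask, image: hs.Image3D | None = None) -> PropagatedAtlas:
    if image is None:
        image = hs.Image3D(
            values=mask.values.astype(float), spacing=mask.spacing,
            origin=mask.origin, direction=mask.direction.copy(),
        )
    return PropagatedAtlas(id=pid, warped_image=image, warped_mask=mask)


def shifted_mask(mask: hs.BinaryMask, shift_mm) -> hs.BinaryMask:
    ref = hs.Image3D(values=np.zeros(mask.dims), spacing=mask.spacing, origin=mask.origin,
                     direction=mask.direction.copy())
    t = RigidTransform(np.eye(3), np.asarray(shift_mm, dtype=float), np.zeros(3))
    return hs.apply_to_mask(t, mask, ref)


@pytest.fixture(scope="module")
def heart_masks(default_case):
    """Seven mildly jittered copies of the truth heart (concordant set)."""
    heart = default_case.truth["heart"]
    rng = np.random.default_rng(21)
    masks = [heart]
    for _ in range(6):
        masks.append(shifted_mask(heart, rng.normal(0.0, 0.8, 3)))
    return masks


class TestConsensus:
    def test_unanimous(self, default_case):
        heart = default_case.truth["heart"]
        props = [propagated_from_mask(f"a{i}", heart) for i in range(4)]
        cons = hs.consensus_mask(props)
        np.testing.assert_array_equal(cons.values, heart.values)

    def test_majority_arithmetic(self):
        dims = (4, 4, 4)
        by_two = np.zeros(dims, dtype=np.uint8); by_two[0, 0, 0] = 1
        by_one = np.zeros(dims, dtype=np.uint8); by_one[1, 1, 1] = 1
        masks = [
            hs.BinaryMask(values=by_two | by_one),
            hs.BinaryMask(values=by_two),
            hs.BinaryMask(values=np.zeros(dims, dtype=np.uint8)),
        ]
        masks[2].values[2, 2, 2] = 1  # avoid empty-mask degenerate case
        cons = hs.consensus_mask([propagated_from_mask(str(i), m) for i, m in enumerate(masks)])
        assert cons.values[0, 0, 0] == 1  # 2 of 3 votes
        assert cons.values[1, 1, 1] == 0  # 1 of 3 votes
        assert cons.values[2, 2, 2] == 0

    def test_tie_resolves_to_zero(self):
        dims = (3, 3, 3)
        on = np.zeros(dims, dtype=np.uint8); on[1, 1, 1] = 1
        off = np.zeros(dims, dtype=np.uint8); off[0, 0, 0] = 1
        props = [propagated_from_mask(str(i), hs.BinaryMask(values=v.copy()))
                 for i, v in enumerate([on, on, off, off])]
        assert hs.consensus_mask(props).values[1, 1, 1] == 0  # exactly half

    def test_matches_vote_count_oracle(self):
        rng = np.random.default_rng(8)
        masks = [blob_mask(rng, (10, 10, 10)) for _ in range(5)]
        props = [propagated_from_mask(str(i), m) for i, m in enumerate(masks)]
        cons = hs.consensus_mask(props)
        votes = sum(m.values.astype(int) for m in masks)
        np.testing.assert_array_equal(cons.values, (votes > 2.5).astype(np.uint8))


class TestDeviationScores:
    def test_zero_for_identical(self, default_case):
        heart = default_case.truth["heart"]
        props = [propagated_from_mask(f"a{i}", heart) for i in range(3)]
        cons = hs.consensus_mask(props)
        assert hs.atlas_deviation_scores(props, cons) == [0.0, 0.0, 0.0]

    def test_translation_gives_matching_masd(self):
        # a compact blob translated by 10 mm scores a deviation of ~10 mm
        # (for extended shapes the surface-distance average is smaller, since
        # surface points moving tangentially stay close to the surface)
        dims, spacing = (24, 24, 24), (2.5, 2.5, 2.5)
        idx = np.stack(np.meshgrid(*(np.arange(n) for n in dims), indexing="ij"), axis=-1)
        center = np.array([12, 12, 8])
        blob = ((((idx - center) * 2.5) ** 2).sum(-1) <= 2.5**2).astype(np.uint8)
        mask = hs.BinaryMask(values=blob, spacing=spacing)
        moved = shifted_mask(mask, (0.0, 0.0, 10.0))
        props = [propagated_from_mask("a", mask), propagated_from_mask("b", moved),
                 propagated_from_mask("c", mask)]
        cons = hs.consensus_mask(props)
        scores = hs.atlas_deviation_scores(props, cons)
        assert scores[0] == 0.0 and scores[2] == 0.0
        assert scores[1] == pytest.approx(10.0, abs=2.5)

    def test_empty_mask_infinite(self, default_case):
        heart = default_case.truth["heart"]
        empty = hs.BinaryMask(values=np.zeros(heart.dims, dtype=np.uint8),
                              spacing=heart.spacing, origin=heart.origin)
        props = [propagated_from_mask("a", heart), propagated_from_mask("b", heart),
                 propagated_from_mask("c", empty)]
        cons = hs.consensus_mask(props)
        scores = hs.atlas_deviation_scores(props, cons)
        assert np.isinf(scores[2])

    def test_order_independent(self, heart_masks):
        props = [propagated_from_mask(str(i), m) for i, m in enumerate(heart_masks)]
        cons = hs.consensus_mask(props)
        fwd = hs.atlas_deviation_scores(props, cons)
        rev = hs.atlas_deviation_scores(props[::-1], cons)
        assert fwd == rev[::-1]


class TestSelectAtlases:
    def test_equal_deviations_keep_all(self, heart_masks):
        props = [propagated_from_mask(str(i), heart_masks[0]) for i in range(5)]
        cons = hs.consensus_mask(props)
        hs.atlas_deviation_scores(props, cons)
        assert len(hs.select_atlases(props)) == 5

    def test_displaced_atlas_rejected(self, heart_masks):
        displaced = shifted_mask(heart_masks[0], (0.0, 0.0, 20.0))
        props = [propagated_from_mask(str(i), m) for i, m in enumerate(heart_masks)]
        props.append(propagated_from_mask("displaced", displaced))
        cons = hs.consensus_mask(props)
        hs.atlas_deviation_scores(props, cons)
        retained = hs.select_atlases(props)
        ids = [p.id for p in retained]
        assert "displaced" not in ids
        assert len(ids) == len(heart_masks)

    def test_min_retained_floor(self, heart_masks):
        props = [propagated_from_mask(str(i), m) for i, m in enumerate(heart_masks[:4])]
        cons = hs.consensus_mask(props)
        hs.atlas_deviation_scores(props, cons)
        cfg = hs.FusionConfig(min_retained=4)
        assert len(hs.select_atlases(props, cfg)) == 4

    def test_order_preserved(self, heart_masks):
        props = [propagated_from_mask(str(i), m) for i, m in enumerate(heart_masks)]
        cons = hs.consensus_mask(props)
        hs.atlas_deviation_scores(props, cons)
        retained = hs.select_atlases(props)
        assert [p.id for p in retained] == sorted([p.id for p in retained], key=int)

    def test_too_few_inputs(self, heart_masks):
        props = [propagated_from_mask(str(i), m) for i, m in enumerate(heart_masks[:2])]
        with pytest.raises(ValueError):
            hs.select_atlases(props)


class TestLocalWeight:
    def test_identical_image_maximal_weight(self, default_case):
        img = default_case.image
        cfg = hs.FusionConfig(epsilon=1.0)
        w = hs.local_weight(img, img, cfg)
        np.testing.assert_allclose(w, 1.0)  # 1 / epsilon

    def test_monotone_in_local_difference(self, default_case):
        img = default_case.image
        offset = hs.Image3D(values=img.values + 100.0, spacing=img.spacing, origin=img.origin)
        w_same = hs.local_weight(img, img)
        w_off = hs.local_weight(img, offset)
        assert (w_same > w_off).all()

    def test_patch_mean_matches_brute_force(self):
        rng = np.random.default_rng(13)
        dims = (8, 8, 8)
        target = hs.Image3D(values=rng.normal(0, 50, dims), spacing=(2.0, 2.0, 2.0))
        warped = hs.Image3D(values=rng.normal(0, 50, dims), spacing=(2.0, 2.0, 2.0))
        cfg = hs.FusionConfig(patch_radius_mm=4.0, epsilon=1.0)  # radius 2 voxels
        w = hs.local_weight(target, warped, cfg)
        absdiff = np.abs(target.values - warped.values)
        r = 2
        for i in range(dims[0]):
            for j in range(dims[1]):
                for k in range(dims[2]):
                    patch = absdiff[
                        max(0, i - r) : i + r + 1,
                        max(0, j - r) : j + r + 1,
                        max(0, k - r) : k + r + 1,
                    ]
                    expect = 1.0 / (1.0 + patch.mean())
                    assert w[i, j, k] == pytest.approx(expect, abs=1e-9)


class TestFuseLabels:
    def test_unanimous_identity(self, default_case):
        heart = default_case.truth["heart"]
        props = [propagated_from_mask(str(i), heart, default_case.image) for i in range(4)]
        weights = [hs.local_weight(default_case.image, p.warped_image) for p in props]
        prob, fused = hs.fuse_labels(props, weights)
        np.testing.assert_array_equal(fused.values, heart.values)
        assert set(np.unique(prob.values)) <= {0.0, 1.0}

    def test_equal_weights_reduce_to_majority(self):
        rng = np.random.default_rng(17)
        masks = [blob_mask(rng, (8, 8, 8)) for _ in range(5)]
        props = [propagated_from_mask(str(i), m) for i, m in enumerate(masks)]
        weights = [np.full((8, 8, 8), 3.7) for _ in props]
        _, fused = hs.fuse_labels(props, weights)
        votes = sum(m.values.astype(int) for m in masks)
        majority = (votes / 5 >= 0.5).astype(np.uint8)  # >= threshold tie rule
        np.testing.assert_array_equal(fused.values, majority)

    def test_hand_built_weighted_example(self):
        # two atlases, weights 3 and 1 at a voxel with masks 1 and 0:
        # probability 3/4 = 0.75 -> labelled 1
        dims = (2, 1, 1)
        m1 = hs.BinaryMask(values=np.array([[[1]], [[1]]], dtype=np.uint8))
        m0 = hs.BinaryMask(values=np.array([[[0]], [[1]]], dtype=np.uint8))
        props = [propagated_from_mask("a", m1), propagated_from_mask("b", m0)]
        weights = [np.full(dims, 3.0), np.full(dims, 1.0)]
        prob, fused = hs.fuse_labels(props, weights)
        assert prob.values[0, 0, 0] == pytest.approx(0.75)
        assert fused.values[0, 0, 0] == 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(19)
        masks = [blob_mask(rng, (9, 9, 9)) for _ in range(4)]
        weights = [rng.uniform(0.5, 2.0, (9, 9, 9)) for _ in range(4)]
        props = [propagated_from_mask(str(i), m) for i, m in enumerate(masks)]
        prob_a, fused_a = hs.fuse_labels(props, weights)
        order = [2, 0, 3, 1]
        prob_b, fused_b = hs.fuse_labels([props[i] for i in order], [weights[i] for i in order])
        np.testing.assert_allclose(prob_a.values, prob_b.values, atol=1e-12)
        np.testing.assert_array_equal(fused_a.values, fused_b.values)

    def test_probability_bounded_and_monotone(self):
        rng = np.random.default_rng(23)
        masks = [blob_mask(rng, (8, 8, 8)) for _ in range(3)]
        weights = [rng.uniform(0.5, 2.0, (8, 8, 8)) for _ in range(3)]
        props = [propagated_from_mask(str(i), m) for i, m in enumerate(masks)]
        prob, _ = hs.fuse_labels(props, weights)
        assert prob.values.min() >= 0.0 and prob.values.max() <= 1.0
        # adding an all-ones atlas never decreases the probability anywhere
        ones = hs.BinaryMask(values=np.ones((8, 8, 8), dtype=np.uint8))
        props2 = props + [propagated_from_mask("ones", ones)]
        weights2 = weights + [rng.uniform(0.5, 2.0, (8, 8, 8))]
        prob2, _ = hs.fuse_labels(props2, weights2)
        assert (prob2.values >= prob.values - 1e-12).all()


class TestPropagateAtlases:
    def test_two_atlases_precondition(self, default_case):
        entries = [
            hs.AtlasEntry(id=str(i), image=default_case.image, mask=default_case.truth["heart"])
            for i in range(2)
        ]
        with pytest.raises(ValueError):
            hs.propagate_atlases(default_case.image, entries)

    def test_duplicate_ids_rejected(self, default_case):
        entries = [
            hs.AtlasEntry(id="same", image=default_case.image, mask=default_case.truth["heart"])
            for _ in range(3)
        ]
        with pytest.raises(ValueError):
            hs.propagate_atlases(default_case.image, entries)

    def test_self_atlas_registration(self, default_case):
        # an atlas identical to the target must come back almost unchanged
        entries = [
            hs.AtlasEntry(id=str(i), image=default_case.image, mask=default_case.truth["heart"])
            for i in range(MIN_ATLASES)
        ]
        props = hs.propagate_atlases(default_case.image, entries)
        assert len(props) == MIN_ATLASES
        for p in props:
            assert hs.dsc(p.warped_mask, default_case.truth["heart"]) >= 0.99

    def test_cohort_atlases_propagate_well(self, default_case):
        # leave-one-out style: warped atlas masks already overlap the target
        # truth well before any fusion
        cohort = hs.make_cohort(4, seed=31)
        entries = [hs.AtlasEntry(id=c.case_id, image=c.image, mask=c.truth["heart"]) for c in cohort[1:]]
        props = hs.propagate_atlases(cohort[0].image, entries)
        for p in props:
            assert hs.dsc(p.warped_mask, cohort[0].truth["heart"]) >= 0.8
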