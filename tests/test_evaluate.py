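"""Dice overlap, majority voting, report assembly and atlas construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ehugs import (
    ImageVolume,
    LabelVolume,
    atlas_sharpness,
    build_atlas,
    dice,
    dice_report,
    majority_vote_labels,
)


class TestDice:
    def test_identical_nonempty_masks(self):
        m = np.zeros((6, 6), bool)
        m[2:4, 2:4] = True
        assert dice(m, m) == 1.0

    def test_disjoint_nonempty_masks(self):
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[0, 0] = True
        b[5, 5] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros(30, bool)
        b = np.zeros(30, bool)
        a[:10] = True
        b[5:15] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_is_zero_by_convention(self):
        z = np.zeros((4, 4), bool)
        assert dice(z, z) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=hnp.arrays(bool, (5, 5), elements=st.booleans()),
        b=hnp.arrays(bool, (5, 5), elements=st.booleans()),
    )
    def test_symmetry_property(self, a, b):
        assert dice(a, b) == dice(b, a)


class TestMajorityVote:
    def _lv(self, arr):
        return LabelVolume(np.asarray(arr, dtype=np.int32))

    def test_identical_volumes_vote_to_themselves(self, rng):
        lv = self._lv(rng.integers(0, 4, (8, 8)))
        out = majority_vote_labels([lv, lv, lv])
        assert np.array_equal(out.data, lv.data)

    def test_two_to_one_majority(self):
        a = self._lv([[1]])
        b = self._lv([[1]])
        c = self._lv([[2]])
        assert majority_vote_labels([a, b, c]).data[0, 0] == 1

    def test_tie_breaks_to_lowest_label(self):
        a = self._lv([[1]])
        b = self._lv([[2]])
        assert majority_vote_labels([a, b]).data[0, 0] == 1

    def test_background_participates(self):
        a = self._lv([[0]])
        b = self._lv([[0]])
        c = self._lv([[3]])
        assert majority_vote_labels([a, b, c]).data[0, 0] == 0

    def test_order_invariance_with_strict_majority(self, rng):
        vols = [self._lv(rng.integers(0, 3, (6, 6))) for _ in range(3)]
        vols.append(self._lv(vols[0].data.copy()))
        vols.append(self._lv(vols[0].data.copy()))  # vols[0] has strict majority
        fwd = majority_vote_labels(vols).data
        rev = majority_vote_labels(vols[::-1]).data
        assert np.array_equal(fwd, rev)


class TestDiceReport:
    def _population(self, rng, n=4):
        base = np.zeros((16, 16), np.int32)
        base[4:12, 4:12] = 1
        base[6:10, 6:10] = 2
        vols = []
        for k in range(n):
            d = base.copy()
            if k:  # jitter one row to create disagreement
                d = np.roll(d, k % 2, axis=0)
            vols.append(LabelVolume(d, id=f"s{k}"))
        return vols

    def test_identical_inputs_score_one(self):
        lv = LabelVolume(np.tile([0, 1, 2, 3], (8, 2)), id="a")
        vols = [LabelVolume(lv.data.copy(), id=f"s{k}") for k in range(3)]
        rep = dice_report(vols)
        assert np.allclose(rep.per_image.values, 1.0)

    def test_permuting_images_reorders_rows_only(self, rng):
        vols = self._population(rng)
        rep = dice_report(vols)
        rep_perm = dice_report(vols[::-1])
        assert sorted(rep.per_image.index) == sorted(rep_perm.per_image.index)
        for sid in rep.per_image.index:
            assert np.allclose(
                rep.per_image.loc[sid].values, rep_perm.per_image.loc[sid].values
            )

    def test_absent_tissue_reported_missing(self, rng):
        vols = self._population(rng)
        rep = dice_report(vols, tissues={1: "WM", 2: "GM", 9: "ghost"})
        assert rep.per_image["ghost"].isna().all()
        assert rep.per_image["WM"].notna().all()

    def test_overall_is_mean_across_tissues(self, rng):
        vols = self._population(rng)
        rep = dice_report(vols)
        cols = [c for c in rep.per_image.columns if c != "overall"]
        assert np.allclose(
            rep.per_image["overall"], rep.per_image[cols].mean(axis=1), equal_nan=True
        )


class TestAtlas:
    def test_single_image_atlas(self):
        img = ImageVolume(np.arange(16.0).reshape(4, 4), id="a")
        lab = LabelVolume((np.arange(16) % 2).reshape(4, 4), id="a")
        atl = build_atlas([img], [lab])
        assert np.array_equal(atl.mean_image.data, img.data)
        for prob in atl.tissue_probability.values():
            assert set(np.unique(prob)) <= {0.0, 1.0}

    def test_mean_of_two_images(self):
        a = ImageVolume(np.zeros((4, 4)))
        b = ImageVolume(np.full((4, 4), 2.0))
        atl = build_atlas([a, b])
        assert np.allclose(atl.mean_image.data, 1.0)

    def test_probabilities_sum_to_one(self, rng):
        labs = [LabelVolume(rng.integers(0, 4, (8, 8)), id=f"s{k}") for k in range(5)]
        imgs = [ImageVolume(rng.random((8, 8)), id=f"s{k}") for k in range(5)]
        atl = build_atlas(imgs, labs)
        total = sum(atl.tissue_probability.values())
        assert np.allclose(total, 1.0)


class TestSharpness:
    def test_constant_image_has_zero_sharpness(self):
        assert atlas_sharpness(ImageVolume(np.full((8, 8), 5.0))) == 0.0

    def test_blurring_reduces_sharpness(self):
        from scipy import ndimage

        step = np.zeros((32, 32))
        step[:, 16:] = 1.0
        sharp = atlas_sharpness(ImageVolume(step))
        blurred = atlas_sharpness(ImageVolume(ndimage.gaussian_filter(step, 3.0)))
        assert sharp > blurred

    def test_structured_image_sharper_than_blurred_copy(self):
        from scipy import ndimage

        from ehugs import make_template

        img, _ = make_template("adult_like", (48, 48))
        blurred = ImageVolume(ndimage.gaussian_filter(img.data, 2.0))
        assert atlas_sharpness(img) > atlas_sharpness(blurred)
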