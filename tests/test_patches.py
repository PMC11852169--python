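import numpy as np
import pytest

from funduslab import patches as pmod
from funduslab.imaging import GrayImage
from funduslab.mcsd import Polarity, region_from_mask
from funduslab.patches import (AUGMENT_OPS, PatchKind, TrainingPatch, augment,
                               grow_clean_patch, indeterminate_pixel_mask,
                               mine_patch_pairs)
from funduslab.scoring import Bucket
from funduslab.typing_rules import LesionType


class TestGrowCleanPatch:
    def test_clean_canvas_reaches_maximum(self):
        indet = np.zeros((300, 300), bool)
        win = grow_clean_patch((150, 150), indet)
        r0, r1, c0, c1 = win
        assert (r1 - r0, c1 - c0) == (120, 120)

    def test_obstacle_at_22px_stalls_below_minimum(self):
        indet = np.zeros((300, 300), bool)
        indet[150, 172] = True  # 22 px right of center
        assert grow_clean_patch((150, 150), indet) is None

    def test_obstacle_just_outside_60_returns_60(self):
        indet = np.zeros((300, 300), bool)
        indet[150, 180] = True  # first covered by side 65, not side 60
        win = grow_clean_patch((150, 150), indet)
        r0, r1, c0, c1 = win
        assert (r1 - r0, c1 - c0) == (60, 60)
        assert not indet[r0:r1, c0:c1].any()

    def test_border_clipping_counts_toward_size(self):
        indet = np.zeros((300, 300), bool)
        # center 10 px from the border: the top of the window is clipped and
        # the clipped height (70) is what the size test sees
        win = grow_clean_patch((10, 150), indet)
        assert win is not None
        assert win[0] == 0 and win[1] - win[0] == 70
        # an obstacle shrinking the clipped window below 60 rejects it
        indet[40, 150] = True
        assert grow_clean_patch((10, 150), indet) is None

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        indet = rng.random((200, 200)) < 0.001
        wins = {grow_clean_patch((100, 100), indet) for _ in range(3)}
        assert len(wins) == 1

    def test_center_outside_bounds(self):
        assert grow_clean_patch((500, 10), np.zeros((100, 100), bool)) is None


def _fake_region(shape, center, radius, bucket, polarity=Polarity.DARK,
                 lesion_type=None, vessel_excluded=False):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    mask = np.hypot(yy - center[0], xx - center[1]) <= radius
    region = region_from_mask(mask, polarity)
    region.bucket = bucket
    region.centroid = center
    region.confidence = {Bucket.LOW: 0.1, Bucket.INDETERMINATE: 0.2,
                         Bucket.HIGH: 0.5}[bucket]
    region.lesion_type = lesion_type
    region.vessel_excluded = vessel_excluded
    return region


def _gray(shape=(300, 300), value=0.5):
    return GrayImage(np.full(shape, value), np.ones(shape, bool))


class TestIndeterminateMask:
    def test_only_ambiguous_regions_block(self):
        shape = (300, 300)
        regions = [
            _fake_region(shape, (50, 50), 4, Bucket.LOW),
            _fake_region(shape, (150, 150), 4, Bucket.INDETERMINATE),
            _fake_region(shape, (250, 250), 4, Bucket.HIGH,
                         lesion_type=LesionType.MICROANEURYSM),
            _fake_region(shape, (50, 250), 4, Bucket.HIGH,
                         vessel_excluded=True),
        ]
        m = indeterminate_pixel_mask(regions, shape)
        assert not m[50, 50] and not m[250, 250]
        assert m[150, 150] and m[50, 250]


class TestMinePatchPairs:
    def test_balanced_and_clean(self):
        shape = (300, 300)
        regions = [
            _fake_region(shape, (60, 60), 3, Bucket.HIGH,
                         lesion_type=LesionType.MICROANEURYSM),
            _fake_region(shape, (60, 240), 3, Bucket.HIGH,
                         lesion_type=LesionType.MICROANEURYSM),
            _fake_region(shape, (240, 60), 5, Bucket.HIGH,
                         lesion_type=LesionType.HEMORRHAGE),
            _fake_region(shape, (150, 150), 3, Bucket.INDETERMINATE),
        ]
        image = _gray(shape)
        negatives = [_gray(shape, 0.55)]
        mined = mine_patch_pairs(image, regions, negatives, rng_seed=7)
        for lt in (LesionType.MICROANEURYSM, LesionType.HEMORRHAGE):
            n_les = sum(1 for p in mined if p.lesion_type is lt
                        and p.kind is PatchKind.LESION)
            n_bg = sum(1 for p in mined if p.lesion_type is lt
                       and p.kind is PatchKind.BACKGROUND)
            assert n_les == n_bg > 0
        indet = indeterminate_pixel_mask(regions, shape)
        for p in mined:
            if p.kind is PatchKind.LESION:
                r0, c0 = p.origin
                h, w = p.window.shape
                assert not indet[r0:r0 + h, c0:c0 + w].any()

    def test_lesion_patch_carries_its_label(self):
        shape = (300, 300)
        regions = [_fake_region(shape, (150, 150), 3, Bucket.HIGH,
                                lesion_type=LesionType.MICROANEURYSM)]
        mined = mine_patch_pairs(_gray(shape), regions, [_gray(shape)],
                                 rng_seed=1)
        lesion = [p for p in mined if p.kind is PatchKind.LESION][0]
        lab = lesion.label_for(LesionType.MICROANEURYSM)
        assert lab.sum() == regions[0].area

    def test_no_high_regions_yields_empty(self):
        mined = mine_patch_pairs(_gray(), [], [_gray()], rng_seed=0)
        assert mined == []

    def test_high_region_near_indeterminate_yields_nothing(self):
        shape = (300, 300)
        regions = [
            _fake_region(shape, (150, 150), 3, Bucket.HIGH,
                         lesion_type=LesionType.MICROANEURYSM),
            _fake_region(shape, (150, 165), 3, Bucket.INDETERMINATE),
        ]
        mined = mine_patch_pairs(_gray(shape), regions, [_gray(shape)],
                                 rng_seed=0)
        assert mined == []

    def test_seed_reproducibility(self):
        shape = (300, 300)
        regions = [_fake_region(shape, (150, 150), 3, Bucket.HIGH,
                                lesion_type=LesionType.MICROANEURYSM)]
        a = mine_patch_pairs(_gray(shape), regions, [_gray(shape)], rng_seed=7)
        b = mine_patch_pairs(_gray(shape), regions, [_gray(shape)], rng_seed=7)
        assert [p.origin for p in a] == [p.origin for p in b]


class TestAugment:
    def _patch(self):
        rng = np.random.default_rng(3)
        win = rng.random((60, 60))
        mask = np.zeros((60, 60), bool)
        mask[25:32, 28:36] = True
        return TrainingPatch(window=win,
                             label_masks={LesionType.MICROANEURYSM: mask},
                             origin=(0, 0), side=60, kind=PatchKind.LESION,
                             lesion_type=LesionType.MICROANEURYSM)

    def test_same_seed_is_deterministic(self):
        p = self._patch()
        a = augment(p, rng_seed=11)
        b = augment(p, rng_seed=11)
        np.testing.assert_array_equal(a.window, b.window)
        np.testing.assert_array_equal(
            a.label_for(LesionType.MICROANEURYSM),
            b.label_for(LesionType.MICROANEURYSM))

    def test_photometric_only_seeds_leave_mask_untouched(self):
        p = self._patch()
        geometric = {"translate", "crop", "pad", "scale", "flip", "rotate"}
        found = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            chosen = [op for op in AUGMENT_OPS if rng.random() < 0.5]
            if not set(chosen) & geometric:
                out = augment(p, rng_seed=seed)
                np.testing.assert_array_equal(
                    out.label_for(LesionType.MICROANEURYSM),
                    p.label_for(LesionType.MICROANEURYSM))
                found += 1
        assert found > 0

    def test_geometry_applies_identically_to_image_and_mask(self):
        # mask painted into the window: after any augmentation the marked
        # pixels must still be the brightest ones
        p = self._patch()
        p.window[:] = 0.2
        p.window[p.label_for(LesionType.MICROANEURYSM)] = 1.0
        for seed in range(10):
            out = augment(p, rng_seed=seed)
            m = out.label_for(LesionType.MICROANEURYSM)
            assert m.shape == out.window.shape
            if m.any() and (~m).any():
                assert out.window[m].mean() > out.window[~m].mean() + 0.3

    def test_output_side_renormalized(self):
        out = augment(self._patch(), rng_seed=4, out_side=48)
        assert out.window.shape == (48, 48)
        assert out.label_for(LesionType.MICROANEURYSM).shape == (48, 48)

    def test_values_stay_in_unit_range(self):
        for seed in range(8):
            out = augment(self._patch(), rng_seed=seed)
            assert out.window.min() >= 0.0 and out.window.max() <= 1.0


class TestArchive:
    def test_roundtrip(self, tmp_path):
        p = TrainingPatch(
            window=np.linspace(0, 1, 64 * 64).reshape(64, 64),
            label_masks={LesionType.HEMORRHAGE: np.eye(64, dtype=bool)},
            origin=(5, 9), side=64, kind=PatchKind.LESION,
            lesion_type=LesionType.HEMORRHAGE, source="img0")
        pmod.save_patch_archive([p], tmp_path, seed=3)
        back = pmod.load_patch_archive(tmp_path)
        assert len(back) == 1
        q = back[0]
        assert q.kind is PatchKind.LESION
        assert q.lesion_type is LesionType.HEMORRHAGE
        assert q.origin == (5, 9)
        np.testing.assert_array_equal(
            q.label_for(LesionType.HEMORRHAGE), np.eye(64, dtype=bool))
        assert np.abs(q.window - p.window).max() <= 1 / 255 + 1e-9
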