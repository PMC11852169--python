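import numpy as np
import pytest

from funduslab.errors import ConfigError, InputError
from funduslab.imaging import GrayImage, Profile
from funduslab.patches import PatchKind, TrainingPatch
from funduslab.typing_rules import LesionType
from funduslab.unet import (EarlyStopper, PlateauLRScheduler, UNet,
                            UNetConfig, _dice_loss_grad, dice_loss,
                            infer_masks, load_model, save_model, train_unet)


class TestConfig:
    def test_default_architecture_doubles_from_32(self):
        assert UNetConfig().encoder_filters == [32, 64, 128, 256]

    @pytest.mark.parametrize("kw", [{"stages": 0}, {"base_filters": 0},
                                    {"lr_factor": 1.5},
                                    {"input_side": 30},
                                    {"patch_fit": "tile"}])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigError):
            UNetConfig(**kw)


class TestDiceLoss:
    def test_perfect_overlap_near_zero(self):
        t = (np.random.default_rng(0).random((16, 16)) > 0.5).astype(float)
        assert dice_loss(t, t) < 1e-6

    def test_disjoint_near_one(self):
        t = np.zeros((16, 16))
        t[:8] = 1.0
        assert dice_loss(1.0 - t, t) > 1 - 1e-6

    def test_uniform_half_prediction_closed_form(self):
        # pred 0.5 everywhere, target half ones: 2*0.5*128/(0.5*256+128)=0.5
        t = np.zeros((16, 16))
        t[:8] = 1.0
        p = np.full((16, 16), 0.5)
        assert dice_loss(p, t) == pytest.approx(0.5, abs=1e-6)

    def test_symmetric_for_binary_and_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = (rng.random((8, 8)) > 0.5).astype(float)
            b = (rng.random((8, 8)) > 0.5).astype(float)
            assert dice_loss(a, b) == pytest.approx(dice_loss(b, a))
            assert 0.0 <= dice_loss(a, b) <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestArchitecture:
    def test_filter_counts_per_stage(self):
        model = UNet(UNetConfig(input_side=32))
        assert [b.c1.cout for b in model.enc] == [32, 64, 128, 256]
        assert [b.c2.cout for b in model.enc] == [32, 64, 128, 256]
        # decoder mirrors the encoder
        assert [blk.c1.cout for (_u, _r, _rl, blk) in model.dec] == [128, 64, 32]

    def test_forward_shape_and_range(self):
        model = UNet(UNetConfig(stages=3, base_filters=4, input_side=16))
        p = model.forward(np.zeros((2, 1, 16, 16), dtype=np.float32))
        assert p.shape == (2, 1, 16, 16)
        assert (p > 0).all() and (p < 1).all()

    def test_backward_matches_numeric_gradient(self):
        cfg = UNetConfig(stages=2, base_filters=2, input_side=8, seed=0)
        net = UNet(cfg)
        rng = np.random.default_rng(0)
        x = rng.random((2, 1, 8, 8)).astype(np.float32)
        y = (rng.random((2, 1, 8, 8)) > 0.5).astype(np.float32)
        p = net.forward(x)
        _l, grad = _dice_loss_grad(p, y)
        net.zero_grad()
        net.backward(grad)
        params = net.params()
        for pi in (0, 3, len(params) - 2):
            w, g = params[pi]
            idx = tuple(0 for _ in w.shape)
            eps, old = 1e-3, w[idx].copy()
            w[idx] = old + eps
            lp = _dice_loss_grad(net.forward(x), y)[0]
            w[idx] = old - eps
            lm = _dice_loss_grad(net.forward(x), y)[0]
            w[idx] = old
            assert g[idx] == pytest.approx((lp - lm) / (2 * eps), abs=2e-3)


class TestSchedules:
    def test_lr_halves_after_three_flat_epochs(self):
        s = PlateauLRScheduler(1e-3, factor=0.5, patience=3)
        assert s.step(0.5) == 1e-3          # improvement
        assert s.step(0.4) == 1e-3          # bad 1
        assert s.step(0.4) == 1e-3          # bad 2
        assert s.step(0.4) == pytest.approx(5e-4)  # bad 3 -> halve
        assert s.step(0.9) == pytest.approx(5e-4)  # recovery keeps new lr

    def test_early_stop_after_ten_flat_epochs(self):
        e = EarlyStopper(patience=10)
        assert not e.step(0.5)
        for i in range(9):
            assert not e.step(0.4)
        assert e.step(0.4)  # tenth non-improving epoch


def _blob_patches(n, side=24, seed=0):
    """Synthetic dark-blob patches with matching masks."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        win = np.clip(rng.normal(0.55, 0.02, (side, side)), 0, 1)
        mask = np.zeros((side, side), bool)
        if i % 2 == 0:
            r, c = rng.integers(6, side - 6, size=2)
            yy, xx = np.mgrid[0:side, 0:side]
            mask = np.hypot(yy - r, xx - c) <= 2.5
            win[mask] -= 0.3
            kind = PatchKind.LESION
        else:
            kind = PatchKind.BACKGROUND
        out.append(TrainingPatch(
            window=np.clip(win, 0, 1),
            label_masks={LesionType.MICROANEURYSM: mask},
            origin=(0, 0), side=side, kind=kind,
            lesion_type=LesionType.MICROANEURYSM))
    return out


class TestTraining:
    def test_smoke_training_reduces_loss_and_is_seeded(self):
        pats = _blob_patches(24)
        cfg = UNetConfig(input_side=24, batch_size=8, max_epochs=3, seed=1,
                         patch_fit="crop")
        model, hist = train_unet(pats, cfg, augment_data=False)
        assert len(hist["train_loss"]) == 3
        assert hist["train_loss"][-1] < hist["train_loss"][0]
        model2, hist2 = train_unet(pats, cfg, augment_data=False)
        assert hist2["train_loss"] == hist["train_loss"]

    def test_too_few_patches_rejected(self):
        with pytest.raises(InputError):
            train_unet(_blob_patches(2), UNetConfig(input_side=24))

    def test_save_load_roundtrip(self, tmp_path):
        pats = _blob_patches(8)
        cfg = UNetConfig(input_side=16, batch_size=4, max_epochs=1, seed=0,
                         patch_fit="crop")
        model, _ = train_unet(pats, cfg, augment_data=False,
                              profile=Profile.CFP)
        path = save_model(model, tmp_path / "m")
        back = load_model(path)
        assert back.lesion_type is LesionType.MICROANEURYSM
        assert back.profile is Profile.CFP
        x = np.random.default_rng(2).random((1, 1, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), back.forward(x))


class TestInference:
    def _gray(self, shape=(60, 60), profile=None):
        rng = np.random.default_rng(4)
        return GrayImage(rng.random(shape), np.ones(shape, bool), profile)

    def test_deterministic_for_fixed_seed(self):
        model = UNet(UNetConfig(stages=2, base_filters=4, input_side=16,
                                seed=5))
        g = self._gray()
        m1, c1 = infer_masks(model, g)
        m2, c2 = infer_masks(model, g)
        np.testing.assert_array_equal(m1, m2)
        assert len(c1) == len(c2)

    def test_threshold_one_gives_empty_mask(self):
        model = UNet(UNetConfig(stages=2, base_filters=4, input_side=16))
        mask, comps = infer_masks(model, self._gray(), threshold=1.0)
        assert not mask.any() and comps == []

    def test_profile_mismatch_rejected(self):
        model = UNet(UNetConfig(stages=2, base_filters=4, input_side=16),
                     profile=Profile.CFP)
        with pytest.raises(ConfigError):
            infer_masks(model, self._gray(profile=Profile.UWF))

    def test_mask_confined_to_fov(self):
        model = UNet(UNetConfig(stages=2, base_filters=4, input_side=16))
        g = self._gray()
        g.fov[:, :30] = False
        mask, _ = infer_masks(model, g, threshold=0.0)
        assert not mask[:, :30].any()
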