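"""Desk-scale U-Net segmentation harness (pure numpy).

A classical encoder/decoder U-Net: four stages of double 3x3
convolution blocks starting at 32 filters and doubling per stage
(32/64/128/256), 2x2 max-pooling between encoder stages, nearest-neighbor
upsampling with skip concatenation in the decoder, and a 1x1 sigmoid
output head. Training minimizes the Dice loss with Adam, reduces the
learning rate by 0.5 after 3 epochs without validation improvement and
stops early after 10 epochs without improvement.

Forward and backward passes are written directly on numpy arrays (im2col
convolutions); this keeps the harness dependency-free and bit-reproducible
on one CPU thread, at desk scale (hundreds of patches, handfuls of
epochs) rather than production scale.

Layout convention: arrays are (N, C, H, W) float32.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field as dfield
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from skimage.transform import resize

from .errors import ConfigError, InputError
from .imaging import GrayImage, Profile
from .patches import PatchKind, TrainingPatch
from .typing_rules import LesionType

log = logging.getLogger(__name__)

EPS = 1e-6


@dataclass(frozen=True)
class UNetConfig:
    stages: int = 4
    base_filters: int = 32
    input_side: int = 96
    lr_init: float = 1e-3
    lr_factor: float = 0.5
    lr_patience: int = 3
    early_stop_patience: int = 10
    batch_size: int = 16
    max_epochs: int = 100
    seed: int = 0
    #: how a mined window becomes a model input: "resize" rescales the whole
    #: window to input_side; "crop" center-crops at native resolution (and
    #: reflect-pads smaller windows), which keeps lesion scale consistent
    #: with sliding-window inference.
    patch_fit: str = "resize"
    #: Adam moment decays. The short second-moment memory (0.9) lets the
    #: optimizer react to the Dice loss's gradient spikes (its gradient
    #: scales inversely with the shrinking denominator), which otherwise
    #: throw the logits into sigmoid saturation on small patch sets.
    adam_beta1: float = 0.9
    adam_beta2: float = 0.9

    def __post_init__(self) -> None:
        if self.stages < 1 or self.base_filters < 1:
            raise ConfigError("stages and base_filters must be >= 1")
        if not (0.0 < self.lr_factor < 1.0):
            raise ConfigError("lr_factor must be in (0, 1)")
        if self.patch_fit not in ("resize", "crop"):
            raise ConfigError("patch_fit must be 'resize' or 'crop'")
        if self.input_side % (2 ** (self.stages - 1)) != 0:
            raise ConfigError("input_side must be divisible by "
                              f"{2 ** (self.stages - 1)}")

    @property
    def encoder_filters(self) -> list[int]:
        return [self.base_filters * 2 ** i for i in range(self.stages)]


def dice_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """1 - Dice overlap of a probability raster against a binary target."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise InputError("dice_loss: shape mismatch "
                         f"{pred.shape} vs {target.shape}")
    num = 2.0 * float((pred * target).sum()) + EPS
    den = float(pred.sum()) + float(target.sum()) + EPS
    return 1.0 - num / den


def _dice_loss_grad(pred: np.ndarray, target: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    num = 2.0 * float((pred * target).sum()) + EPS
    den = float(pred.sum()) + float(target.sum()) + EPS
    grad = -(2.0 * target * den - num) / den ** 2
    return 1.0 - num / den, grad


# ------------------------------------------------------------------- layers

class _Conv:
    """k x k same-padding convolution via im2col."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = (rng.normal(0.0, scale, (cout, cin * k * k))
                  .astype(np.float32))
        self.b = np.zeros(cout, dtype=np.float32)
        self.k = k
        self.cin, self.cout = cin, cout
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))   # n,c,h,w,k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        self._cols, self._shape = cols, (n, c, h, w)
        out = cols @ self.W.T + self.b
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        k, p = self.k, self.k // 2
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        dyf = np.ascontiguousarray(dyf, dtype=np.float32)
        self.dW += dyf.T @ self._cols
        self.db += dyf.sum(axis=0)
        dcols = (dyf @ self.W).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        a = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        a = a.reshape(n, c, h // 2, w // 2, 4)
        self._idx = a.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(a, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        da = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(da, self._idx[..., None], dy[..., None], axis=-1)
        da = da.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return da.reshape(n, c, h, w)


class _Upsample2:
    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _Block:
    """conv-relu conv-relu."""

    def __init__(self, cin, cout, rng):
        self.c1, self.r1 = _Conv(cin, cout, 3, rng), _ReLU()
        self.c2, self.r2 = _Conv(cout, cout, 3, rng), _ReLU()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(
            self.r1.forward(self.c1.forward(x))))

    def backward(self, dy):
        return self.c1.backward(self.r1.backward(
            self.c2.backward(self.r2.backward(dy))))

    def params(self):
        return self.c1.params() + self.c2.params()


class UNet:
    """Four-stage (configurable) U-Net with sigmoid output."""

    def __init__(self, config: UNetConfig,
                 lesion_type: LesionType | None = None,
                 profile: Profile | None = None):
        self.config = config
        self.lesion_type = lesion_type
        self.profile = profile
        rng = np.random.default_rng(config.seed)
        filt = config.encoder_filters
        self.enc = []
        cin = 1
        for f in filt:
            self.enc.append(_Block(cin, f, rng))
            cin = f
        self.pools = [_MaxPool2() for _ in filt[:-1]]
        self.dec = []
        for f_skip in reversed(filt[:-1]):
            up = _Upsample2()
            reduce = _Conv(cin, f_skip, 3, rng)
            relu = _ReLU()
            block = _Block(2 * f_skip, f_skip, rng)
            self.dec.append((up, reduce, relu, block))
            cin = f_skip
        self.head = _Conv(cin, 1, 1, rng)
        # start the output near a low foreground prior: lesions cover a tiny
        # fraction of a patch, and a neutral start lets the background term
        # saturate the sigmoid before the foreground signal can act
        self.head.b[...] = -2.0

    @property
    def encoder_filters(self) -> list[int]:
        return self.config.encoder_filters

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        for i, block in enumerate(self.enc):
            x = block.forward(x)
            if i < len(self.enc) - 1:
                skips.append(x)
                x = self.pools[i].forward(x)
        for (up, reduce, relu, block), skip in zip(self.dec, reversed(skips)):
            x = relu.forward(reduce.forward(up.forward(x)))
            x = block.forward(np.concatenate([skip, x], axis=1))
        z = np.clip(self.head.forward(x), -30.0, 30.0)
        self._p = 1.0 / (1.0 + np.exp(-z))
        return self._p

    def backward(self, dprob: np.ndarray) -> None:
        dz = (dprob * self._p * (1.0 - self._p)).astype(np.float32)
        dx = self.head.backward(dz)
        dskips = []
        for (up, reduce, relu, block) in reversed(self.dec):
            d = block.backward(dx)
            f = d.shape[1] // 2
            dskip, d = d[:, :f], d[:, f:]
            dskips.append(dskip)
            dx = up.backward(reduce.backward(relu.backward(d)))
        for i in range(len(self.enc) - 1, -1, -1):
            if i < len(self.enc) - 1:
                dx = self.pools[i].backward(dx) + dskips[i]
            dx = self.enc[i].backward(dx)

    def params(self):
        out = []
        for b in self.enc:
            out += b.params()
        for (_u, reduce, _r, block) in self.dec:
            out += reduce.params() + block.params()
        out += self.head.params()
        return out

    def zero_grad(self):
        for _w, g in self.params():
            g[...] = 0.0

    # -------- (de)serialization
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": w for i, (w, _g) in enumerate(self.params())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, (w, _g) in enumerate(self.params()):
            w[...] = arrays[f"p{i}"]


class _Adam:
    def __init__(self, params, lr):
        self.params = params
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(w) for w, _ in params]
        self.v = [np.zeros_like(w) for w, _ in params]

    def step(self, beta1=0.9, beta2=0.999, eps=1e-8):
        self.t += 1
        for i, (w, g) in enumerate(self.params):
            self.m[i] = beta1 * self.m[i] + (1 - beta1) * g
            self.v[i] = beta2 * self.v[i] + (1 - beta2) * g * g
            mh = self.m[i] / (1 - beta1 ** self.t)
            vh = self.v[i] / (1 - beta2 ** self.t)
            w -= self.lr * mh / (np.sqrt(vh) + eps)


class PlateauLRScheduler:
    """Halve the LR when the monitored metric stops improving (mode max)."""

    def __init__(self, lr_init: float, factor: float = 0.5, patience: int = 3):
        self.lr = lr_init
        self.factor = factor
        self.patience = patience
        self.best = -np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> float:
        if metric > self.best:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr *= self.factor
                self.bad_epochs = 0
        return self.lr


class EarlyStopper:
    """Stop when the metric has not improved for ``patience`` epochs."""

    def __init__(self, patience: int = 10):
        self.patience = patience
        self.best = -np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> bool:
        if metric > self.best:
            self.best = metric
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.bad_epochs >= self.patience


# ----------------------------------------------------------------- training

def _fit_to_side(img: np.ndarray, side: int, is_mask: bool,
                 mode: str) -> np.ndarray:
    if img.shape == (side, side):
        return img
    if mode == "crop":
        h, w = img.shape
        if h >= side and w >= side:
            r0, c0 = (h - side) // 2, (w - side) // 2
            return img[r0:r0 + side, c0:c0 + side]
        pr, pc = max(0, side - h), max(0, side - w)
        pad = ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2))
        img = np.pad(img, pad, mode="constant" if is_mask else "reflect")
        return _fit_to_side(img, side, is_mask, "crop")
    out = resize(img.astype(np.float64), (side, side),
                 order=0 if is_mask else 1, anti_aliasing=False,
                 preserve_range=True)
    return out.astype(bool) if is_mask else out


def _patch_arrays(patches: list[TrainingPatch], target: LesionType,
                  side: int, mode: str = "resize"
                  ) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for p in patches:
        img = _fit_to_side(p.window, side, False, mode)
        m = _fit_to_side(p.label_for(target), side, True, mode)
        xs.append(img.astype(np.float32))
        ys.append(m.astype(np.float32))
    return np.stack(xs)[:, None], np.stack(ys)[:, None]


def _augment_batch(x: np.ndarray, y: np.ndarray,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Cheap on-the-fly augmentation: flips, 90-degree rotations, noise,
    intensity shift (geometric ops applied to image and mask alike)."""
    x, y = x.copy(), y.copy()
    for i in range(x.shape[0]):
        if rng.random() < 0.5:
            ax = int(rng.integers(1, 3))
            x[i] = np.flip(x[i], axis=ax)
            y[i] = np.flip(y[i], axis=ax)
        if rng.random() < 0.5:
            k = int(rng.integers(1, 4))
            x[i] = np.rot90(x[i], k, axes=(1, 2))
            y[i] = np.rot90(y[i], k, axes=(1, 2))
        if rng.random() < 0.3:
            x[i] = x[i] + rng.normal(0, 0.02, x[i].shape).astype(np.float32)
        if rng.random() < 0.3:
            x[i] = x[i] + np.float32(rng.uniform(-0.05, 0.05))
    return np.clip(x, 0, 1), y


def train_unet(patches: list[TrainingPatch], config: UNetConfig,
               lesion_type: LesionType | None = None,
               augment_data: bool = True,
               profile: Profile | None = None) -> tuple[UNet, dict]:
    """Train one per-type U-Net on mined patches.

    Returns (model, history) where history holds per-epoch training loss,
    validation Dice coefficient and learning rate. Fully seeded from
    ``config.seed``.
    """
    if lesion_type is None:
        types = {p.lesion_type for p in patches if p.lesion_type}
        if len(types) != 1:
            raise InputError("lesion_type must be given when the archive "
                             "mixes types")
        lesion_type = types.pop()
    pats = [p for p in patches
            if p.lesion_type is lesion_type or p.lesion_type is None]
    n_pos = sum(1 for p in pats if p.kind is PatchKind.LESION)
    n_neg = len(pats) - n_pos
    if n_pos < 2 or n_neg < 2:
        raise InputError(f"need >= 2 patches per class, got {n_pos} lesion / "
                         f"{n_neg} background")
    x, y = _patch_arrays(pats, lesion_type, config.input_side,
                         config.patch_fit)

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(x))
    n_val = max(1, len(x) // 10)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    xv, yv = x[val_idx], y[val_idx]
    xt, yt = x[tr_idx], y[tr_idx]

    model = UNet(config, lesion_type=lesion_type, profile=profile)
    opt = _Adam(model.params(), config.lr_init)
    sched = PlateauLRScheduler(config.lr_init, config.lr_factor,
                               config.lr_patience)
    stopper = EarlyStopper(config.early_stop_patience)
    history: dict = {"train_loss": [], "val_dice": [], "lr": []}

    for epoch in range(config.max_epochs):
        perm = rng.permutation(len(xt))
        losses = []
        for s in range(0, len(xt), config.batch_size):
            idx = perm[s:s + config.batch_size]
            xb, yb = xt[idx], yt[idx]
            if augment_data:
                xb, yb = _augment_batch(xb, yb, rng)
            p = model.forward(xb)
            # Dice over the whole batch tensor: background-only patches
            # enter through the denominator instead of degenerating into
            # their own all-or-nothing per-patch term.
            li, grad = _dice_loss_grad(p, yb)
            losses.append(li)
            model.zero_grad()
            model.backward(grad)
            opt.step(beta1=config.adam_beta1, beta2=config.adam_beta2)
        val_dice = evaluate_dice(model, xv, yv)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_dice"].append(val_dice)
        history["lr"].append(opt.lr)
        log.info("epoch %d: train loss %.4f, val dice %.4f, lr %.2e",
                 epoch, history["train_loss"][-1], val_dice, opt.lr)
        opt.lr = sched.step(val_dice)
        if stopper.step(val_dice):
            log.info("early stop at epoch %d", epoch)
            break
    return model, history


def evaluate_dice(model: UNet, x: np.ndarray, y: np.ndarray,
                  batch_size: int = 16) -> float:
    """Soft Dice coefficient over a patch set (pooled over all patches)."""
    inter = psum = tsum = 0.0
    for s in range(0, len(x), batch_size):
        p = model.forward(x[s:s + batch_size])
        t = y[s:s + batch_size]
        inter += float((p * t).sum())
        psum += float(p.sum())
        tsum += float(t.sum())
    return (2.0 * inter + EPS) / (psum + tsum + EPS)


# -------------------------------------------------------- model persistence

def save_model(model: UNet, path: str | Path) -> Path:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_arrays())
    sidecar = {
        "config": asdict(model.config),
        "lesion_type": model.lesion_type.name if model.lesion_type else None,
        "profile": model.profile.name if model.profile else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npz")


def load_model(path: str | Path) -> UNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = UNetConfig(**sidecar["config"])
    lt = (LesionType[sidecar["lesion_type"]]
          if sidecar["lesion_type"] else None)
    prof = Profile[sidecar["profile"]] if sidecar["profile"] else None
    model = UNet(config, lesion_type=lt, profile=prof)
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_arrays(dict(data))
    return model


# ---------------------------------------------------------------- inference

def infer_masks(model: UNet, gray: GrayImage, threshold: float = 0.5,
                stride: int | None = None
                ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Sliding-window full-image inference.

    Tiles of the model's input side (default stride: half a side) are
    averaged where they overlap; the probability map is thresholded and
    split into 8-connected components. Returns (binary mask, list of
    per-component masks).
    """
    if (model.profile is not None and gray.profile is not None
            and model.profile is not gray.profile):
        raise ConfigError(f"model trained for {model.profile.name} applied "
                          f"to a {gray.profile.name} image")
    side = model.config.input_side
    stride = stride or side // 2
    h, w = gray.shape
    ph = max(side, int(np.ceil((h - side) / stride)) * stride + side) if h > side else side
    pw = max(side, int(np.ceil((w - side) / stride)) * stride + side) if w > side else side
    padded = np.zeros((ph, pw), dtype=np.float32)
    padded[:h, :w] = gray.pixels
    prob = np.zeros((ph, pw), dtype=np.float64)
    count = np.zeros((ph, pw), dtype=np.float64)
    tiles, coords = [], []
    for r0 in range(0, ph - side + 1, stride):
        for c0 in range(0, pw - side + 1, stride):
            tiles.append(padded[r0:r0 + side, c0:c0 + side])
            coords.append((r0, c0))
    for s in range(0, len(tiles), 16):
        batch = np.stack(tiles[s:s + 16])[:, None]
        p = model.forward(batch)
        for bi, (r0, c0) in enumerate(coords[s:s + 16]):
            prob[r0:r0 + side, c0:c0 + side] += p[bi, 0]
            count[r0:r0 + side, c0:c0 + side] += 1.0
    prob = (prob / np.maximum(count, 1.0))[:h, :w]
    # clip below 1 so a threshold of 1.0 yields the empty mask even where
    # the sigmoid saturates in float32
    prob = np.clip(prob, 0.0, 1.0 - 1e-7)
    mask = (prob >= threshold) & gray.fov
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
    comps = [labels == i for i in range(1, n + 1)]
    return mask, comps
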