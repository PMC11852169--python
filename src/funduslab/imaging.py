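"""Image loading, canonical resizing, working channel and field-of-view.

Fundus photographs arrive as color rasters of arbitrary size. All geometric
computation downstream runs on a single normalized intensity channel at one
of two canonical square sizes: 1000x1000 for standard color fundus
photography (CFP) and 1500x1500 for ultrawide-field (UWF) imaging. The
working channel is green: in fundus photography it carries the strongest
lesion/vessel contrast (red saturates on the choroid, blue is noisy).

A field-of-view (FOV) mask marks the imaged retina inside the dark camera
surround. It is eroded by the largest descriptor scale so that every ray
sampled by the contrast descriptor stays inside the originally imaged area.

Coordinates are (row, col), 0-based, origin top-left; windows are half-open.
Indexed label masks use 0=background, 1=microaneurysm, 2=hemorrhage,
3=hard exudate, 4=soft exudate.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.transform import resize

from .errors import ConfigError, InputError

log = logging.getLogger(__name__)

#: Default FOV erosion radius = the largest default descriptor scale, so a
#: ray of that length started on any FOV-true pixel cannot leave the imaged
#: area.
DEFAULT_MAX_SCALE = 10

#: Fallback FOV intensity threshold when Otsu is degenerate (near-constant
#: channel), on the normalized [0, 1] scale.
FOV_FALLBACK_THRESHOLD = 0.05

#: Indexed-PNG label values, shared bit-exactly across all modules.
LABEL_VALUES = {
    "background": 0,
    "microaneurysm": 1,
    "hemorrhage": 2,
    "hard_exudate": 3,
    "soft_exudate": 4,
}


class Profile(enum.Enum):
    """Acquisition profile fixing the canonical working resolution."""

    CFP = 1000
    UWF = 1500

    @property
    def side(self) -> int:
        return self.value


@dataclass
class GrayImage:
    """Working-channel intensity raster in [0, 1] with its FOV mask."""

    pixels: np.ndarray
    fov: np.ndarray
    profile: Profile | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.fov = np.asarray(self.fov, dtype=bool)
        if self.pixels.ndim != 2:
            raise InputError("GrayImage.pixels must be 2-D")
        if self.pixels.shape != self.fov.shape:
            raise InputError("pixels and fov shapes differ")
        if not np.isfinite(self.pixels).all():
            raise InputError("GrayImage.pixels contains non-finite values")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise InputError("GrayImage.pixels must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def load_and_resize(path: str | Path, profile: Profile) -> np.ndarray:
    """Load a raster image and resample it to the profile's canonical square.

    Aspect ratio is deliberately not preserved: inputs are stretched to the
    uniform square dimensions, matching the preprocessing convention the
    pipeline is calibrated for. Returns a float64 array in [0, 1], shape
    (S, S) or (S, S, C) with the source's channel count.
    """
    if not isinstance(profile, Profile):
        raise ConfigError(f"unknown profile: {profile!r}")
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (UnidentifiedImageError, OSError, ValueError) as exc:
        raise InputError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim not in (2, 3) or arr.size == 0:
        raise InputError(f"file {path} did not decode to a 2-D raster")
    arr = _to_unit_float(arr)
    side = profile.side
    if arr.shape[:2] == (side, side):
        return arr
    out_shape = (side, side) if arr.ndim == 2 else (side, side, arr.shape[2])
    return resize(arr, out_shape, order=1, anti_aliasing=False,
                  preserve_range=True).astype(np.float64)


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    """Scale an integer or float raster to float64 in [0, 1]."""
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / info.max
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def to_working_gray(image: np.ndarray, profile: Profile | None = None,
                    max_scale: int = DEFAULT_MAX_SCALE) -> GrayImage:
    """Extract the working gray channel and attach the FOV mask.

    3-channel input uses the green channel; 1-channel input is used as-is.
    Any other channel count is rejected.
    """
    arr = _to_unit_float(image)
    if arr.ndim == 2:
        gray = arr
    elif arr.ndim == 3 and arr.shape[2] == 3:
        gray = arr[:, :, 1]
    elif arr.ndim == 3 and arr.shape[2] == 1:
        gray = arr[:, :, 0]
    else:
        nchan = arr.shape[2] if arr.ndim == 3 else arr.ndim
        raise InputError(f"expected 1 or 3 channels, got {nchan}")
    fov = estimate_fov_mask(arr, max_scale=max_scale)
    return GrayImage(pixels=gray, fov=fov, profile=profile)


def estimate_fov_mask(image: np.ndarray, max_scale: int = DEFAULT_MAX_SCALE) -> np.ndarray:
    """Estimate the imaged-retina mask of a fundus photograph.

    Thresholds the red channel (Otsu with a fixed fallback for degenerate
    histograms), keeps the largest connected component, closes small gaps
    and erodes by ``max_scale`` so no descriptor ray leaves the imaged area.
    """
    arr = _to_unit_float(image)
    channel = arr[:, :, 0] if arr.ndim == 3 else arr
    try:
        thr = threshold_otsu(channel)
        # Otsu on a near-constant channel returns a cut with an empty side;
        # fall back to the fixed threshold in that case.
        if thr <= channel.min() or thr >= channel.max():
            thr = FOV_FALLBACK_THRESHOLD
    except ValueError:
        thr = FOV_FALLBACK_THRESHOLD
    mask = channel > thr
    if not mask.any():
        log.warning("FOV estimation found no bright pixels; empty mask")
        return mask
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_closing(mask, structure=disk(3))
    if max_scale > 0:
        mask = ndimage.binary_erosion(mask, structure=disk(max_scale),
                                      border_value=0)
    if not mask.any():
        log.warning("FOV mask empty after erosion by %d px", max_scale)
    return mask


def write_label_mask(path: str | Path, labels: np.ndarray) -> None:
    """Write an indexed label mask PNG (values 0-4 per the shared contract)."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 4:
        raise InputError("label mask values must be in 0..4")
    im = Image.fromarray(labels.astype(np.uint8), mode="P")
    # background black, MA red, hemorrhage dark blue, hard exudate green,
    # soft exudate light blue -- only indices 0..4 are meaningful.
    palette = [0, 0, 0, 255, 0, 0, 0, 0, 160, 0, 200, 0, 80, 200, 255]
    im.putpalette(palette + [0] * (768 - len(palette)))
    im.save(Path(path))


def read_label_mask(path: str | Path) -> np.ndarray:
    """Read an indexed label mask PNG back to a uint8 array."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (UnidentifiedImageError, OSError) as exc:
        raise InputError(f"cannot read mask file {path}: {exc}") from exc
    if arr.ndim != 2:
        raise InputError(f"mask file {path} is not single-channel indexed")
    return arr.astype(np.uint8)


def resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resize for label/boolean masks (no label bleeding)."""
    if mask.shape == tuple(shape):
        return mask
    out = resize(mask.astype(np.float64), shape, order=0,
                 anti_aliasing=False, preserve_range=True)
    return out.astype(mask.dtype)
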