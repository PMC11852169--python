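"""Multiscale contrast shape descriptor (MCSD).

The descriptor probes, at every pixel, line segments of length ``d`` leaving
the pixel in ``n_directions`` uniformly spaced directions. For each direction
theta the directional contrast is

    c(theta) = mean_{k=1..d} I(p + k * u_theta) - I(p)

with bilinear interpolation along the ray. Blob-like lesions are roughly
isotropic, so their contrast has the same sign in *every* direction; a
curvilinear vessel always has one direction (its own axis) along which the
contrast vanishes. The descriptor therefore reduces the directional profile
two ways:

* BLOB mode keeps the extremum *nearest zero* on the polarity's side and
  rectifies: a dark blob needs min_theta c(theta) > 0, a bright blob needs
  max_theta c(theta) < 0. A vessel pixel scores ~0 in blob mode because the
  along-vessel direction contributes c ~ 0.
* LINEAR mode keeps the signed maximum max_theta c(theta): large on dark
  curvilinear structure (the across-vessel direction sees the bright
  background), near zero on background.

Segment lengths act as scales: a ray only registers a blob it can exit, so
scale d responds to blobs of radius up to ~d. Per-scale fields are floored
(low-contrast suppression) and merged by pixelwise maximum.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigError, InputError
from .imaging import GrayImage

log = logging.getLogger(__name__)

#: 8-connectivity structure for candidate component labeling.
_STRUCT8 = np.ones((3, 3), dtype=bool)


class Mode(enum.Enum):
    BLOB = "blob"
    LINEAR = "linear"


class Polarity(enum.Enum):
    DARK = "dark"      # lesion darker than background (bleeding spots)
    BRIGHT = "bright"  # lesion brighter than background (exudates)


@dataclass(frozen=True)
class MCSDParams:
    """Descriptor parameters: scales, angular sampling, mode and polarity."""

    scales: tuple[int, ...] = (3, 5, 10)
    n_directions: int = 16
    mode: Mode = Mode.BLOB
    polarity: Polarity = Polarity.DARK

    def __post_init__(self) -> None:
        if len(self.scales) == 0:
            raise ConfigError("MCSDParams.scales must be non-empty")
        if any(int(d) < 2 for d in self.scales):
            raise ConfigError("all MCSD scales must be >= 2")
        if self.n_directions < 4 or self.n_directions % 2 != 0:
            raise ConfigError("n_directions must be even and >= 4")
        object.__setattr__(self, "scales", tuple(int(d) for d in self.scales))

    @property
    def max_scale(self) -> int:
        return max(self.scales)

    def angles(self) -> np.ndarray:
        return np.arange(self.n_directions) * (2.0 * np.pi / self.n_directions)


@dataclass
class ContrastField:
    """Per-pixel rectified descriptor response for one mode/polarity."""

    values: np.ndarray
    params: MCSDParams
    source_shape: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.source_shape is None:
            self.source_shape = self.values.shape
        if not np.isfinite(self.values).all() or self.values.min() < 0:
            raise InputError("ContrastField values must be finite and >= 0")


def _ray_offsets(d: int, theta: float) -> tuple[np.ndarray, np.ndarray]:
    """Row/col offsets of the d samples at unit arc-length spacing."""
    k = np.arange(1, d + 1, dtype=np.float64)
    return k * np.sin(theta), k * np.cos(theta)


def directional_profile_contrast(gray: GrayImage, center: tuple[int, int],
                                 d: int, theta: float) -> float:
    """Reference single-pixel contrast c(theta) of the descriptor.

    Mean of ``d`` bilinearly interpolated samples along the ray from
    ``center`` at angle ``theta`` minus the center intensity. Samples
    falling outside the raster are clamped to the border value (the FOV
    erosion normally prevents this; a debug log notes it when it happens).
    """
    if d < 2:
        raise ConfigError("segment length d must be >= 2")
    r, c = center
    dr, dc = _ray_offsets(d, theta)
    rows, cols = r + dr, c + dc
    h, w = gray.shape
    if (rows.min() < 0 or rows.max() > h - 1 or cols.min() < 0
            or cols.max() > w - 1):
        log.debug("ray from %s exits the raster; samples clamped", (r, c))
    samples = ndimage.map_coordinates(gray.pixels, [rows, cols], order=1,
                                      mode="nearest")
    return float(samples.mean() - gray.pixels[r, c])


def directional_contrast_stack(gray: GrayImage, scales: Sequence[int],
                               n_directions: int) -> dict[int, np.ndarray]:
    """c(theta) rasters for every scale, shared by all modes/polarities.

    Returns {d: array (n_directions, H, W)}. The running sum over ray
    samples is snapshotted at each requested scale so the work for the
    largest scale covers all smaller ones.
    """
    scales = sorted(set(int(d) for d in scales))
    angles = np.arange(n_directions) * (2.0 * np.pi / n_directions)
    h, w = gray.shape
    base_r, base_c = np.mgrid[0:h, 0:w].astype(np.float64)
    out: dict[int, np.ndarray] = {
        d: np.empty((n_directions, h, w), dtype=np.float64) for d in scales
    }
    for ti, theta in enumerate(angles):
        sin_t, cos_t = np.sin(theta), np.cos(theta)
        acc = np.zeros((h, w), dtype=np.float64)
        for k in range(1, scales[-1] + 1):
            rows = base_r + k * sin_t
            cols = base_c + k * cos_t
            acc += ndimage.map_coordinates(gray.pixels, [rows, cols],
                                           order=1, mode="nearest")
            if k in out:
                out[k][ti] = acc / k - gray.pixels
    return out


def _reduce_stack(stack: np.ndarray, mode: Mode, polarity: Polarity) -> np.ndarray:
    """Rectified per-pixel response from the (n_dir, H, W) c(theta) stack."""
    if mode is Mode.BLOB:
        if polarity is Polarity.DARK:
            return np.maximum(0.0, stack.min(axis=0))
        return np.maximum(0.0, -stack.max(axis=0))
    # LINEAR: signed maximum over directions (dark curvilinear structure).
    return np.maximum(0.0, stack.max(axis=0))


def shape_descriptor_field(gray: GrayImage, d: int, params: MCSDParams,
                           stack: np.ndarray | None = None) -> ContrastField:
    """Single-scale descriptor field for the params' mode and polarity.

    ``stack`` may carry a precomputed c(theta) raster for scale ``d`` (from
    :func:`directional_contrast_stack`) to avoid recomputation.
    """
    if stack is None:
        stack = directional_contrast_stack(gray, [d], params.n_directions)[d]
    values = _reduce_stack(stack, params.mode, params.polarity)
    values[~gray.fov] = 0.0
    return ContrastField(values=values, params=replace(params, scales=(d,)),
                         source_shape=gray.shape)


def multiscale_field(gray: GrayImage, params: MCSDParams,
                     contrast_floor: float = 0.0,
                     stacks: dict[int, np.ndarray] | None = None) -> ContrastField:
    """Merge per-scale fields: floor each at ``contrast_floor``, then
    pixelwise maximum. The merged field keeps the full scale list."""
    if stacks is None:
        stacks = directional_contrast_stack(gray, params.scales,
                                            params.n_directions)
    merged = np.zeros(gray.shape, dtype=np.float64)
    for d in params.scales:
        f = shape_descriptor_field(gray, d, params, stack=stacks[d]).values
        f[f < contrast_floor] = 0.0
        np.maximum(merged, f, out=merged)
    return ContrastField(values=merged, params=params, source_shape=gray.shape)


def multiscale_blob_field(gray: GrayImage, params: MCSDParams,
                          contrast_floor: float = 0.02,
                          stacks: dict[int, np.ndarray] | None = None) -> ContrastField:
    """Low-contrast-suppressed multiscale blob field (params fix polarity)."""
    if params.mode is not Mode.BLOB:
        params = replace(params, mode=Mode.BLOB)
    return multiscale_field(gray, params, contrast_floor, stacks)


def derive_vessel_mask(gray: GrayImage, params: MCSDParams,
                       contrast_floor: float = 0.02,
                       vessel_floor: float = 0.06,
                       stacks: dict[int, np.ndarray] | None = None) -> np.ndarray:
    """Mask of curvilinear dark structure (vessels).

    A pixel is vessel-like when its multiscale LINEAR response reaches
    ``vessel_floor`` while its dark-blob response stays below
    ``contrast_floor`` -- elongated contrast without isotropic contrast.
    Exists to support the ring vessel-adjacency filter, not as a general
    vessel segmentation.
    """
    if stacks is None:
        stacks = directional_contrast_stack(gray, params.scales,
                                            params.n_directions)
    linear = multiscale_field(
        gray, replace(params, mode=Mode.LINEAR, polarity=Polarity.DARK),
        0.0, stacks).values
    blob = multiscale_field(
        gray, replace(params, mode=Mode.BLOB, polarity=Polarity.DARK),
        0.0, stacks).values
    return (linear >= vessel_floor) & (blob < contrast_floor)


@dataclass
class CandidateRegion:
    """One connected candidate lesion and its scoring state.

    ``mask`` is local to the bounding box ``slices``; ``boundary`` holds
    global (row, col) coordinates of the region's inner boundary pixels.
    Scoring fields (confidence, bucket, ...) are filled by region_scoring,
    ``lesion_type`` by lesion_typing.
    """

    mask: np.ndarray
    slices: tuple[slice, slice]
    area: int
    polarity: Polarity
    boundary: np.ndarray
    # --- filled in by region_scoring ---
    r_max: float | None = None
    centroid: tuple[int, int] | None = None
    confidence: float | None = None
    bucket: "object | None" = None  # scoring.Bucket; late import avoidance
    vessel_excluded: bool = False
    rings: "object | None" = None   # scoring.RingPair
    # --- filled in by lesion_typing ---
    lesion_type: "object | None" = None

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        r, c = self.slices
        return (r.start, r.stop, c.start, c.stop)

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.slices] = self.mask
        return out

    def to_record(self, region_id: int) -> dict:
        rec = {
            "id": region_id,
            "polarity": self.polarity.value,
            "area": int(self.area),
            "centroid": list(map(int, self.centroid)) if self.centroid else None,
            "r_max": float(self.r_max) if self.r_max is not None else None,
            "confidence": (None if self.confidence is None
                           else float(min(self.confidence, 1e30))),
            "bucket": getattr(self.bucket, "value", None),
            "vessel_excluded": bool(self.vessel_excluded),
            "lesion_type": getattr(self.lesion_type, "name", None),
            "bbox": list(self.bbox),
        }
        return rec


def extract_candidate_regions(fld: ContrastField, gray: GrayImage,
                              min_area: int = 2) -> list[CandidateRegion]:
    """8-connected components of the positive field as candidate regions.

    Components below ``min_area`` pixels are noise and dropped. Interior
    holes are filled: a lesion wider than the largest scale responds only in
    a boundary band (interior rays never exit it), and scoring needs the
    full lesion extent. Ordering is deterministic, by first raster pixel.
    """
    if fld.values.min() < 0:
        raise InputError("contrast field must be nonnegative")
    binary = fld.values > 0
    labels, n = ndimage.label(binary, structure=_STRUCT8)
    regions: list[CandidateRegion] = []
    for idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        local = labels[sl] == idx
        if int(local.sum()) < min_area:
            continue
        local = ndimage.binary_fill_holes(local)
        interior = ndimage.binary_erosion(local, structure=_STRUCT8,
                                          border_value=0)
        br, bc = np.nonzero(local & ~interior)
        boundary = np.column_stack([br + sl[0].start, bc + sl[1].start])
        regions.append(CandidateRegion(
            mask=local, slices=(sl[0], sl[1]), area=int(local.sum()),
            polarity=fld.params.polarity, boundary=boundary))
    return regions


def region_from_mask(full_mask: np.ndarray, polarity: Polarity) -> CandidateRegion:
    """Build a CandidateRegion from a known full-frame mask.

    Used to score/type ground-truth (oracle) masks with the same machinery
    as descriptor-extracted candidates.
    """
    full_mask = np.asarray(full_mask, dtype=bool)
    if not full_mask.any():
        raise InputError("region_from_mask: empty mask")
    sl = ndimage.find_objects(full_mask.astype(np.int8))[0]
    local = full_mask[sl]
    interior = ndimage.binary_erosion(local, structure=_STRUCT8, border_value=0)
    br, bc = np.nonzero(local & ~interior)
    boundary = np.column_stack([br + sl[0].start, bc + sl[1].start])
    return CandidateRegion(mask=local, slices=(sl[0], sl[1]),
                           area=int(local.sum()), polarity=polarity,
                           boundary=boundary)


def field_to_png16(fld: ContrastField) -> np.ndarray:
    """Scale a contrast field to uint16 for debug PNG dumps."""
    v = fld.values
    top = v.max() if v.max() > 0 else 1.0
    return np.round(v / top * 65535).astype(np.uint16)
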