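"""Seeded generator of fundus-like scenes with per-lesion ground truth.

The generator emulates the appearance model the geometric labeler assumes:
a smooth bright background with a gentle illumination gradient and sensor
noise, dark curvilinear vessels with Gaussian cross-sections, and the four
lesion phenotypes --

* microaneurysm: small dark disc (radius ~1-3 px),
* hemorrhage: darker elongated blob with an irregular boundary,
* hard exudate: bright disc whose intensity falls off monotonically from
  center to boundary,
* soft exudate: bright blob with an uneven "cotton-wool" interior,
  rendered as scattered intensity dips so a large fraction of its shell
  stays brighter than its core mean.

Default size and contrast priors are chosen so the planted lesions lie
inside the descriptor's design range at the default scales (a blob only
registers when rays of the largest scale can traverse it, which caps the
detectable diameter at roughly the largest scale) and so the ring
confidences straddle the LOW/INDETERMINATE/HIGH buckets: main lesions land
HIGH, the optional faint microaneurysms land LOW/INDETERMINATE.

Everything is driven by one ``numpy.random.Generator``; the same seed
reproduces the scene bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage

from .errors import ConfigError, GenerationError
from .imaging import GrayImage
from .typing_rules import LesionType

log = logging.getLogger(__name__)

#: placement retry budget per lesion
RETRY_BUDGET = 100


@dataclass(frozen=True)
class SceneConfig:
    """Scene content and phenotype priors (intensities on the [0,1] scale)."""

    shape: tuple[int, int] = (320, 320)
    n_vessels: int = 3
    n_microaneurysms: int = 5
    n_hemorrhages: int = 3
    n_hard_exudates: int = 3
    n_soft_exudates: int = 2
    n_faint: int = 2                      # low-contrast dark spots (LOW/INDET)
    noise_sigma: float = 0.01
    background_mean: float = 0.45
    illumination_amp: float = 0.02
    vessel_contrast: tuple[float, float] = (0.15, 0.30)
    vessel_sigma: tuple[float, float] = (1.0, 2.5)   # Gaussian half-width
    ma_radius: tuple[float, float] = (1.2, 3.0)
    ma_contrast: tuple[float, float] = (0.15, 0.35)
    hem_semi_major: tuple[float, float] = (2.5, 3.8)
    hem_axis_ratio: tuple[float, float] = (1.5, 2.2)
    hem_contrast: tuple[float, float] = (0.20, 0.35)
    hex_radius: tuple[float, float] = (2.0, 3.2)
    hex_contrast: tuple[float, float] = (0.30, 0.40)
    hex_falloff: float = 0.15             # boundary drop as fraction of contrast
    sex_radius: tuple[float, float] = (2.5, 3.5)
    sex_contrast: tuple[float, float] = (0.32, 0.40)
    sex_dip_fraction: float = 0.30        # fraction of pixels dipped
    sex_dip_depth: float = 0.5            # dip as fraction of contrast
    faint_contrast: tuple[float, float] = (0.04, 0.10)
    vessel_fused_fraction: float = 0.0    # fraction of hemorrhages on a vessel
    margin: int = 16                      # keep lesions off the border/FOV edge
    fov_erosion: int = 10                 # matches the largest descriptor scale

    def __post_init__(self) -> None:
        if min(self.shape) < 256:
            raise ConfigError("scene canvas must be at least 256x256")
        counts = (self.n_vessels, self.n_microaneurysms, self.n_hemorrhages,
                  self.n_hard_exudates, self.n_soft_exudates, self.n_faint)
        if min(counts) < 0:
            raise ConfigError("scene counts must be >= 0")


@dataclass
class LesionRecord:
    """Ground truth for one planted lesion."""

    lesion_type: LesionType
    center: tuple[int, int]
    area: int
    contrast: float
    requested_area: float
    params: dict
    vessel_fused: bool = False
    faint: bool = False


@dataclass
class SyntheticScene:
    """Rendered scene plus all ground-truth structure."""

    image: GrayImage
    color: np.ndarray
    vessel_mask: np.ndarray          # vessel body (visible darkening)
    vessel_centerline: np.ndarray
    lesion_masks: dict = dfield(default_factory=dict)  # LesionType -> bool mask
    records: list = dfield(default_factory=list)
    seed: int = 0
    config: SceneConfig = SceneConfig()

    def truth_label_mask(self) -> np.ndarray:
        """Indexed label mask per the shared 0-4 contract."""
        out = np.zeros(self.image.shape, dtype=np.uint8)
        for ltype, mask in self.lesion_masks.items():
            out[mask] = int(ltype)
        return out

    def truth_masks_of(self, ltype: LesionType) -> list[np.ndarray]:
        """Per-lesion boolean masks of one type (full-frame)."""
        out = []
        for rec, m in zip(self.records, self._per_lesion_masks):
            if rec.lesion_type is ltype:
                out.append(m)
        return out

    _per_lesion_masks: list = dfield(default_factory=list)


# ----------------------------------------------------------------- background

def _background(shape: tuple[int, int], cfg: SceneConfig,
                rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    gdir = rng.uniform(0, 2 * np.pi)
    grad = (np.cos(gdir) * xx / w + np.sin(gdir) * yy / h)
    low = ndimage.gaussian_filter(rng.normal(0.0, 1.0, shape), min(shape) / 6)
    low_std = low.std() if low.std() > 0 else 1.0
    img = (cfg.background_mean + cfg.illumination_amp * grad
           + cfg.illumination_amp * low / low_std)
    return img


# -------------------------------------------------------------------- vessels

def render_vessels(pixels: np.ndarray, cfg: SceneConfig,
                   rng: np.random.Generator,
                   n_vessels: int | None = None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw dark curvilinear vessels; returns (pixels, body_mask, centerline).

    Each vessel is a smooth jittered curve across the canvas with a Gaussian
    cross-section whose width tapers along its length.
    """
    h, w = pixels.shape
    n = cfg.n_vessels if n_vessels is None else n_vessels
    centerline = np.zeros((h, w), dtype=bool)
    darkening = np.zeros((h, w), dtype=np.float64)
    for _ in range(n):
        contrast = rng.uniform(*cfg.vessel_contrast)
        s0, s1 = rng.uniform(*cfg.vessel_sigma, size=2)
        horizontal = rng.random() < 0.5
        t = np.linspace(0.0, 1.0, 4 * max(h, w))
        a1, a2 = rng.uniform(0.03, 0.10, size=2) * min(h, w)
        p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
        wiggle = a1 * np.sin(2 * np.pi * t + p1) + a2 * np.sin(4 * np.pi * t + p2)
        if horizontal:
            cols = t * (w - 1)
            rows = rng.uniform(0.15, 0.85) * h + wiggle
        else:
            rows = t * (h - 1)
            cols = rng.uniform(0.15, 0.85) * w + wiggle
        rr = np.clip(np.round(rows).astype(int), 0, h - 1)
        cc = np.clip(np.round(cols).astype(int), 0, w - 1)
        vline = np.zeros((h, w), dtype=bool)
        vline[rr, cc] = True
        centerline |= vline
        # tapering width: piecewise-constant sigma over 4 chunks
        n_chunks = 4
        chunk = len(t) // n_chunks
        for ci in range(n_chunks):
            seg = np.zeros((h, w), dtype=bool)
            lo, hi = ci * chunk, (ci + 1) * chunk if ci < n_chunks - 1 else len(t)
            seg[rr[lo:hi], cc[lo:hi]] = True
            sigma = s0 + (s1 - s0) * (ci + 0.5) / n_chunks
            dist = ndimage.distance_transform_edt(~seg)
            contrib = contrast * np.exp(-dist ** 2 / (2.0 * sigma ** 2))
            contrib[dist > 3 * sigma] = 0.0
            np.maximum(darkening, contrib, out=darkening)
    pixels = pixels - darkening
    body = darkening > 0.03
    return pixels, body, centerline


# -------------------------------------------------------------------- lesions

def _stamp_window(shape, center, radius):
    r, c = center
    rad = int(np.ceil(radius)) + 2
    r0, r1 = max(0, r - rad), min(shape[0], r + rad + 1)
    c0, c1 = max(0, c - rad), min(shape[1], c + rad + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    return (slice(r0, r1), slice(c0, c1)), (yy - r).astype(float), (xx - c).astype(float)


def _lesion_stamp(lesion_type: LesionType, params: dict, shape, center,
                  rng: np.random.Generator):
    """Local mask and signed intensity delta of one lesion phenotype."""
    if lesion_type is LesionType.MICROANEURYSM:
        radius, contrast = params["radius"], params["contrast"]
        sl, dy, dx = _stamp_window(shape, center, radius)
        mask = np.hypot(dy, dx) <= radius
        delta = np.where(mask, -contrast, 0.0)
        requested = np.pi * radius ** 2
    elif lesion_type is LesionType.HEMORRHAGE:
        a, b, contrast = params["a"], params["b"], params["contrast"]
        phi = params["angle"]
        sl, dy, dx = _stamp_window(shape, center, a * 1.3)
        xr = np.cos(phi) * dx + np.sin(phi) * dy
        yr = -np.sin(phi) * dx + np.cos(phi) * dy
        theta = np.arctan2(yr, xr)
        warp = (1.0 + 0.12 * np.sin(2 * theta + params["ph1"])
                + 0.08 * np.sin(3 * theta + params["ph2"]))
        mask = (xr / a) ** 2 + (yr / b) ** 2 <= warp ** 2
        delta = np.where(mask, -contrast, 0.0)
        requested = np.pi * a * b
    elif lesion_type is LesionType.HARD_EXUDATE:
        radius, contrast = params["radius"], params["contrast"]
        falloff = params["falloff"]
        sl, dy, dx = _stamp_window(shape, center, radius)
        d = np.hypot(dy, dx)
        mask = d <= radius
        profile = contrast * (1.0 - falloff * (d / radius) ** 2)
        delta = np.where(mask, profile, 0.0)
        requested = np.pi * radius ** 2
    elif lesion_type is LesionType.SOFT_EXUDATE:
        radius, contrast = params["radius"], params["contrast"]
        sl, dy, dx = _stamp_window(shape, center, radius)
        d = np.hypot(dy, dx)
        mask = d <= radius
        dips = (rng.random(mask.shape) < params["dip_fraction"]) & mask
        profile = np.full(mask.shape, contrast)
        profile[dips] = contrast * (1.0 - params["dip_depth"])
        delta = np.where(mask, profile, 0.0)
        requested = np.pi * radius ** 2
    else:  # pragma: no cover - enum is exhaustive
        raise ConfigError(f"unknown lesion type {lesion_type}")
    return sl, mask, delta, requested


def plant_lesion(pixels: np.ndarray, lesion_type: LesionType, params: dict,
                 rng: np.random.Generator, forbidden: np.ndarray,
                 margin: int, center: tuple[int, int] | None = None
                 ) -> tuple[np.ndarray, np.ndarray, LesionRecord]:
    """Place one lesion avoiding ``forbidden`` pixels; returns
    (updated pixels, full-frame mask, record). Additive blending, clipped
    to [0, 1] by the caller at the end of scene assembly.
    """
    h, w = pixels.shape
    for _ in range(RETRY_BUDGET):
        if center is None:
            r = int(rng.integers(margin, h - margin))
            c = int(rng.integers(margin, w - margin))
        else:
            r, c = center
        sl, mask, delta, requested = _lesion_stamp(lesion_type, params,
                                                   (h, w), (r, c), rng)
        if center is None and forbidden[sl][mask].any():
            continue
        out = pixels.copy()
        out[sl] += delta
        full = np.zeros((h, w), dtype=bool)
        full[sl] = mask
        record = LesionRecord(
            lesion_type=lesion_type, center=(r, c), area=int(mask.sum()),
            contrast=float(params["contrast"]), requested_area=float(requested),
            params=dict(params), faint=bool(params.get("faint", False)),
            vessel_fused=bool(params.get("vessel_fused", False)))
        return out, full, record
    raise GenerationError(
        f"could not place {lesion_type.name} after {RETRY_BUDGET} retries "
        f"(canvas too crowded)")


def _sample_params(lesion_type: LesionType, cfg: SceneConfig,
                   rng: np.random.Generator, faint: bool = False,
                   vessel_fused: bool = False) -> dict:
    if faint:
        return {"radius": rng.uniform(1.5, 2.5),
                "contrast": rng.uniform(*cfg.faint_contrast), "faint": True}
    if lesion_type is LesionType.MICROANEURYSM:
        return {"radius": rng.uniform(*cfg.ma_radius),
                "contrast": rng.uniform(*cfg.ma_contrast)}
    if lesion_type is LesionType.HEMORRHAGE:
        a = rng.uniform(*cfg.hem_semi_major)
        q = rng.uniform(*cfg.hem_axis_ratio)
        return {"a": a, "b": a / q, "contrast": rng.uniform(*cfg.hem_contrast),
                "angle": rng.uniform(0, np.pi),
                "ph1": rng.uniform(0, 2 * np.pi),
                "ph2": rng.uniform(0, 2 * np.pi),
                "vessel_fused": vessel_fused}
    if lesion_type is LesionType.HARD_EXUDATE:
        return {"radius": rng.uniform(*cfg.hex_radius),
                "contrast": rng.uniform(*cfg.hex_contrast),
                "falloff": cfg.hex_falloff}
    return {"radius": rng.uniform(*cfg.sex_radius),
            "contrast": rng.uniform(*cfg.sex_contrast),
            "dip_fraction": cfg.sex_dip_fraction,
            "dip_depth": cfg.sex_dip_depth}


def generate_scene(config: SceneConfig = SceneConfig(), seed: int = 0
                   ) -> SyntheticScene:
    """Render a complete seeded scene with ground truth."""
    rng = np.random.default_rng(seed)
    h, w = config.shape
    pixels = _background(config.shape, config, rng)
    pixels, body, centerline = render_vessels(pixels, config, rng)

    # Keep lesions clear of vessels, each other and the border.
    spacing = ndimage.generate_binary_structure(2, 2)
    forbidden = ndimage.binary_dilation(body, spacing, iterations=4)
    border = np.ones((h, w), dtype=bool)
    border[config.margin:h - config.margin, config.margin:w - config.margin] = False
    forbidden |= border

    lesion_masks: dict = {lt: np.zeros((h, w), dtype=bool) for lt in LesionType}
    per_lesion: list[np.ndarray] = []
    records: list[LesionRecord] = []

    n_fused = int(round(config.n_hemorrhages * config.vessel_fused_fraction))
    plan: list[tuple[LesionType, bool, bool]] = (
        [(LesionType.MICROANEURYSM, False, False)] * config.n_microaneurysms
        + [(LesionType.HEMORRHAGE, False, True)] * n_fused
        + [(LesionType.HEMORRHAGE, False, False)] * (config.n_hemorrhages - n_fused)
        + [(LesionType.HARD_EXUDATE, False, False)] * config.n_hard_exudates
        + [(LesionType.SOFT_EXUDATE, False, False)] * config.n_soft_exudates
        + [(LesionType.MICROANEURYSM, True, False)] * config.n_faint)

    cl_rows, cl_cols = np.nonzero(centerline & ~border)
    for lesion_type, faint, fused in plan:
        params = _sample_params(lesion_type, config, rng, faint, fused)
        center = None
        if fused:
            if cl_rows.size == 0:
                raise GenerationError("vessel-fused hemorrhage requested but "
                                      "no vessel centerline inside the margin")
            k = int(rng.integers(cl_rows.size))
            center = (int(cl_rows[k]), int(cl_cols[k]))
        pixels, mask, record = plant_lesion(pixels, lesion_type, params, rng,
                                            forbidden, config.margin, center)
        lesion_masks[lesion_type] |= mask
        per_lesion.append(mask)
        records.append(record)
        forbidden |= ndimage.binary_dilation(mask, spacing, iterations=6)

    pixels = pixels + rng.normal(0.0, config.noise_sigma, (h, w))
    pixels = np.clip(pixels, 0.0, 1.0)

    fov = np.zeros((h, w), dtype=bool)
    e = config.fov_erosion
    fov[e:h - e, e:w - e] = True
    gray = GrayImage(pixels=pixels, fov=fov)

    color = np.stack([np.clip(pixels + 0.30, 0, 1), pixels,
                      np.clip(pixels * 0.35, 0, 1)], axis=-1)
    scene = SyntheticScene(image=gray, color=color, vessel_mask=body,
                           vessel_centerline=centerline,
                           lesion_masks=lesion_masks, records=records,
                           seed=seed, config=config)
    scene._per_lesion_masks = per_lesion
    return scene


# ------------------------------------------------------- test-scene builders

def make_disc_image(shape: tuple[int, int], interior: float, surround: float,
                    radius: float, center: tuple[int, int] | None = None,
                    noise_sigma: float = 0.0, seed: int = 0) -> tuple[GrayImage, np.ndarray]:
    """Uniform disc of intensity ``interior`` on a flat ``surround``.

    Returns the GrayImage (full-frame FOV eroded by the default margin) and
    the exact disc mask. Used for closed-form confidence checks.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    if center is None:
        center = (h // 2, w // 2)
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.hypot(yy - center[0], xx - center[1]) <= radius
    pixels = np.full(shape, surround, dtype=np.float64)
    pixels[mask] = interior
    if noise_sigma > 0:
        pixels = np.clip(pixels + rng.normal(0, noise_sigma, shape), 0, 1)
    fov = np.zeros(shape, dtype=bool)
    fov[10:h - 10, 10:w - 10] = True
    return GrayImage(pixels=pixels, fov=fov), mask


def make_line_disc_scene(shape: tuple[int, int] = (160, 160),
                         contrast: float = 0.30, line_width: int = 3,
                         disc_radius: float = 3.0, seed: int = 0,
                         noise_sigma: float = 0.005
                         ) -> tuple[GrayImage, tuple[int, int], np.ndarray]:
    """A straight dark line plus an equal-contrast dark disc.

    Returns (image, disc_center, centerline_mask). The line is axis-aligned
    at a seeded random row/column; the disc sits well away from it. Used for
    the vessel-suppression property of the blob descriptor.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    pixels = np.full(shape, 0.55, dtype=np.float64)
    horizontal = rng.random() < 0.5
    pos = int(rng.integers(int(0.2 * h), int(0.45 * h)))
    half = line_width // 2
    centerline = np.zeros(shape, dtype=bool)
    if horizontal:
        pixels[pos - half:pos + half + 1, :] -= contrast
        centerline[pos, :] = True
    else:
        pixels[:, pos - half:pos + half + 1] -= contrast
        centerline[:, pos] = True
    # disc in the opposite half of the canvas
    dr = int(rng.integers(int(0.65 * h), int(0.85 * h)))
    dc = int(rng.integers(int(0.2 * w), int(0.8 * w)))
    yy, xx = np.mgrid[0:h, 0:w]
    disc = np.hypot(yy - dr, xx - dc) <= disc_radius
    pixels[disc] -= contrast
    if noise_sigma > 0:
        pixels = np.clip(pixels + rng.normal(0, noise_sigma, shape), 0, 1)
    fov = np.zeros(shape, dtype=bool)
    fov[10:h - 10, 10:w - 10] = True
    return GrayImage(pixels=pixels, fov=fov), (dr, dc), centerline
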