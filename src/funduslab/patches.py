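"""Self-supervised mining of clean training patches.

High-confidence regions become segmentation pseudo-labels; the windows
around them become training patches. A window is *clean* when it contains
no pixel of an indeterminate region (confidence in the ambiguous middle
band) -- those would poison the labels either way. Starting from a 10x10
window centered on a seed pixel, the side grows in 5 px steps while the
window stays clean, up to 120 px; on the first violation the window
reverts to the last clean size and is kept only if its side reached 60 px.

Per lesion type, each mined lesion patch is paired with a background patch
mined the same way from a lesion-free image at a seeded random center, so
every type's training set is exactly balanced.

Patch windows are half-open [r0, r1) x [c0, c1) in source coordinates.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize, rotate

from .imaging import GrayImage
from .mcsd import CandidateRegion
from .scoring import Bucket, is_high
from .typing_rules import LesionType

log = logging.getLogger(__name__)

INIT_SIDE = 10
STEP = 5
MIN_SIDE = 60
MAX_SIDE = 120


class PatchKind(enum.Enum):
    LESION = "lesion"
    BACKGROUND = "background"


@dataclass
class TrainingPatch:
    """One square training window with per-type label masks."""

    window: np.ndarray                      # 2-D float in [0,1]
    label_masks: dict = dfield(default_factory=dict)  # LesionType -> bool mask
    origin: tuple[int, int] = (0, 0)        # top-left in the source image
    side: int = 0                           # nominal (pre-clip) side
    kind: PatchKind = PatchKind.BACKGROUND
    lesion_type: LesionType | None = None   # target type of the dataset
    source: str = ""

    def label_for(self, ltype: LesionType) -> np.ndarray:
        m = self.label_masks.get(ltype)
        if m is None:
            return np.zeros(self.window.shape, dtype=bool)
        return m


def indeterminate_pixel_mask(regions: list[CandidateRegion],
                             shape: tuple[int, int]) -> np.ndarray:
    """Pixels belonging to INDETERMINATE regions (plus vessel-excluded HIGH
    regions, which are equally unreliable as labels). LOW regions do not
    block patches."""
    out = np.zeros(shape, dtype=bool)
    for r in regions:
        ambiguous = (r.bucket is Bucket.INDETERMINATE
                     or (r.bucket is Bucket.HIGH and r.vessel_excluded))
        if ambiguous:
            out[r.slices][r.mask] = True
    return out


def _clip_window(center: tuple[int, int], side: int,
                 bounds: tuple[int, int]) -> tuple[int, int, int, int]:
    r0 = center[0] - side // 2
    c0 = center[1] - side // 2
    r1, c1 = r0 + side, c0 + side
    return (max(0, r0), min(bounds[0], r1), max(0, c0), min(bounds[1], c1))


def grow_clean_patch(center: tuple[int, int],
                     indeterminate_mask: np.ndarray,
                     bounds: tuple[int, int] | None = None,
                     min_side: int = MIN_SIDE, max_side: int = MAX_SIDE,
                     init_side: int = INIT_SIDE, step: int = STEP
                     ) -> tuple[int, int, int, int] | None:
    """Grow a clean window around ``center``; the 10/5/120/60 schedule.

    Returns the half-open window (r0, r1, c0, c1) or None if growth stalls
    below the minimum side. Windows are clipped at the raster border and
    the clipped extent is what is compared against the size thresholds.
    """
    if bounds is None:
        bounds = indeterminate_mask.shape
    if not (0 <= center[0] < bounds[0] and 0 <= center[1] < bounds[1]):
        return None
    last_clean = None
    for side in range(init_side, max_side + 1, step):
        r0, r1, c0, c1 = _clip_window(center, side, bounds)
        if indeterminate_mask[r0:r1, c0:c1].any():
            break
        last_clean = (r0, r1, c0, c1)
    if last_clean is None:
        return None
    r0, r1, c0, c1 = last_clean
    if min(r1 - r0, c1 - c0) >= min_side:
        return last_clean
    return None


def _window_patch(gray: GrayImage, win: tuple[int, int, int, int],
                  regions: list[CandidateRegion], kind: PatchKind,
                  target: LesionType | None, source: str) -> TrainingPatch:
    r0, r1, c0, c1 = win
    window = gray.pixels[r0:r1, c0:c1].copy()
    labels: dict = {}
    for reg in regions:
        if not is_high(reg) or reg.lesion_type is None:
            continue
        full = reg.full_mask(gray.shape)[r0:r1, c0:c1]
        if not full.any():
            continue
        lt = reg.lesion_type
        labels[lt] = labels.get(lt, np.zeros(window.shape, bool)) | full
    return TrainingPatch(window=window, label_masks=labels, origin=(r0, c0),
                         side=r1 - r0, kind=kind, lesion_type=target,
                         source=source)


def mine_patch_pairs(image: GrayImage, regions: list[CandidateRegion],
                     negatives: list[GrayImage], rng_seed: int,
                     negative_regions: list[list[CandidateRegion]] | None = None,
                     source: str = "image") -> list[TrainingPatch]:
    """Mine balanced lesion/background patches from one labeled image.

    One lesion-patch attempt per typed HIGH region, grown from its centroid
    against the image's indeterminate-pixel mask; per lesion type, an equal
    number of background patches is rejection-sampled from the negative
    (lesion-free) images with the same growth procedure. Returns the
    combined list; determinism follows from ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    indet = indeterminate_pixel_mask(regions, image.shape)
    out: list[TrainingPatch] = []
    per_type: dict[LesionType, int] = {}
    highs = [r for r in regions if is_high(r) and r.lesion_type is not None]
    if not highs:
        log.warning("no typed HIGH regions; nothing to mine")
        return []
    for reg in highs:
        win = grow_clean_patch(reg.centroid, indet)
        if win is None:
            continue
        out.append(_window_patch(image, win, regions, PatchKind.LESION,
                                 reg.lesion_type, source))
        per_type[reg.lesion_type] = per_type.get(reg.lesion_type, 0) + 1

    if negative_regions is None:
        negative_regions = [[] for _ in negatives]
    neg_indets = [indeterminate_pixel_mask(rs, g.shape)
                  for g, rs in zip(negatives, negative_regions)]
    for ltype, quota in sorted(per_type.items()):
        mined = 0
        attempts = 0
        while mined < quota and attempts < 50 * quota and negatives:
            attempts += 1
            gi = int(rng.integers(len(negatives)))
            g = negatives[gi]
            rr, cc = np.nonzero(g.fov)
            if rr.size == 0:
                break
            k = int(rng.integers(rr.size))
            win = grow_clean_patch((int(rr[k]), int(cc[k])), neg_indets[gi])
            if win is None:
                continue
            out.append(_window_patch(g, win, negative_regions[gi],
                                     PatchKind.BACKGROUND, ltype,
                                     f"negative_{gi}"))
            mined += 1
        if mined < quota:
            log.warning("only %d/%d background patches for %s",
                        mined, quota, ltype.name)
    return out


# --------------------------------------------------------------- augmentation

#: the eight augmentation operations; geometric ones transform image and
#: label masks identically, photometric ones touch the image only.
AUGMENT_OPS = ("translate", "crop", "pad", "scale", "flip", "rotate",
               "noise", "intensity_shift")


def augment(patch: TrainingPatch, rng_seed: int,
            out_side: int | None = None) -> TrainingPatch:
    """Apply a seeded random subset of the augmentation operations.

    The output window is resized to ``out_side`` when given (the model
    input size); label masks always use nearest-neighbor resampling.
    """
    rng = np.random.default_rng(rng_seed)
    img = patch.window.astype(np.float64)
    masks = {lt: m.copy() for lt, m in patch.label_masks.items()}
    chosen = [op for op in AUGMENT_OPS if rng.random() < 0.5]

    def geo(fn):
        nonlocal img, masks
        img = fn(img, False)
        masks = {lt: fn(m, True) for lt, m in masks.items()}

    for op in chosen:
        if op == "flip":
            axis = int(rng.integers(2))
            geo(lambda a, _m, ax=axis: np.flip(a, axis=ax).copy())
        elif op == "rotate":
            k = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                geo(lambda a, _m, kk=k: np.rot90(a, kk).copy())
            else:
                ang = float(rng.uniform(-15, 15))
                geo(lambda a, m, an=ang: _rotate(a, an, m))
        elif op == "translate":
            dr, dc = (int(v) for v in rng.integers(-5, 6, size=2))
            geo(lambda a, _m, r=dr, c=dc: np.roll(np.roll(a, r, 0), c, 1))
        elif op == "crop":
            s = img.shape[0]
            cut = int(rng.integers(1, max(2, s // 10)))
            geo(lambda a, _m, t=cut: a[t:a.shape[0] - t, t:a.shape[1] - t])
        elif op == "pad":
            padw = int(rng.integers(1, 6))
            geo(lambda a, m, p=padw: np.pad(
                a, p, mode="reflect" if not m else "constant"))
        elif op == "scale":
            f = float(rng.uniform(0.85, 1.15))
            geo(lambda a, m, ff=f: _rescale(a, ff, m))
        elif op == "noise":
            img = img + rng.normal(0.0, 0.02, img.shape)
        elif op == "intensity_shift":
            img = img + float(rng.uniform(-0.05, 0.05))
    img = np.clip(img, 0.0, 1.0)

    if out_side is not None and img.shape != (out_side, out_side):
        img = resize(img, (out_side, out_side), order=1,
                     anti_aliasing=False, preserve_range=True)
        masks = {lt: resize(m.astype(float), (out_side, out_side), order=0,
                            preserve_range=True).astype(bool)
                 for lt, m in masks.items()}
    # masks may have drifted in shape relative to img only via ops that
    # treat them identically, so shapes always agree here
    return TrainingPatch(window=img, label_masks=masks, origin=patch.origin,
                         side=patch.side, kind=patch.kind,
                         lesion_type=patch.lesion_type, source=patch.source)


def _rotate(a: np.ndarray, angle: float, is_mask: bool) -> np.ndarray:
    out = rotate(a.astype(np.float64), angle, order=0 if is_mask else 1,
                 mode="edge", preserve_range=True)
    return out.astype(bool) if is_mask else out


def _rescale(a: np.ndarray, f: float, is_mask: bool) -> np.ndarray:
    s = a.shape[0]
    ns = max(8, int(round(s * f)))
    out = resize(a.astype(np.float64), (ns, ns), order=0 if is_mask else 1,
                 anti_aliasing=False, preserve_range=True)
    return out.astype(bool) if is_mask else out


# -------------------------------------------------------------- disk archive

def save_patch_archive(patches: list[TrainingPatch], outdir: str | Path,
                       seed: int) -> Path:
    """Write paired image/mask PNGs plus a manifest CSV; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["patch_id", "kind", "lesion_type", "origin_row",
                     "origin_col", "side", "source", "seed"])
        for i, p in enumerate(patches):
            img8 = np.round(p.window * 255).astype(np.uint8)
            Image.fromarray(img8, mode="L").save(outdir / f"image_{i:04d}.png")
            lab = np.zeros(p.window.shape, dtype=np.uint8)
            for lt, m in p.label_masks.items():
                lab[m] = int(lt)
            Image.fromarray(lab, mode="L").save(outdir / f"mask_{i:04d}.png")
            wr.writerow([i, p.kind.value,
                         p.lesion_type.name if p.lesion_type else "",
                         p.origin[0], p.origin[1], p.side, p.source, seed])
    return outdir


def load_patch_archive(outdir: str | Path) -> list[TrainingPatch]:
    """Read an archive written by :func:`save_patch_archive`."""
    outdir = Path(outdir)
    out: list[TrainingPatch] = []
    with open(outdir / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            i = int(row["patch_id"])
            img = np.asarray(Image.open(outdir / f"image_{i:04d}.png"),
                             dtype=np.float64) / 255.0
            lab = np.asarray(Image.open(outdir / f"mask_{i:04d}.png"))
            masks = {lt: lab == int(lt) for lt in LesionType
                     if (lab == int(lt)).any()}
            out.append(TrainingPatch(
                window=img, label_masks=masks,
                origin=(int(row["origin_row"]), int(row["origin_col"])),
                side=int(row["side"]), kind=PatchKind(row["kind"]),
                lesion_type=(LesionType[row["lesion_type"]]
                             if row["lesion_type"] else None),
                source=row["source"]))
    return out
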