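"""Reference experiments validating the pipeline on synthetic scenes.

Each function recomputes one quantitative property of the method from
scratch on seeded synthetic data: descriptor correctness against the
single-ray oracle, vessel suppression of the blob descriptor, closed-form
recovery of ring confidences, typing-rule accuracy on ground-truth masks,
end-to-end lesion recovery of the geometric labeler, and the smoke-scale
segmentation experiment. The test suite asserts on these numbers and the
acceptance script reports them.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from . import pipeline, synthetic, unet
from .config import RunConfig, load_config
from .imaging import GrayImage
from .mcsd import (MCSDParams, Mode, Polarity, directional_profile_contrast,
                   extract_candidate_regions, multiscale_blob_field,
                   region_from_mask, shape_descriptor_field)
from .scoring import build_ring_pair, filter_and_bucket, is_high
from .synthetic import (SceneConfig, generate_scene, make_disc_image,
                        make_line_disc_scene)
from .typing_rules import LesionType, classify_bleeding, classify_exudate
from .unet import UNetConfig

log = logging.getLogger(__name__)


# ------------------------------------------------------- descriptor oracle

def brute_force_field(gray: GrayImage, d: int, params: MCSDParams) -> np.ndarray:
    """Per-pixel loop over the single-ray oracle (reference implementation)."""
    h, w = gray.shape
    out = np.zeros((h, w))
    angles = params.angles()
    for r in range(h):
        for c in range(w):
            if not gray.fov[r, c]:
                continue
            cs = [directional_profile_contrast(gray, (r, c), d, t)
                  for t in angles]
            if params.mode is Mode.BLOB:
                if params.polarity is Polarity.DARK:
                    out[r, c] = max(0.0, min(cs))
                else:
                    out[r, c] = max(0.0, -max(cs))
            else:
                out[r, c] = max(0.0, max(cs))
    return out


def descriptor_oracle_deviation(n_images: int = 20, side: int = 32,
                                seed: int = 0) -> float:
    """Max abs deviation of the field computation from the per-pixel oracle
    over random images, cycling modes, polarities and scales."""
    rng = np.random.default_rng(seed)
    variants = [(Mode.BLOB, Polarity.DARK), (Mode.BLOB, Polarity.BRIGHT),
                (Mode.LINEAR, Polarity.DARK)]
    scales = (3, 5, 10)
    worst = 0.0
    for i in range(n_images):
        px = rng.random((side, side))
        fov = np.zeros((side, side), bool)
        m = side // 4
        fov[m:side - m, m:side - m] = True
        g = GrayImage(px, fov)
        mode, pol = variants[i % len(variants)]
        d = scales[i % len(scales)]
        params = MCSDParams(scales=(d,), n_directions=16, mode=mode,
                            polarity=pol)
        fld = shape_descriptor_field(g, d, params)
        ref = brute_force_field(g, d, params)
        worst = max(worst, float(np.abs(fld.values - ref).max()))
    return worst


# --------------------------------------------------------- vessel suppression

def vessel_suppression_ratios(n_scenes: int = 50, seed: int = 0) -> list[float]:
    """Blob response at a planted disc center over the max blob response on
    an equal-contrast line's centerline, per seeded scene."""
    params = MCSDParams()
    ratios = []
    for i in range(n_scenes):
        g, center, line = make_line_disc_scene(seed=seed + i)
        blob = multiscale_blob_field(g, params, 0.0).values
        line_max = float(blob[line & g.fov].max())
        ratios.append(float(blob[center]) / max(line_max, 1e-12))
    return ratios


# ------------------------------------------------------ confidence closed form

def confidence_grid_errors(seed: int = 0, radius: float = 4.0
                           ) -> list[float]:
    """|pipeline confidence - |b-a|/a| for a 5x5 grid of planted uniform
    discs (interior a, surround b)."""
    cfg = load_config(None, seed=seed)
    errors = []
    for a in np.linspace(0.2, 0.6, 5):
        for delta in (0.10, 0.15, 0.20, 0.25, 0.30):
            b = a + delta
            g, _mask = make_disc_image((80, 80), float(a), float(b), radius)
            params = cfg.mcsd.params(polarity=Polarity.DARK)
            fld = multiscale_blob_field(g, params, cfg.mcsd.contrast_floor)
            regs = extract_candidate_regions(fld, g, cfg.mcsd.min_area)
            regs = filter_and_bucket(regs, np.zeros(g.shape, bool), g)
            hit = [r for r in regs
                   if r.slices[0].start <= 40 < r.slices[0].stop
                   and r.slices[1].start <= 40 < r.slices[1].stop]
            if not hit:
                errors.append(float("inf"))
                continue
            closed_form = delta / a
            errors.append(abs(hit[0].confidence - closed_form))
    return errors


# --------------------------------------------------------------- typing rules

def typing_accuracy(n_lesions: int = 200, seed: int = 0) -> float:
    """Fraction of generator lesions whose ground-truth mask the typing
    rules classify as the generated type (no descriptor involved)."""
    ok = tot = 0
    s = seed
    while tot < n_lesions:
        sc = generate_scene(seed=s)
        s += 1
        for rec, mask in zip(sc.records, sc._per_lesion_masks):
            if rec.faint or tot >= n_lesions:
                continue
            dark = rec.lesion_type in (LesionType.MICROANEURYSM,
                                       LesionType.HEMORRHAGE)
            region = region_from_mask(
                mask, Polarity.DARK if dark else Polarity.BRIGHT)
            rings = build_ring_pair(sc.image, region)
            if dark:
                got = classify_bleeding(region, sc.image.pixels.size)
            else:
                got = classify_exudate(sc.image, region, rings)
            tot += 1
            ok += got is rec.lesion_type
    return ok / tot


# ------------------------------------------------------- end-to-end labeler

def labeler_recovery(n_scenes: int = 20, n_clean: int = 5, seed: int = 0,
                     cfg: RunConfig | None = None,
                     min_contrast: float = 0.25) -> dict:
    """HIGH-bucket recovery of planted lesions and clean-scene HIGH counts.

    A planted lesion counts as recovered when any HIGH region overlaps its
    ground-truth mask; only isolated lesions with contrast >= min_contrast
    enter the denominator. Type agreement is measured on the recovered
    subset against per-type HIGH masks.
    """
    cfg = cfg or load_config(None, seed=seed)
    n_lesions = n_recovered = n_type_ok = 0
    for i in range(n_scenes):
        sc = generate_scene(cfg.synth, seed=seed + i)
        res = pipeline.label_gray(sc.image, cfg)
        high_union = np.zeros(sc.image.shape, bool)
        high_by_type: dict = {}
        for r in res.high_regions:
            fm = r.full_mask(sc.image.shape)
            high_union |= fm
            if r.lesion_type is not None:
                acc = high_by_type.setdefault(r.lesion_type,
                                              np.zeros(sc.image.shape, bool))
                acc |= fm
        for rec, mask in zip(sc.records, sc._per_lesion_masks):
            if rec.faint or rec.contrast < min_contrast or rec.vessel_fused:
                continue
            n_lesions += 1
            if (high_union & mask).any():
                n_recovered += 1
                tm = high_by_type.get(rec.lesion_type)
                if tm is not None and (tm & mask).any():
                    n_type_ok += 1
    clean_cfg = replace(cfg.synth, n_microaneurysms=0, n_hemorrhages=0,
                        n_hard_exudates=0, n_soft_exudates=0, n_faint=0)
    clean_counts = []
    for i in range(n_clean):
        sc = generate_scene(clean_cfg, seed=seed + 5000 + i)
        res = pipeline.label_gray(sc.image, cfg)
        clean_counts.append(sum(1 for r in res.regions if is_high(r)))
    return {
        "n_lesions": n_lesions,
        "n_recovered": n_recovered,
        "recovery": n_recovered / max(n_lesions, 1),
        "type_agreement": n_type_ok / max(n_recovered, 1),
        "clean_scene_high_counts": clean_counts,
    }


# ----------------------------------------------------------- segmentation

def mine_training_patches(n_scenes: int = 10, n_negatives: int = 4,
                          seed: int = 0, cfg: RunConfig | None = None,
                          scene_cfg: SceneConfig | None = None):
    """Label seeded scenes and mine the balanced patch pool."""
    cfg = cfg or load_config(None, seed=seed)
    scene_cfg = scene_cfg or SceneConfig(
        n_microaneurysms=10, n_hemorrhages=0, n_hard_exudates=0,
        n_soft_exudates=0, n_faint=0)
    clean = replace(scene_cfg, n_microaneurysms=0, n_hemorrhages=0,
                    n_hard_exudates=0, n_soft_exudates=0, n_faint=0)
    scenes = [generate_scene(scene_cfg, seed=seed + i)
              for i in range(n_scenes)]
    negs = [generate_scene(clean, seed=seed + 9000 + i)
            for i in range(n_negatives)]
    labeled = [pipeline.label_gray(s.image, cfg) for s in scenes]
    nlab = [pipeline.label_gray(s.image, cfg) for s in negs]
    return pipeline.mine_dataset_patches(labeled, nlab, seed=seed), scenes


#: desk-scale training setup: native-resolution crops keep the few-pixel
#: synthetic lesions intact, and the smaller learning rate suits a
#: 200-patch dataset (the full-scale default follows the published recipe)
SMOKE_UNET = UNetConfig(input_side=24, batch_size=8, max_epochs=5, seed=0,
                        patch_fit="crop", lr_init=1e-4)


def _smoke_patch_pool(seed: int, n_patches: int = 200):
    """Mine microaneurysm patches from seeded scenes until ``n_patches``
    are available (balanced lesion/background), then trim to that count."""
    from .patches import PatchKind
    lesion, background = [], []
    batch = 0
    while min(len(lesion), len(background)) < n_patches // 2 and batch < 8:
        mined, _scenes = mine_training_patches(
            n_scenes=7, n_negatives=3, seed=seed + 131 * batch)
        for p in mined:
            if p.lesion_type is LesionType.MICROANEURYSM:
                (lesion if p.kind is PatchKind.LESION else background).append(p)
        batch += 1
    half = n_patches // 2
    return lesion[:half] + background[:half]


def training_smoke(seed: int = 0, epochs: int = 5, n_patches: int = 200):
    """Train the microaneurysm U-Net briefly; returns the history."""
    sub = _smoke_patch_pool(seed, n_patches)
    cfg = replace(SMOKE_UNET, max_epochs=epochs, seed=seed)
    _model, history = unet.train_unet(sub, cfg)
    return history, len(sub)


def detection_experiment(seed: int = 0, epochs: int = 15,
                         n_eval: int = 3) -> dict:
    """Full Stage-1 + Stage-2 experiment for microaneurysms.

    Trains on mined patches and scores sliding-window detections on
    held-out scenes against ground truth.
    """
    from . import evaluation
    sub = _smoke_patch_pool(seed)
    cfg = replace(SMOKE_UNET, max_epochs=epochs, seed=seed)
    model, history = unet.train_unet(sub, cfg)
    scene_cfg = SceneConfig(n_microaneurysms=10, n_hemorrhages=0,
                            n_hard_exudates=0, n_soft_exudates=0, n_faint=0)
    preds, truths = [], []
    for i in range(n_eval):
        sc = generate_scene(scene_cfg, seed=seed + 7000 + i)
        _mask, comps = unet.infer_masks(model, sc.image)
        preds.append(comps)
        truths.append(sc.truth_masks_of(LesionType.MICROANEURYSM))
    rep = evaluation.match_and_score(preds, truths)
    return {
        "history": history,
        "n_patches": len(sub),
        "sensitivity": rep.sensitivity,
        "fp_per_image": rep.fp_per_image,
    }
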