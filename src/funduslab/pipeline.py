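"""Orchestration of the two-stage pipeline.

Stage 1 (geometric labeler): image -> working gray + FOV -> multiscale
blob fields for both polarities -> vessel mask -> candidate regions ->
ring confidence, buckets and the vessel-adjacency filter -> rule-based
typing. Its HIGH regions are the pseudo-ground-truth.

Stage 2 (learning): clean patches mined around HIGH regions (paired with
background patches from lesion-free images) train one U-Net per lesion
type; sliding-window inference produces per-type masks that are scored
against ground truth when available.

Every stage is a pure function of (input pixels, config, seed); artifacts
are written under a run directory with the config alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dfield, replace
from pathlib import Path

import numpy as np

from . import evaluation, mcsd, patches, scoring, typing_rules, unet
from .config import RunConfig, save_config
from .errors import InputError
from .imaging import (GrayImage, load_and_resize, to_working_gray,
                      write_label_mask)
from .mcsd import CandidateRegion, Polarity
from .scoring import is_high
from .typing_rules import LesionType

log = logging.getLogger(__name__)


@dataclass
class LabelerResult:
    """Everything Stage 1 derives from one image."""

    gray: GrayImage
    regions: list[CandidateRegion]
    vessel_mask: np.ndarray
    stage_counts: dict = dfield(default_factory=dict)

    @property
    def high_regions(self) -> list[CandidateRegion]:
        return [r for r in self.regions if is_high(r)]

    def label_mask(self) -> np.ndarray:
        """Indexed lesion-type mask of the HIGH regions (0-4 contract)."""
        out = np.zeros(self.gray.shape, dtype=np.uint8)
        for r in self.high_regions:
            if r.lesion_type is not None:
                out[r.slices][r.mask] = int(r.lesion_type)
        return out

    def region_records(self) -> list[dict]:
        return [r.to_record(i) for i, r in enumerate(self.regions)]


def label_gray(gray: GrayImage, cfg: RunConfig) -> LabelerResult:
    """Run the geometric labeler on an in-memory gray image."""
    mp = cfg.mcsd.params()
    stacks = mcsd.directional_contrast_stack(gray, mp.scales, mp.n_directions)
    regions: list[CandidateRegion] = []
    counts: dict = {}
    for pol in (Polarity.DARK, Polarity.BRIGHT):
        fld = mcsd.multiscale_blob_field(gray, replace(mp, polarity=pol),
                                         cfg.mcsd.contrast_floor, stacks)
        regs = mcsd.extract_candidate_regions(fld, gray, cfg.mcsd.min_area)
        counts[f"candidates_{pol.value}"] = len(regs)
        regions.extend(regs)
    vessel_mask = mcsd.derive_vessel_mask(gray, mp, cfg.mcsd.contrast_floor,
                                          cfg.mcsd.vessel_floor, stacks)
    regions = scoring.filter_and_bucket(
        regions, vessel_mask, gray,
        cfg.scoring.low_threshold, cfg.scoring.high_threshold,
        cfg.scoring.ring_width_fraction, cfg.scoring.vessel_overlap_threshold)
    for r in regions:
        if is_high(r):
            typing_rules.classify_region(gray, r, cfg.typing)
    counts["scored"] = len(regions)
    counts["high"] = sum(1 for r in regions if is_high(r))
    counts["indeterminate"] = sum(
        1 for r in regions if r.bucket is scoring.Bucket.INDETERMINATE)
    log.info("labeler: %s", counts)
    return LabelerResult(gray=gray, regions=regions, vessel_mask=vessel_mask,
                         stage_counts=counts)


def run_geometric_labeler(image_path: str | Path, cfg: RunConfig,
                          out_dir: str | Path | None = None) -> LabelerResult:
    """Stage 1 on an image file; optionally writes region JSON + label PNG."""
    color = load_and_resize(image_path, cfg.profile)
    gray = to_working_gray(color, cfg.profile,
                           max_scale=max(cfg.mcsd.scales))
    result = label_gray(gray, cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = Path(image_path).stem
        with open(out / f"{stem}_regions.jsonl", "w") as fh:
            for rec in result.region_records():
                fh.write(json.dumps(rec) + "\n")
        write_label_mask(out / f"{stem}_labels.png", result.label_mask())
    return result


def mine_dataset_patches(labeled: list[LabelerResult],
                         negatives: list[LabelerResult],
                         seed: int) -> list[patches.TrainingPatch]:
    """Mine balanced patch sets across a labeled dataset.

    Negatives are themselves labeler outputs so their (rare) indeterminate
    regions still block background windows.
    """
    neg_grays = [n.gray for n in negatives]
    neg_regs = [n.regions for n in negatives]
    mined: list[patches.TrainingPatch] = []
    for i, res in enumerate(labeled):
        mined.extend(patches.mine_patch_pairs(
            res.gray, res.regions, neg_grays, rng_seed=seed + i,
            negative_regions=neg_regs, source=f"image_{i}"))
    return mined


def train_per_type_models(mined: list[patches.TrainingPatch],
                          cfg: RunConfig,
                          types: tuple[LesionType, ...] = tuple(LesionType)
                          ) -> dict[LesionType, tuple[unet.UNet, dict]]:
    """Train one U-Net per lesion type from the mined patch pool."""
    out: dict[LesionType, tuple[unet.UNet, dict]] = {}
    for lt in types:
        subset = [p for p in mined if p.lesion_type is lt]
        try:
            model, history = unet.train_unet(
                subset, replace(cfg.segmentation, seed=cfg.seed + int(lt)),
                lesion_type=lt, profile=cfg.profile)
        except InputError as exc:
            log.warning("skipping %s: %s", lt.name, exc)
            continue
        out[lt] = (model, history)
    return out


def run_full_pipeline(scenes: "list",
                      cfg: RunConfig,
                      out_dir: str | Path,
                      negatives: "list | None" = None,
                      eval_scenes: "list | None" = None) -> dict:
    """Labeler -> patch mining -> per-type training -> inference -> report.

    ``scenes`` (and the optional held-out ``eval_scenes``) are
    SyntheticScene objects or bare GrayImages; synthetic scenes carry their
    own ground truth, enabling the final detection report. Returns a
    summary dict; all artifacts land under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out / "config.yaml")

    def gray_of(s):
        return s.image if hasattr(s, "image") else s

    labeled = [label_gray(gray_of(s), cfg) for s in scenes]
    neg_results = [label_gray(gray_of(s), cfg) for s in (negatives or [])]
    mined = mine_dataset_patches(labeled, neg_results, cfg.seed)
    patches.save_patch_archive(mined, out / "patches", cfg.seed)
    summary: dict = {
        "n_images": len(scenes),
        "n_patches": len(mined),
        "patches_per_type": {
            lt.name: sum(1 for p in mined if p.lesion_type is lt)
            for lt in LesionType},
    }

    models = train_per_type_models(mined, cfg)
    summary["trained_types"] = [lt.name for lt in models]
    for lt, (model, history) in models.items():
        unet.save_model(model, out / f"unet_{lt.name.lower()}")
        summary[f"final_train_loss_{lt.name}"] = history["train_loss"][-1]

    if eval_scenes:
        report = evaluate_on_scenes(models, eval_scenes)
        for lt, rep in report.items():
            rep.to_json(out / f"report_{lt.name.lower()}.json")
            rep.to_csv(out / f"report_{lt.name.lower()}.csv")
        summary["evaluation"] = {lt.name: rep.to_dict()
                                 for lt, rep in report.items()}
    else:
        log.warning("no evaluation scenes with ground truth; report omitted")
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def evaluate_on_scenes(models: dict, scenes: list) -> dict:
    """Per-type detection reports of trained models on truth-bearing scenes."""
    out: dict = {}
    for lt, (model, _hist) in models.items():
        preds, truths = [], []
        for sc in scenes:
            _mask, comps = unet.infer_masks(model, sc.image)
            preds.append(comps)
            truths.append(sc.truth_masks_of(lt))
        out[lt] = evaluation.match_and_score(preds, truths)
    return out
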