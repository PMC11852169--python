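"""Detection scoring: sensitivity and false positives per image.

The matching rule is binary overlap: a predicted region is a true positive
iff it shares at least one pixel with any ground-truth region, otherwise a
false positive; a truth region counts as detected iff at least one
prediction overlaps it, and it is counted once no matter how many
predictions hit it. Sensitivity = detected truths / all truths; the false
positive rate is reported per image.

For granular reporting (ultrawide-field images are scored by lesion size
rather than type), truths can be binned by their own pixel area into
half-open intervals; false positives are binned by the predicted area.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

#: area bins used for size-granular reporting: (0,10), [10,50), [50,100), [100,inf)
DEFAULT_SIZE_BINS = ((0.0, 10.0), (10.0, 50.0), (50.0, 100.0), (100.0, math.inf))


@dataclass
class BinMetrics:
    interval: tuple[float, float]
    n_truth: int = 0
    n_detected_truth: int = 0
    n_false_positives: int = 0

    @property
    def sensitivity(self) -> float | None:
        if self.n_truth == 0:
            return None
        return self.n_detected_truth / self.n_truth


@dataclass
class DetectionReport:
    n_images: int
    n_truth: int
    n_detected_truth: int
    n_false_positives: int
    size_bins: list[BinMetrics] = dfield(default_factory=list)

    @property
    def sensitivity(self) -> float | None:
        if self.n_truth == 0:
            return None
        return self.n_detected_truth / self.n_truth

    @property
    def fp_per_image(self) -> float:
        return self.n_false_positives / self.n_images

    def to_dict(self) -> dict:
        out = {
            "n_images": self.n_images,
            "n_truth": self.n_truth,
            "n_detected_truth": self.n_detected_truth,
            "sensitivity": self.sensitivity,
            "n_false_positives": self.n_false_positives,
            "fp_per_image": self.fp_per_image,
        }
        if self.size_bins:
            out["size_bins"] = [
                {"interval": [b.interval[0],
                              "inf" if math.isinf(b.interval[1]) else b.interval[1]],
                 "n_truth": b.n_truth, "n_detected_truth": b.n_detected_truth,
                 "sensitivity": b.sensitivity,
                 "n_false_positives": b.n_false_positives}
                for b in self.size_bins]
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv(self, path: str | Path) -> None:
        rows = [{"bin": "all", **{k: v for k, v in self.to_dict().items()
                                  if k != "size_bins"}}]
        for b in self.size_bins:
            rows.append({"bin": f"[{b.interval[0]},{b.interval[1]})",
                         "n_truth": b.n_truth,
                         "n_detected_truth": b.n_detected_truth,
                         "sensitivity": b.sensitivity,
                         "n_false_positives": b.n_false_positives})
        pd.DataFrame(rows).to_csv(path, index=False)


def _check_geometry(pred_masks, truth_masks):
    shapes = {m.shape for m in pred_masks} | {m.shape for m in truth_masks}
    if len(shapes) > 1:
        raise InputError(f"masks share no single raster geometry: {shapes}")


def match_and_score(pred_regions: list[list[np.ndarray]],
                    truth_regions: list[list[np.ndarray]],
                    n_images: int | None = None,
                    min_iou: float = 0.0) -> DetectionReport:
    """Score predictions against truths over a set of images.

    ``pred_regions[i]`` / ``truth_regions[i]`` are the per-region boolean
    masks of image i. ``min_iou`` > 0 switches from the default
    any-overlap rule to an intersection-over-union criterion.
    """
    if len(pred_regions) != len(truth_regions):
        raise InputError("pred and truth image lists differ in length")
    n_images = n_images or len(pred_regions)
    n_truth = n_detected = n_fp = 0
    for preds, truths in zip(pred_regions, truth_regions):
        _check_geometry(preds, truths)
        n_truth += len(truths)
        if min_iou > 0.0:
            overlap = [[_iou(p, t) >= min_iou for t in truths] for p in preds]
        else:
            truth_union = _union(truths)
            pred_union = _union(preds)
            overlap = None
        if overlap is not None:
            for pi in range(len(preds)):
                if not any(overlap[pi]):
                    n_fp += 1
            for ti in range(len(truths)):
                if any(overlap[pi][ti] for pi in range(len(preds))):
                    n_detected += 1
        else:
            for p in preds:
                if truth_union is None or not (p & truth_union).any():
                    n_fp += 1
            for t in truths:
                if pred_union is not None and (t & pred_union).any():
                    n_detected += 1
    return DetectionReport(n_images=n_images, n_truth=n_truth,
                           n_detected_truth=n_detected,
                           n_false_positives=n_fp)


def _union(masks):
    if not masks:
        return None
    out = masks[0].copy()
    for m in masks[1:]:
        out |= m
    return out


def _iou(a, b) -> float:
    inter = float((a & b).sum())
    union = float((a | b).sum())
    return inter / union if union else 0.0


def _validate_bins(bins) -> list[tuple[float, float]]:
    bins = [tuple(map(float, b)) for b in bins]
    bins.sort()
    for lo, hi in bins:
        if hi <= lo:
            raise ConfigError(f"empty bin [{lo}, {hi})")
    for (lo1, hi1), (lo2, _hi2) in zip(bins, bins[1:]):
        if lo2 < hi1:
            raise ConfigError("size bins overlap")
        if lo2 > hi1:
            raise ConfigError("size bins leave a gap")
    if bins[0][0] != 0.0 or not math.isinf(bins[-1][1]):
        raise ConfigError("size bins must cover (0, inf)")
    return bins


def _bin_of(area: float, bins) -> int:
    # first interval is open at 0: (0, hi); the rest are [lo, hi)
    for i, (lo, hi) in enumerate(bins):
        if (area > lo if i == 0 else area >= lo) and area < hi:
            return i
    raise InputError(f"area {area} fits no bin")


def size_binned_metrics(pred_regions: list[list[np.ndarray]],
                        truth_regions: list[list[np.ndarray]],
                        bins=DEFAULT_SIZE_BINS,
                        n_images: int | None = None) -> DetectionReport:
    """match_and_score plus per-size-bin sensitivity and false positives.

    Truths are assigned to bins by their own pixel area; false positives by
    the predicted region's area.
    """
    bins = _validate_bins(bins)
    report = match_and_score(pred_regions, truth_regions, n_images)
    bm = [BinMetrics(interval=b) for b in bins]
    for preds, truths in zip(pred_regions, truth_regions):
        pred_union = _union(preds)
        truth_union = _union(truths)
        for t in truths:
            i = _bin_of(float(t.sum()), bins)
            bm[i].n_truth += 1
            if pred_union is not None and (t & pred_union).any():
                bm[i].n_detected_truth += 1
        for p in preds:
            if truth_union is None or not (p & truth_union).any():
                bm[_bin_of(float(p.sum()), bins)].n_false_positives += 1
    report.size_bins = bm
    return report
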