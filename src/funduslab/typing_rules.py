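"""Rule-based typing of high-confidence regions into four lesion types.

Polarity splits the candidates first: dark regions are bleeding spots
(microaneurysm vs hemorrhage), bright regions are exudates (hard vs soft).

Bleeding spots: a microaneurysm is small and round. Roundness is measured
as the ratio of the two eigenvalues of the covariance of the region's
boundary coordinates (principal component analysis): ~1 for a circle,
growing with elongation. A region is a microaneurysm iff its eigenvalue
ratio is <= 1.25 AND its area is below 1/200th of the image area;
otherwise it is a hemorrhage.

Exudates: a hard exudate's intensity falls off monotonically from center
to boundary, a soft exudate ("cotton-wool spot") is internally uneven. The
lesion is split by its own inner ring into a core (deeper than the ring
width w) and a shell (the band of depth <= w). The fraction f of shell
pixels brighter than the core's mean intensity is ~0 for a monotone
profile; f > 15% marks a soft exudate.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np

from .imaging import GrayImage
from .mcsd import CandidateRegion, Polarity
from .scoring import RingPair, region_signed_distance

log = logging.getLogger(__name__)


class LesionType(enum.IntEnum):
    """Lesion classes; integer values match the indexed-PNG mask contract."""

    MICROANEURYSM = 1
    HEMORRHAGE = 2
    HARD_EXUDATE = 3
    SOFT_EXUDATE = 4


@dataclass(frozen=True)
class TypingParams:
    pca_ratio_threshold: float = 1.25
    ma_size_fraction: float = 1.0 / 200.0   # of image area
    soft_exudate_fraction: float = 0.15

    def __post_init__(self) -> None:
        if min(self.pca_ratio_threshold, self.ma_size_fraction,
               self.soft_exudate_fraction) <= 0:
            raise ValueError("typing thresholds must be positive")


def elongation_ratio(boundary: np.ndarray) -> float:
    """Eigenvalue ratio lambda1/lambda2 (>= 1) of the boundary covariance.

    Degenerate boundaries (collinear points, lambda2 ~ 0) return +inf and
    therefore classify as elongated.
    """
    pts = np.asarray(boundary, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 3:
        return float("inf")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / pts.shape[0]
    lam = np.linalg.eigvalsh(cov)
    lam1, lam2 = float(lam[1]), float(lam[0])
    if lam2 <= 1e-12 * max(lam1, 1.0):
        return float("inf")
    return lam1 / lam2


def classify_bleeding(region: CandidateRegion, image_area: int,
                      params: TypingParams = TypingParams()) -> LesionType:
    """Microaneurysm iff round (ratio <= threshold) AND small; else hemorrhage."""
    ratio = elongation_ratio(region.boundary)
    small = region.area < image_area * params.ma_size_fraction
    if ratio <= params.pca_ratio_threshold and small:
        return LesionType.MICROANEURYSM
    return LesionType.HEMORRHAGE


def classify_exudate(gray: GrayImage, region: CandidateRegion,
                     rings: RingPair,
                     params: TypingParams = TypingParams()) -> LesionType:
    """Hard vs soft exudate by the core/shell intensity unevenness rule."""
    w = rings.width_w
    sd, (r0, c0) = region_signed_distance(region, gray.shape, pad=1)
    rr, cc = np.nonzero(sd > 0)
    depth = sd[rr, cc]
    vals = gray.pixels[rr + r0, cc + c0]
    core = depth > w
    shell = ~core
    if not core.any():
        log.warning("lesion at %s too small for a core; typed hard exudate",
                    region.bbox)
        return LesionType.HARD_EXUDATE
    core_mean = float(vals[core].mean())
    f = float((vals[shell] > core_mean).mean()) if shell.any() else 0.0
    if f > params.soft_exudate_fraction:
        return LesionType.SOFT_EXUDATE
    return LesionType.HARD_EXUDATE


def classify_region(gray: GrayImage, region: CandidateRegion,
                    params: TypingParams = TypingParams()) -> LesionType:
    """Type one scored region; sets and returns ``region.lesion_type``."""
    image_area = int(gray.pixels.size)
    if region.polarity is Polarity.DARK:
        label = classify_bleeding(region, image_area, params)
    else:
        label = classify_exudate(gray, region, region.rings, params)
    region.lesion_type = label
    return label
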