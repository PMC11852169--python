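"""Ring-contrast confidence scoring of candidate regions.

Noise can produce spurious candidate regions, so each region is scored by
the intensity contrast between two bands straddling its boundary: an inner
band just inside the region and an outer band just outside it, both of
width w = max(1, round(r_max / 4)) where r_max is the region's maximum
interior distance. The confidence level is

    confidence = |outer_mean - inner_mean| / inner_mean

which is invariant to multiplicative illumination changes. Regions bucket
as LOW (< 0.15, discarded from candidacy but kept for bookkeeping),
INDETERMINATE ([0.15, 0.35), excluded from training patches) or HIGH
(>= 0.35, treated as lesions).

Bands come from a signed Euclidean distance field (positive inside,
negative outside, zero on the boundary contour), computed with the exact
distance transform; pixel centers sit at half-integer distances from the
implied boundary contour, hence the 0.5 px offset below.

Dark regions whose outer band lies mostly on vessel pixels are flagged
``vessel_excluded``: a dark spot fused with a vessel scores high contrast
for the wrong reason and must not become a bleeding-spot pseudo-label.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InputError, ScoringError
from .imaging import GrayImage
from .mcsd import CandidateRegion, Polarity

log = logging.getLogger(__name__)

LOW_THRESHOLD = 0.15
HIGH_THRESHOLD = 0.35
RING_WIDTH_FRACTION = 0.25
VESSEL_OVERLAP_THRESHOLD = 0.35


class Bucket(enum.Enum):
    LOW = "low"
    INDETERMINATE = "indeterminate"
    HIGH = "high"


@dataclass
class RingPair:
    """Inner/outer boundary bands of one region and their mean intensities.

    Coordinates are global (row, col) index arrays.
    """

    inner_band: tuple[np.ndarray, np.ndarray]
    outer_band: tuple[np.ndarray, np.ndarray]
    width_w: int
    inner_mean: float
    outer_mean: float


def signed_distance_field(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance: positive inside, negative outside.

    Pixel centers adjacent to the boundary contour get +/-0.5; the result is
    within 0.5 px of the exact signed distance to the region outline.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InputError("signed_distance_field: empty mask")
    if mask.all():
        return _inside_distance(mask)
    return np.where(mask, _inside_distance(mask),
                    -(ndimage.distance_transform_edt(~mask) - 0.5))


def _inside_distance(mask: np.ndarray) -> np.ndarray:
    if (~mask).any():
        return ndimage.distance_transform_edt(mask) - 0.5
    # Degenerate full-frame mask: distance to the raster border.
    h, w = mask.shape
    r, c = np.mgrid[0:h, 0:w]
    return np.minimum.reduce([r, c, h - 1 - r, w - 1 - c]).astype(np.float64) + 0.5


def region_signed_distance(region: CandidateRegion,
                           shape: tuple[int, int],
                           pad: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Signed distance of a region on its padded bounding box.

    Returns (sd, (row0, col0)) where sd[i, j] corresponds to global pixel
    (row0 + i, col0 + j). Padding is clipped at the raster border.
    """
    rs, cs = region.slices
    r0 = max(0, rs.start - pad)
    r1 = min(shape[0], rs.stop + pad)
    c0 = max(0, cs.start - pad)
    c1 = min(shape[1], cs.stop + pad)
    local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    local[rs.start - r0:rs.stop - r0, cs.start - c0:cs.stop - c0] = region.mask
    return signed_distance_field(local), (r0, c0)


def _geometry(region: CandidateRegion, shape: tuple[int, int]) -> None:
    """Fill r_max and centroid (pixel of maximum interior distance)."""
    sd, (r0, c0) = region_signed_distance(region, shape, pad=1)
    idx = int(np.argmax(sd))
    ri, ci = np.unravel_index(idx, sd.shape)
    region.r_max = float(sd[ri, ci])
    region.centroid = (int(ri + r0), int(ci + c0))


def build_ring_pair(gray: GrayImage, region: CandidateRegion,
                    ring_width_fraction: float = RING_WIDTH_FRACTION) -> RingPair:
    """Construct the inner/outer bands of width max(1, round(r_max/4)).

    Inner band: signed distance in (0, w] (inside, boundary-adjacent).
    Outer band: signed distance in [-w, 0), restricted to the FOV.
    """
    if region.r_max is None or region.centroid is None:
        _geometry(region, gray.shape)
    w = max(1, int(round(region.r_max * ring_width_fraction)))
    sd, (r0, c0) = region_signed_distance(region, gray.shape, pad=w + 1)
    inner = (sd > 0) & (sd <= w)
    outer = (sd < 0) & (sd >= -w)
    ir, ic = np.nonzero(inner)
    orow, ocol = np.nonzero(outer)
    ir, ic = ir + r0, ic + c0
    orow, ocol = orow + r0, ocol + c0
    keep = gray.fov[orow, ocol]
    orow, ocol = orow[keep], ocol[keep]
    if orow.size == 0:
        raise ScoringError("outer ring entirely outside the field of view")
    inner_mean = float(gray.pixels[ir, ic].mean())
    outer_mean = float(gray.pixels[orow, ocol].mean())
    return RingPair(inner_band=(ir, ic), outer_band=(orow, ocol), width_w=w,
                    inner_mean=inner_mean, outer_mean=outer_mean)


def confidence_level(rings: RingPair) -> float:
    """|outer - inner| / inner ring-mean contrast ratio."""
    if rings.inner_mean == 0.0:
        log.warning("inner ring mean is 0; confidence set to +inf")
        return float("inf")
    return abs(rings.outer_mean - rings.inner_mean) / rings.inner_mean


def bucket_of(confidence: float,
              low_threshold: float = LOW_THRESHOLD,
              high_threshold: float = HIGH_THRESHOLD) -> Bucket:
    """Three-way bucketing; thresholds pass at equality (>=)."""
    if confidence >= high_threshold:
        return Bucket.HIGH
    if confidence >= low_threshold:
        return Bucket.INDETERMINATE
    return Bucket.LOW


def filter_and_bucket(regions: list[CandidateRegion],
                      vessel_mask: np.ndarray,
                      gray: GrayImage,
                      low_threshold: float = LOW_THRESHOLD,
                      high_threshold: float = HIGH_THRESHOLD,
                      ring_width_fraction: float = RING_WIDTH_FRACTION,
                      vessel_overlap_threshold: float = VESSEL_OVERLAP_THRESHOLD,
                      ) -> list[CandidateRegion]:
    """Score, bucket and vessel-filter all regions.

    Every region gets confidence and bucket; LOW regions stay in the list
    (they matter for patch-cleanliness bookkeeping) but are never lesions.
    A DARK region whose outer band overlaps vessel pixels above the
    threshold fraction is flagged vessel_excluded and removed from HIGH
    candidacy. Regions that cannot be scored are dropped.
    """
    if vessel_mask.shape != gray.shape:
        raise InputError("vessel mask is not aligned with the image")
    scored: list[CandidateRegion] = []
    for region in regions:
        try:
            rings = build_ring_pair(gray, region, ring_width_fraction)
        except ScoringError as exc:
            log.info("region at %s discarded: %s", region.bbox, exc)
            continue
        region.rings = rings
        region.confidence = confidence_level(rings)
        region.bucket = bucket_of(region.confidence, low_threshold,
                                  high_threshold)
        if region.polarity is Polarity.DARK:
            orow, ocol = rings.outer_band
            frac = float(vessel_mask[orow, ocol].mean())
            if frac > vessel_overlap_threshold:
                region.vessel_excluded = True
        scored.append(region)
    return scored


def is_high(region: CandidateRegion) -> bool:
    """HIGH-bucket lesion candidate, not vessel-excluded."""
    return region.bucket is Bucket.HIGH and not region.vessel_excluded
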