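"""Circular well detection with confidence filtering, NMS and role assignment.

Wells are bright discs on a dark background, so detection is a scale-searched
circular matched filter: Laplacian-of-Gaussian maxima propose candidate
centres and scales, and each candidate is scored by the Pearson correlation
between the local image patch and an ideal disc template at the best-fitting
radius.  That correlation is the detection confidence — it is 1 for a perfect
disc, lies in [0, 1] after clamping, and is exactly invariant under affine
intensity changes of the image (gain/offset), so the same probability
threshold works across cameras.  Candidates are filtered at a probability
threshold (default 0.67), then greedily non-maximum suppressed with a
bounding-box IoU threshold (default 0.01, i.e. essentially no overlap
tolerated), and finally assigned to layout roles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.feature import blob_log

from .layout import SensorLayout

__all__ = [
    "Detection",
    "DetectorParams",
    "RoleAssignment",
    "RoleAssignmentError",
    "luminance",
    "detect_candidates",
    "filter_by_confidence",
    "non_maximum_suppression",
    "circle_bbox_iou",
    "assign_roles",
]

MIN_IMAGE_SIDE = 32


@dataclass(frozen=True)
class Detection:
    """One candidate well: pixel centre (0-based, pixel-centre convention),
    radius and confidence in [0, 1]."""

    x: float
    y: float
    radius: float
    confidence: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "radius": self.radius,
                "confidence": self.confidence}


@dataclass(frozen=True)
class DetectorParams:
    """Detector configuration.

    The probability threshold and NMS overlap threshold default to the
    values the phone application was tuned to (0.67 and 0.01).
    """

    probability_threshold: float = 0.67
    nms_overlap_threshold: float = 0.01
    radius_min_px: float = 6.0
    radius_max_px: float = 40.0
    n_scales: int = 10
    blob_threshold: float = 0.02  # LoG response floor on the range-normalized image

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability_threshold <= 1.0:
            raise ValueError("probability_threshold must lie in [0, 1]")
        if not 0.0 <= self.nms_overlap_threshold <= 1.0:
            raise ValueError("nms_overlap_threshold must lie in [0, 1]")
        if not 0 < self.radius_min_px < self.radius_max_px:
            raise ValueError("radius search range is empty")


class RoleAssignmentError(ValueError):
    """A layout role could not be matched to a detection."""


@dataclass(frozen=True)
class RoleAssignment:
    """Mapping from well label to detection, with registration residual."""

    mapping: dict  # label -> Detection
    residual_px: float
    roles: dict  # label -> WellRole

    def detection(self, label: str) -> Detection:
        return self.mapping[label]


def luminance(image: np.ndarray, channel: int | None = None) -> np.ndarray:
    """Reduce an image to 2-D luminance as float.

    RGB images are averaged over channels by default (the blue-green
    emission spreads over G and B); ``channel`` selects a single plane.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[-1] in (3, 4):
        if channel is not None:
            return img[..., channel]
        return img[..., :3].mean(axis=-1)
    raise ValueError(f"expected 2-D or RGB image, got shape {img.shape}")


def _disc_template(radius: float, window: int) -> np.ndarray:
    """Ideal disc of given radius centred in a (2*window+1)^2 patch,
    with a 1 px antialiased rim."""
    yy, xx = np.mgrid[-window:window + 1, -window:window + 1]
    dist = np.hypot(xx, yy)
    return np.clip(radius + 0.5 - dist, 0.0, 1.0)


def _patch_correlation(img: np.ndarray, cx: int, cy: int, radius: float) -> float:
    """Pearson correlation between the image around (cx, cy) and an ideal
    disc of the given radius.  Window spans 1.6 radii so the template sees
    both the disc and its dark surround; cropped consistently at borders."""
    window = int(math.ceil(1.6 * radius))
    h, w = img.shape
    y0, y1 = cy - window, cy + window + 1
    x0, x1 = cx - window, cx + window + 1
    ty0, tx0 = max(0, -y0), max(0, -x0)
    y0, x0 = max(0, y0), max(0, x0)
    y1, x1 = min(h, y1), min(w, x1)
    patch = img[y0:y1, x0:x1]
    tmpl = _disc_template(radius, window)[ty0:ty0 + (y1 - y0), tx0:tx0 + (x1 - x0)]
    if patch.size < 9 or patch.size < 0.5 * (2 * window + 1) ** 2:
        return 0.0
    p = patch - patch.mean()
    t = tmpl - tmpl.mean()
    denom = np.sqrt((p * p).sum() * (t * t).sum())
    if denom == 0:
        return 0.0
    return float((p * t).sum() / denom)


def detect_candidates(image: np.ndarray, params: DetectorParams | None = None) -> list[Detection]:
    """Find candidate wells, sorted by decreasing confidence.

    Constant images (including dark frames) yield an empty list.  Images
    smaller than 32x32 px are rejected.
    """
    if params is None:
        params = DetectorParams()
    img = luminance(image)
    if min(img.shape) < MIN_IMAGE_SIDE:
        raise ValueError(f"image must be at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE} px")
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return []
    norm = (img - lo) / (hi - lo)

    blobs = blob_log(
        norm,
        min_sigma=params.radius_min_px / math.sqrt(2),
        max_sigma=params.radius_max_px / math.sqrt(2),
        num_sigma=params.n_scales,
        threshold=params.blob_threshold,
        overlap=1.0,
    )

    radii = np.geomspace(params.radius_min_px, params.radius_max_px, 25)
    detections: list[Detection] = []
    for by, bx, bsigma in blobs:
        cx, cy = int(round(bx)), int(round(by))
        r0 = bsigma * math.sqrt(2)
        # radius scan near the blob scale, then a +-1 px centre refinement
        near = radii[(radii > 0.5 * r0) & (radii < 2.0 * r0)]
        if near.size == 0:
            near = np.array([r0])
        best_r, best_c = max(
            ((r, _patch_correlation(img, cx, cy, r)) for r in near),
            key=lambda rc: rc[1],
        )
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dx == dy == 0:
                    continue
                c = _patch_correlation(img, cx + dx, cy + dy, best_r)
                if c > best_c:
                    best_c, cx, cy = c, cx + dx, cy + dy
        detections.append(
            Detection(x=float(cx), y=float(cy), radius=float(best_r),
                      confidence=float(np.clip(best_c, 0.0, 1.0)))
        )

    # merge duplicates from adjacent scales (same centre within 2 px)
    detections.sort(key=lambda d: (-d.confidence, d.y, d.x))
    merged: list[Detection] = []
    for d in detections:
        if all(math.hypot(d.x - m.x, d.y - m.y) > 2.0 for m in merged):
            merged.append(d)
    return merged


def filter_by_confidence(detections: list[Detection], threshold: float) -> list[Detection]:
    """Keep detections with confidence >= threshold, order preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [d for d in detections if d.confidence >= threshold]


def circle_bbox_iou(a: Detection, b: Detection) -> float:
    """IoU of the axis-aligned bounding boxes of two detection circles."""
    ax0, ax1 = a.x - a.radius, a.x + a.radius
    ay0, ay1 = a.y - a.radius, a.y + a.radius
    bx0, bx1 = b.x - b.radius, b.x + b.radius
    by0, by1 = b.y - b.radius, b.y + b.radius
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union > 0 else 0.0


def non_maximum_suppression(
    detections: list[Detection], overlap_threshold: float
) -> list[Detection]:
    """Greedy NMS by decreasing confidence.

    A detection is removed when its bounding-box IoU with any already-kept
    detection exceeds ``overlap_threshold``.  Ties in confidence are broken
    by smaller centre row, then column, making the result independent of
    input order.  Idempotent.
    """
    if not 0.0 <= overlap_threshold <= 1.0:
        raise ValueError("overlap_threshold must lie in [0, 1]")
    ordered = sorted(detections, key=lambda d: (-d.confidence, d.y, d.x))
    kept: list[Detection] = []
    for d in ordered:
        if all(circle_bbox_iou(d, k) <= overlap_threshold for k in kept):
            kept.append(d)
    return kept


def _mean_disc_intensity(img: np.ndarray, det: Detection) -> float:
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.hypot(xx - det.x, yy - det.y) <= det.radius
    return float(img[mask].mean()) if mask.any() else 0.0


def _assign_flower(
    detections: list[Detection],
    layout: SensorLayout,
    orientation_deg: float | None,
    image: np.ndarray | None,
) -> RoleAssignment:
    if len(detections) < 7:
        missing = "sample" if len(detections) == 0 else "undetermined"
        raise RoleAssignmentError(
            f"flower7 needs 7 detections, got {len(detections)} (missing role: {missing})"
        )
    pts = np.array([(d.x, d.y) for d in detections])
    centroid = pts.mean(axis=0)
    d_from_centroid = np.hypot(*(pts - centroid).T)
    inner = int(np.argmin(d_from_centroid))
    sample = detections[inner]
    outers = [d for i, d in enumerate(detections) if i != inner]
    if len(outers) > 6:
        # keep the six most confident ring candidates
        outers = sorted(outers, key=lambda d: -d.confidence)[:6]
    if len(outers) < 6:
        raise RoleAssignmentError("fewer than 6 outer wells detected")

    angles = np.array(
        [math.degrees(math.atan2(d.y - sample.y, d.x - sample.x)) for d in outers]
    )
    if orientation_deg is None:
        if image is None:
            raise RoleAssignmentError(
                "flower orientation unknown: pass orientation_deg or the image "
                "(S0 is then taken as the brightest outer well)"
            )
        lum = luminance(image)
        bright = int(np.argmax([_mean_disc_intensity(lum, d) for d in outers]))
        orientation_deg = float(angles[bright])

    rel = np.mod(angles - orientation_deg, 360.0)
    slots = np.rint(rel / 60.0).astype(int) % 6
    resid_deg = np.abs((rel - 60.0 * np.rint(rel / 60.0) + 180.0) % 360.0 - 180.0)
    if np.any(resid_deg > 15.0):
        worst = int(np.argmax(resid_deg))
        raise RoleAssignmentError(
            f"outer well at angle {angles[worst]:.1f} deg does not sit on the "
            f"60-degree ring grid (off by {resid_deg[worst]:.1f} deg)"
        )
    # angular ambiguity: two outer wells competing for one slot
    for slot in range(6):
        idx = np.flatnonzero(slots == slot)
        if len(idx) > 1:
            raise RoleAssignmentError(
                f"ambiguous angular order: wells at "
                f"{', '.join(f'{angles[i]:.1f}' for i in idx)} deg both map to S{slot}"
            )
    if len(set(slots)) < 6:
        missing = sorted(set(range(6)) - set(slots.tolist()))[0]
        raise RoleAssignmentError(f"missing role: S{missing}")
    pair_gap = np.abs((angles[:, None] - angles[None, :] + 180.0) % 360.0 - 180.0)
    iu = np.triu_indices(6, k=1)
    if np.any(pair_gap[iu] < 5.0):
        raise RoleAssignmentError("ambiguous angular order: two wells within 5 degrees")

    mapping = {"sample": sample}
    for slot, det in zip(slots, outers):
        mapping[f"S{slot}"] = det

    # registration residual against an ideal ring of the mean detected radius
    ring_r = float(np.mean(np.hypot(*(np.array([(d.x, d.y) for d in outers]) -
                                      (sample.x, sample.y)).T)))
    resid = []
    for slot, det in zip(slots, outers):
        theta = math.radians(orientation_deg + 60.0 * slot)
        px = sample.x + ring_r * math.cos(theta)
        py = sample.y + ring_r * math.sin(theta)
        resid.append(math.hypot(det.x - px, det.y - py))
    roles = dict(zip(layout.labels, layout.roles))
    return RoleAssignment(mapping=mapping, residual_px=float(np.mean(resid)), roles=roles)


def _assign_grid(
    detections: list[Detection],
    layout: SensorLayout,
    orientation_deg: float | None,
) -> RoleAssignment:
    from scipy.optimize import linear_sum_assignment

    n = layout.n_wells
    if len(detections) < n:
        raise RoleAssignmentError(
            f"grid3x6 needs {n} detections, got {len(detections)}"
        )
    theta = math.radians(orientation_deg or 0.0)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    ref = np.asarray(layout.well_centers_mm, dtype=float) @ rot.T / layout.mm_per_pixel
    pts = np.array([(d.x, d.y) for d in detections])
    ref_c = ref - ref.mean(axis=0)
    pts_c = pts - pts.mean(axis=0)
    scale = np.sqrt((pts_c ** 2).sum() / max(len(pts), 1)) / np.sqrt((ref_c ** 2).sum() / n)
    pred = ref_c * scale + pts.mean(axis=0)

    cost = np.hypot(*(pred[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
    rows, cols = linear_sum_assignment(cost)
    tol = layout.well_radius_px
    mapping, dists = {}, []
    for i, j in zip(rows, cols):
        if cost[i, j] > tol:
            raise RoleAssignmentError(
                f"missing role: {layout.labels[i]} (nearest detection "
                f"{cost[i, j]:.1f} px away, tolerance {tol:.1f})"
            )
        mapping[layout.labels[i]] = detections[j]
        dists.append(cost[i, j])
    roles = dict(zip(layout.labels, layout.roles))
    return RoleAssignment(mapping=mapping, residual_px=float(np.mean(dists)), roles=roles)


def assign_roles(
    detections: list[Detection],
    layout: SensorLayout,
    orientation_deg: float | None = None,
    image: np.ndarray | None = None,
) -> RoleAssignment:
    """Assign detections to layout roles.

    Flower sensor: the detection nearest the centroid is the sample well;
    the outer six are ordered by angle from the orientation cue (S0's
    direction).  Without an explicit ``orientation_deg``, S0 is taken as the
    brightest outer well in ``image`` (the control is uninhibited and so
    emits maximal light).  Array sensor: row-major nearest-neighbour match
    after similarity registration.  Any unmatched role raises
    :class:`RoleAssignmentError` naming the role.
    """
    if layout.kind == "flower7":
        return _assign_flower(detections, layout, orientation_deg, image)
    if layout.kind == "grid3x6":
        return _assign_grid(detections, layout, orientation_deg)
    raise ValueError(f"unknown layout kind {layout.kind!r}")
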