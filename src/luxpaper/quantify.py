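"""Per-well signal extraction in relative light units (RLU).

The RLU of a well is the mean pixel value over the detected disc minus a
local background taken as the median of a concentric annulus (1.2-1.6 well
radii) — the mean-gray-value convention, robust to radius jitter and to
glow from neighbouring wells.  Signals are then normalized to the control
well (residual activity, % of control), the quantity the dose-response
calibration is fitted on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .detect import Detection, luminance
from .layout import WellRole

__all__ = [
    "WellQuant",
    "AssayInvalidError",
    "extract_rlu",
    "normalize_to_control",
    "stability_normalize",
]

ANNULUS_INNER = 1.2  # in units of the well radius
ANNULUS_OUTER = 1.6


class AssayInvalidError(RuntimeError):
    """The assay cannot be interpreted (e.g. dead control well)."""


@dataclass(frozen=True)
class WellQuant:
    """Quantified signal of one well."""

    label: str
    role: WellRole
    x: float
    y: float
    radius: float
    rlu: float
    background_adu: float
    saturated_fraction: float
    pixel_sd: float  # SD of background-subtracted in-disc pixels
    n_pixels: int
    residual_activity_pct: float | None = None
    clamped: bool = False

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "role": self.role.value,
            "x": self.x,
            "y": self.y,
            "radius": self.radius,
            "rlu": self.rlu,
            "background_adu": self.background_adu,
            "saturated_fraction": self.saturated_fraction,
            "residual_activity_pct": self.residual_activity_pct,
            "clamped": self.clamped,
        }
        return d


def _saturation_value(image: np.ndarray) -> float | None:
    if image.dtype == np.uint8:
        return 255.0
    if image.dtype == np.uint16:
        return 65535.0
    return None


def extract_rlu(
    image: np.ndarray,
    detection: Detection,
    label: str = "",
    role: WellRole = WellRole.SAMPLE,
    others: list[Detection] = (),
    saturation_value: float | None = None,
) -> WellQuant:
    """Extract the background-subtracted mean signal of one well.

    ``rlu = mean(disc) - median(annulus)``, clamped at zero (a flag records
    clamping).  The disc must lie fully inside the image; the background
    annulus must not intersect any disc in ``others``.
    """
    lum = luminance(image)
    h, w = lum.shape
    r = detection.radius
    if (detection.x - r < -0.5 or detection.y - r < -0.5
            or detection.x + r > w - 0.5 or detection.y + r > h - 0.5):
        raise ValueError(
            f"ROI {label or '(unnamed)'} extends outside the image"
        )
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(xx - detection.x, yy - detection.y)
    disc = dist <= r
    annulus = (dist > ANNULUS_INNER * r) & (dist <= ANNULUS_OUTER * r)
    for other in others:
        if other is detection:
            continue
        d_other = np.hypot(xx - other.x, yy - other.y) <= other.radius
        if np.any(annulus & d_other):
            raise ValueError(
                f"background annulus of well {label or '(unnamed)'} overlaps "
                f"the ROI at ({other.x:.0f}, {other.y:.0f})"
            )
    if not annulus.any():
        raise ValueError("background annulus is empty")

    background = float(np.median(lum[annulus]))
    mean_in = float(lum[disc].mean())
    rlu = mean_in - background
    clamped = rlu < 0
    rlu = max(rlu, 0.0)

    if saturation_value is None:
        saturation_value = _saturation_value(np.asarray(image))
    if saturation_value is None:
        sat_frac = 0.0
    else:
        sat_frac = float(np.mean(np.asarray(luminance(image))[disc] >= saturation_value))

    return WellQuant(
        label=label,
        role=role,
        x=detection.x,
        y=detection.y,
        radius=r,
        rlu=rlu,
        background_adu=background,
        saturated_fraction=sat_frac,
        pixel_sd=float(lum[disc].std(ddof=1)),
        n_pixels=int(disc.sum()),
        clamped=clamped,
    )


def normalize_to_control(quants: list[WellQuant]) -> list[WellQuant]:
    """Express every well as residual activity, % of the control well.

    The control maps to exactly 100 %.  A control with zero signal makes the
    assay uninterpretable (dead control) and raises
    :class:`AssayInvalidError`.  With several control replicates (array
    sensor) their mean is the reference.
    """
    controls = [q for q in quants if q.role is WellRole.CONTROL]
    if not controls:
        raise AssayInvalidError("no control well present")
    ref = float(np.mean([q.rlu for q in controls]))
    if ref <= 0:
        raise AssayInvalidError("control failure: control well shows no signal")
    out = []
    for q in quants:
        pct = 100.0 * q.rlu / ref
        if q.role is WellRole.CONTROL and len(controls) == 1:
            pct = 100.0
        out.append(replace(q, residual_activity_pct=pct))
    return out


def stability_normalize(series, day0_rlu: float) -> list[float]:
    """Per-day signal as % of the freshly prepared (day 0) signal."""
    if day0_rlu <= 0:
        raise AssayInvalidError("day-0 signal must be positive")
    return [100.0 * float(v) / float(day0_rlu) for v in series]
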