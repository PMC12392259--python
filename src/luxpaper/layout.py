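"""Sensor geometries: the 7-well flower sensor and the 3x6 well array.

Coordinates are millimetres in the paper frame: origin at the paper centre,
x to the right, y downward (image convention).  ``mm_per_pixel`` fixes the
reproduction scale when the layout is rendered or registered to a photo.

The flower sensor is a 30 mm disc with six 5 mm calibrator wells (S0..S5)
on a ring around one central sample well; S0 carries the zero-dose control.
The array sensor holds 3 replicate rows x 6 concentration columns of 7 mm
wells, used for calibration studies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import yaml

__all__ = ["WellRole", "SensorLayout", "flower7_layout", "grid3x6_layout"]


class WellRole(str, Enum):
    CONTROL = "control"
    CALIBRATOR = "calibrator"
    SAMPLE = "sample"


@dataclass(frozen=True)
class SensorLayout:
    """Geometric and semantic description of one paper sensor.

    ``concentrations`` holds the nominal analyte concentration for control
    and calibrator wells and ``None`` for the sample well.  ``labels`` name
    wells ("S0".."S5", "sample" for the flower; "r{i}c{j}" for the array).
    """

    kind: str  # "flower7" | "grid3x6"
    paper_diameter_mm: float
    well_centers_mm: tuple[tuple[float, float], ...]
    well_diameter_mm: float
    roles: tuple[WellRole, ...]
    concentrations: tuple[float | None, ...]
    unit: str = "ppm"
    mm_per_pixel: float = 0.2
    labels: tuple[str, ...] = ()
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.well_centers_mm)
        if not (len(self.roles) == len(self.concentrations) == len(self.labels) == n):
            raise ValueError("well attribute lists must have equal length")
        if self.kind == "flower7" and n != 7:
            raise ValueError("flower7 layout must have exactly 7 wells")
        if self.kind == "grid3x6" and n != 18:
            raise ValueError("grid3x6 layout must have exactly 18 wells")
        if self.kind == "flower7":
            if sum(r is WellRole.SAMPLE for r in self.roles) != 1:
                raise ValueError("flower7 needs exactly one sample well")
            if sum(r is WellRole.CONTROL for r in self.roles) != 1:
                raise ValueError("flower7 needs exactly one control well")
        for role, conc in zip(self.roles, self.concentrations):
            if role is WellRole.SAMPLE:
                if conc is not None:
                    raise ValueError("sample well carries no nominal concentration")
            elif conc is None or conc < 0:
                raise ValueError("calibrator/control wells need a concentration >= 0")
            if role is WellRole.CONTROL and conc != 0:
                raise ValueError("control well concentration must be 0")
        cal = self.calibrator_concentrations()
        if any(b <= a for a, b in zip(cal, cal[1:])):
            raise ValueError("calibrator concentrations must be strictly increasing")
        self._check_geometry()

    def _check_geometry(self) -> None:
        centers = np.asarray(self.well_centers_mm, dtype=float)
        r = self.well_diameter_mm / 2.0
        dist = np.hypot(*(centers[:, None, :] - centers[None, :, :]).transpose(2, 0, 1))
        iu = np.triu_indices(len(centers), k=1)
        if np.any(dist[iu] < 2 * r):
            raise ValueError("well discs overlap")
        if np.any(np.hypot(centers[:, 0], centers[:, 1]) + r > self.paper_diameter_mm / 2):
            raise ValueError("a well extends outside the paper disc")

    # -- derived geometry -------------------------------------------------

    @property
    def n_wells(self) -> int:
        return len(self.well_centers_mm)

    @property
    def well_radius_px(self) -> float:
        return self.well_diameter_mm / 2.0 / self.mm_per_pixel

    def calibrator_concentrations(self) -> list[float]:
        """Concentrations of control + calibrator wells in label order (S0..S5)."""
        pairs = [
            (lbl, c)
            for lbl, c, role in zip(self.labels, self.concentrations, self.roles)
            if role is not WellRole.SAMPLE
        ]
        if self.kind == "flower7":
            pairs.sort(key=lambda p: p[0])
            return [c for _, c in pairs]
        # grid: unique column concentrations in increasing order
        return sorted(set(c for _, c in pairs))

    def image_shape(self, margin: float = 0.15) -> tuple[int, int]:
        """Pixel shape of a rendered image with a fractional margin."""
        side = int(math.ceil(self.paper_diameter_mm * (1 + 2 * margin) / self.mm_per_pixel))
        return (side, side)

    def well_centers_px(self, image_shape: tuple[int, int]) -> np.ndarray:
        """(n, 2) array of (x, y) pixel centres for a paper-centred image."""
        h, w = image_shape[:2]
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        centers = np.asarray(self.well_centers_mm, dtype=float) / self.mm_per_pixel
        return centers + [cx, cy]

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "paper_diameter_mm": self.paper_diameter_mm,
            "well_centers_mm": [list(c) for c in self.well_centers_mm],
            "well_diameter_mm": self.well_diameter_mm,
            "roles": [r.value for r in self.roles],
            "concentrations": list(self.concentrations),
            "unit": self.unit,
            "mm_per_pixel": self.mm_per_pixel,
            "labels": list(self.labels),
            "orientation_deg": self.orientation_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorLayout":
        return cls(
            kind=d["kind"],
            paper_diameter_mm=float(d["paper_diameter_mm"]),
            well_centers_mm=tuple((float(x), float(y)) for x, y in d["well_centers_mm"]),
            well_diameter_mm=float(d["well_diameter_mm"]),
            roles=tuple(WellRole(r) for r in d["roles"]),
            concentrations=tuple(None if c is None else float(c) for c in d["concentrations"]),
            unit=d.get("unit", "ppm"),
            mm_per_pixel=float(d.get("mm_per_pixel", 0.2)),
            labels=tuple(d["labels"]),
            orientation_deg=float(d.get("orientation_deg", 0.0)),
        )

    def save(self, path) -> None:
        path = Path(path)
        text = (
            yaml.safe_dump(self.to_dict(), sort_keys=False)
            if path.suffix in (".yml", ".yaml")
            else json.dumps(self.to_dict(), indent=2)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "SensorLayout":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(d)


def flower7_layout(
    calibrator_concs,
    unit: str = "ppm",
    orientation_deg: float = 0.0,
    paper_diameter_mm: float = 30.0,
    well_diameter_mm: float = 5.0,
    ring_radius_mm: float = 10.0,
    mm_per_pixel: float = 0.2,
) -> SensorLayout:
    """Seven-well flower sensor: S0..S5 on a ring, sample in the centre.

    ``calibrator_concs`` are the six strictly increasing concentrations for
    S0..S5; S0 must be 0 (the control).  ``orientation_deg`` is the angle of
    S0 from the +x axis, i.e. the physical orientation cue of the sensor.
    """
    concs = [float(c) for c in calibrator_concs]
    if len(concs) != 6:
        raise ValueError("flower7 requires exactly 6 calibrator concentrations")
    if concs[0] != 0:
        raise ValueError("S0 (control) concentration must be 0")
    centers = []
    for k in range(6):
        theta = math.radians(orientation_deg + 60.0 * k)
        centers.append((ring_radius_mm * math.cos(theta), ring_radius_mm * math.sin(theta)))
    centers.append((0.0, 0.0))
    roles = (WellRole.CONTROL,) + (WellRole.CALIBRATOR,) * 5 + (WellRole.SAMPLE,)
    return SensorLayout(
        kind="flower7",
        paper_diameter_mm=paper_diameter_mm,
        well_centers_mm=tuple(centers),
        well_diameter_mm=well_diameter_mm,
        roles=roles,
        concentrations=tuple(concs) + (None,),
        unit=unit,
        mm_per_pixel=mm_per_pixel,
        labels=tuple(f"S{k}" for k in range(6)) + ("sample",),
        orientation_deg=orientation_deg,
    )


def grid3x6_layout(
    column_concs,
    unit: str = "ppm",
    well_diameter_mm: float = 7.0,
    pitch_mm: float = 10.0,
    mm_per_pixel: float = 0.2,
) -> SensorLayout:
    """3 replicate rows x 6 concentration columns of 7 mm wells.

    Column j of every row receives ``column_concs[j]``; column 0 must be the
    zero-dose control.
    """
    concs = [float(c) for c in column_concs]
    if len(concs) != 6:
        raise ValueError("grid3x6 requires exactly 6 column concentrations")
    if concs[0] != 0:
        raise ValueError("column 0 (control) concentration must be 0")
    centers, roles, well_concs, labels = [], [], [], []
    for i in range(3):
        for j in range(6):
            centers.append(((j - 2.5) * pitch_mm, (i - 1.0) * pitch_mm))
            roles.append(WellRole.CONTROL if j == 0 else WellRole.CALIBRATOR)
            well_concs.append(concs[j])
            labels.append(f"r{i}c{j}")
    half_extent = math.hypot(2.5 * pitch_mm, pitch_mm) + well_diameter_mm / 2
    return SensorLayout(
        kind="grid3x6",
        paper_diameter_mm=2 * half_extent + 4.0,
        well_centers_mm=tuple(centers),
        well_diameter_mm=well_diameter_mm,
        roles=tuple(roles),
        concentrations=tuple(well_concs),
        unit=unit,
        mm_per_pixel=mm_per_pixel,
        labels=tuple(labels),
    )
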