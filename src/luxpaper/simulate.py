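"""Synthetic renderer for bioluminescent paper-sensor photographs.

Stands in for photographing a live sensor in the dark box: each well is a
uniform disc of photon flux (photons/s per pixel, proportional to the
bacteria's light output), the scene is blurred by the camera point-spread,
shot noise is Poisson in detected photons, the sensor applies an affine
gain plus Gaussian read noise and a dark baseline, and the result is
clipped and quantised at the camera bit depth.  Every image ships with a
ground-truth record so downstream stages can be tested against known
fluxes and concentrations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .camera import CameraModel
from .inhibition import InhibitionModel, simulate_inhibition
from .layout import SensorLayout, flower7_layout

__all__ = [
    "SceneTruth",
    "render_sensor_image",
    "make_assay_fixture",
    "write_truth",
    "read_truth",
    "CONTROL_FLUX",
]

# Photon flux of an untreated control well, photons/s per pixel.  Chosen so
# a 30 s exposure at the default gain puts the control at ~15 % of the
# 16-bit full scale — bright enough for SNR >> 5, far from saturation.
CONTROL_FLUX = 40.0

# Stray-light background inside the dark box, photons/s per pixel.
BACKGROUND_FLUX = 0.2

# Blue-green tint of A. fischeri emission for optional RGB output (R, G, B).
EMISSION_TINT = (0.12, 0.78, 1.0)


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for one rendered sensor image."""

    well_flux: tuple[float, ...]  # photons/s per pixel, one per well
    background_flux: float = BACKGROUND_FLUX
    inhibition: InhibitionModel | None = None
    sample_conc: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.well_flux):
            raise ValueError("photon fluxes must be >= 0")
        if self.background_flux < 0:
            raise ValueError("background flux must be >= 0")

    def to_dict(self) -> dict:
        return {
            "well_flux": list(self.well_flux),
            "background_flux": self.background_flux,
            "inhibition": None if self.inhibition is None else self.inhibition.to_dict(),
            "sample_conc": self.sample_conc,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneTruth":
        return cls(
            well_flux=tuple(float(f) for f in d["well_flux"]),
            background_flux=float(d["background_flux"]),
            inhibition=(
                None if d.get("inhibition") is None
                else InhibitionModel.from_dict(d["inhibition"])
            ),
            sample_conc=(None if d.get("sample_conc") is None else float(d["sample_conc"])),
            seed=int(d.get("seed", 0)),
        )


def _disc_coverage(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Antialiased disc mask: per-pixel coverage in [0, 1].

    Linear ramp over one pixel at the rim approximates the area a disc edge
    covers in a pixel; exact area integration is not needed at these radii.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(xx - center[0], yy - center[1])
    return np.clip(radius + 0.5 - dist, 0.0, 1.0)


def render_sensor_image(
    layout: SensorLayout,
    truth: SceneTruth,
    camera: CameraModel,
    seed: int | None = None,
    rgb: bool = False,
):
    """Render one photograph of the sensor; returns ``(image, record)``.

    The expected pixel value inside a well is
    ``baseline_offset + gain * flux * exposure`` (before PSF blur); noise is
    Poisson shot noise on photons plus Gaussian read noise in ADU.  The same
    ``(layout, truth, camera, seed)`` renders bit-identically.  Wells whose
    expected level exceeds saturation are flagged in the record.
    """
    if len(truth.well_flux) != layout.n_wells:
        raise ValueError(
            f"truth has {len(truth.well_flux)} wells, layout has {layout.n_wells}"
        )
    if seed is None:
        seed = truth.seed
    shape = layout.image_shape()
    centers = layout.well_centers_px(shape)
    radius = layout.well_radius_px

    rate = np.full(shape, truth.background_flux, dtype=float)
    saturated = []
    for (x, y), flux in zip(centers, truth.well_flux):
        rate += flux * _disc_coverage(shape, (x, y), radius)
        expected_adu = (
            camera.baseline_offset_adu
            + camera.gain_adu_per_photon * (flux + truth.background_flux) * camera.exposure_s
        )
        saturated.append(bool(expected_adu > camera.saturation_adu))

    photons = rate * camera.exposure_s
    if camera.psf_sigma_px > 0:
        photons = gaussian_filter(photons, camera.psf_sigma_px, mode="nearest")

    rng = np.random.default_rng(seed)
    if camera.shot_noise:
        photons = rng.poisson(photons).astype(float)
    adu = camera.gain_adu_per_photon * photons + camera.baseline_offset_adu
    if camera.read_noise_adu > 0:
        adu = adu + rng.normal(0.0, camera.read_noise_adu, size=adu.shape)

    adu = np.clip(np.rint(adu), 0, camera.saturation_adu)
    dtype = np.uint8 if camera.bit_depth == 8 else np.uint16
    img = adu.astype(dtype)
    if rgb:
        img = np.stack(
            [np.clip(np.rint(adu * t), 0, camera.saturation_adu).astype(dtype)
             for t in EMISSION_TINT],
            axis=-1,
        )

    record = {
        "layout": layout.to_dict(),
        "truth": truth.to_dict(),
        "camera": camera.to_dict(),
        "seed": int(seed),
        "well_saturated": saturated,
        "well_labels": list(layout.labels),
    }
    return img, record


def make_assay_fixture(
    analyte_name: str,
    calibrator_concs,
    sample_conc: float,
    model: InhibitionModel,
    camera: CameraModel,
    seed: int,
    cv: float = 0.0,
    unit: str = "ppm",
    orientation_deg: float = 0.0,
    control_flux: float = CONTROL_FLUX,
    rgb: bool = False,
):
    """End-to-end flower-sensor fixture: spiked sample plus on-board calibrators.

    Calibrator fluxes follow the inhibition model exactly; ``cv`` adds
    multiplicative per-well variability (biological replicate scatter) on top
    of camera noise.  Returns ``(image, layout, record)`` where the record
    stores the true sample concentration for recovery testing.
    """
    concs = [float(c) for c in calibrator_concs]
    if len(concs) != 6 or concs[0] != 0:
        raise ValueError("need 6 calibrator concentrations starting at 0")
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise ValueError("calibrator concentrations must be strictly increasing")
    if sample_conc < 0:
        raise ValueError("sample concentration must be >= 0")

    layout = flower7_layout(concs, unit=unit, orientation_deg=orientation_deg)
    activities = simulate_inhibition(concs, model) + [float(model.activity(sample_conc))]
    fluxes = np.array([control_flux * a / 100.0 for a in activities])
    rng = np.random.default_rng(seed)
    if cv > 0:
        fluxes = fluxes * np.clip(rng.normal(1.0, cv, size=fluxes.shape), 0.0, None)
    truth = SceneTruth(
        well_flux=tuple(float(f) for f in fluxes),
        inhibition=model,
        sample_conc=float(sample_conc),
        seed=int(seed),
    )
    # decorrelate render noise from the flux jitter
    img, record = render_sensor_image(layout, truth, camera, seed=seed + 1, rgb=rgb)
    record["analyte"] = analyte_name
    record["cv"] = cv
    return img, layout, record


def write_truth(record: dict, path) -> None:
    Path(path).write_text(json.dumps(record, indent=2))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())
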