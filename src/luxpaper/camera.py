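"""Smartphone camera models for low-light acquisition of the paper sensor.

The sensor is photographed inside a dark box, so the imaging chain is the
plain photon-transfer model of a CMOS sensor: photons accumulated over the
exposure, a Gaussian point-spread, Poisson shot noise, affine gain to ADU,
Gaussian read noise, a dark baseline offset and clipping at full scale.
No demosaicing or tone mapping is modelled — bioluminescence quantification
only needs a scalar intensity per pixel.

Presets approximate the handsets used for sensor read-out at their reported
integration times (ISO 1600 unless the phone exposes only a "night mode").
Gains are set so the untreated control well lands at a comparable fraction
of full scale on every phone; absolute ADU levels differ by design, which is
exactly what the on-board calibration must cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["CameraModel", "CAMERA_PRESETS", "get_camera"]


@dataclass(frozen=True)
class CameraModel:
    """Exposure and noise parameters of one acquisition configuration.

    ``gain_adu_per_photon`` folds quantum efficiency and ISO amplification
    into a single ADU-per-detected-photon factor.  ``shot_noise=False``
    disables Poisson sampling for analytic tests.
    """

    name: str
    exposure_s: float
    iso: int
    gain_adu_per_photon: float
    read_noise_adu: float
    bit_depth: int = 16
    psf_sigma_px: float = 1.2
    baseline_offset_adu: float = 400.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.exposure_s <= 0:
            raise ValueError("exposure_s must be positive")
        if self.gain_adu_per_photon <= 0:
            raise ValueError("gain must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.read_noise_adu < 0:
            raise ValueError("read noise must be >= 0")

    @property
    def saturation_adu(self) -> int:
        return 2 ** self.bit_depth - 1

    def with_(self, **kw) -> "CameraModel":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "exposure_s": self.exposure_s,
            "iso": self.iso,
            "gain_adu_per_photon": self.gain_adu_per_photon,
            "read_noise_adu": self.read_noise_adu,
            "bit_depth": self.bit_depth,
            "psf_sigma_px": self.psf_sigma_px,
            "baseline_offset_adu": self.baseline_offset_adu,
            "shot_noise": self.shot_noise,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(**d)


CAMERA_PRESETS: dict[str, CameraModel] = {
    "oneplus6": CameraModel(
        name="oneplus6", exposure_s=30.0, iso=1600,
        gain_adu_per_photon=8.0, read_noise_adu=4.0,
        baseline_offset_adu=400.0,
    ),
    "motorola_edge40neo": CameraModel(
        name="motorola_edge40neo", exposure_s=16.0, iso=1600,
        gain_adu_per_photon=15.0, read_noise_adu=5.0,
        baseline_offset_adu=380.0,
    ),
    "samsung_galaxy_s20": CameraModel(
        name="samsung_galaxy_s20", exposure_s=30.0, iso=1600,
        gain_adu_per_photon=7.0, read_noise_adu=3.5,
        baseline_offset_adu=420.0,
    ),
    "huawei_p10": CameraModel(
        name="huawei_p10", exposure_s=8.0, iso=1600,
        gain_adu_per_photon=28.0, read_noise_adu=6.0,
        baseline_offset_adu=350.0,
    ),
    "iphone12mini": CameraModel(
        name="iphone12mini", exposure_s=10.0, iso=2000,
        gain_adu_per_photon=24.0, read_noise_adu=3.0,
        baseline_offset_adu=300.0,
    ),
    "iphone13mini": CameraModel(
        name="iphone13mini", exposure_s=20.0, iso=2000,
        gain_adu_per_photon=12.0, read_noise_adu=3.0,
        baseline_offset_adu=300.0,
    ),
}

DEFAULT_CAMERA = "oneplus6"


def get_camera(name: str) -> CameraModel:
    """Look up a camera preset by name."""
    try:
        return CAMERA_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown camera preset {name!r}; available: {sorted(CAMERA_PRESETS)}"
        ) from None
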