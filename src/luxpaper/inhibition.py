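"""Four-parameter logistic (4PL) inhibition model.

Acute toxicants suppress the light output of *Aliivibrio fischeri* in a
dose-dependent way.  The residual bioluminescent activity (signal as a
percentage of the untreated control) is modelled with the standard
symmetric four-parameter logistic on log-concentration:

    activity(c) = bottom + (top - bottom) / (1 + (c / ec50) ** hill)

with ``top`` the uninhibited plateau (100 % by convention), ``bottom``
the fully-inhibited plateau, ``ec50`` the midpoint concentration and
``hill`` the slope.  With ``hill > 0`` the curve is strictly decreasing
in concentration and evaluates exactly to ``top`` at zero dose, so the
blank needs no special-casing.  The symmetric form inverts in closed
form, which the calibration stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["InhibitionModel", "simulate_inhibition", "invert_inhibition"]


@dataclass(frozen=True)
class InhibitionModel:
    """Dose-response parameters of a toxicant acting on the reporter.

    Parameters
    ----------
    top : float
        Residual activity (%) at zero dose.  100 by convention.
    bottom : float
        Residual activity (%) at saturating dose.  Must be < ``top``.
    ec50 : float
        Concentration producing half-maximal inhibition, in the assay's
        concentration unit (ppm or ppb).
    hill : float
        Hill slope; > 0 (the curve decreases with dose).
    """

    top: float = 100.0
    bottom: float = 0.0
    ec50: float = 1.0
    hill: float = 1.5

    def __post_init__(self) -> None:
        if not self.top > self.bottom:
            raise ValueError(f"top ({self.top}) must exceed bottom ({self.bottom})")
        if self.bottom < 0:
            raise ValueError("bottom must be >= 0")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.hill <= 0:
            raise ValueError("hill slope must be positive")

    def activity(self, conc):
        """Residual activity (%) at concentration(s) ``conc``."""
        c = np.asarray(conc, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        out = self.bottom + (self.top - self.bottom) / (1.0 + (c / self.ec50) ** self.hill)
        return out if out.ndim else float(out)

    def inverse(self, activity):
        """Concentration at residual activity ``activity`` (closed form).

        Defined on the open interval ``bottom < activity < top``.
        """
        y = float(activity)
        if not (self.bottom < y < self.top):
            raise ValueError(
                f"activity {y} outside open interval ({self.bottom}, {self.top})"
            )
        return self.ec50 * ((self.top - y) / (y - self.bottom)) ** (1.0 / self.hill)

    def to_dict(self) -> dict:
        return {
            "top": self.top,
            "bottom": self.bottom,
            "ec50": self.ec50,
            "hill": self.hill,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InhibitionModel":
        return cls(**{k: float(d[k]) for k in ("top", "bottom", "ec50", "hill")})


def simulate_inhibition(concentrations, model: InhibitionModel):
    """Residual activities (%) for a list of concentrations.

    Zero dose returns ``model.top``; values decrease strictly with dose
    towards ``model.bottom``.
    """
    return [float(model.activity(c)) for c in np.asarray(concentrations, dtype=float)]


def invert_inhibition(activity: float, model: InhibitionModel) -> float:
    """Concentration producing ``activity`` % residual signal."""
    return model.inverse(activity)
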