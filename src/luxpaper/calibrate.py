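"""On-board dose-response calibration, LOD/LOQ and inverse prediction.

The six calibrator wells give residual activities at known concentrations;
a four-parameter logistic is least-squares fitted to them (deterministic
initialization), the blank statistics define the limits of detection and
quantification in signal space,

    LOD_signal = mean(blank) - 3 * SD(blank)
    LOQ_signal = mean(blank) - 10 * SD(blank)

(the blank is the uninhibited control, so detectability is a *decrease*),
and both the limits and the unknown sample are mapped to concentration by
the closed-form inverse of the fitted logistic.  Confidence intervals come
from a seeded parametric bootstrap of the calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .inhibition import InhibitionModel

__all__ = [
    "CalibrationCurve",
    "SampleResult",
    "NoDoseResponseError",
    "BelowDetectionError",
    "AboveRangeError",
    "fit_dose_response",
    "compute_lod_loq",
    "lod_loq_from_stats",
    "invert_curve",
    "analyze_sample",
    "recovery_percent",
]


class NoDoseResponseError(RuntimeError):
    """Signals do not decrease with dose: no usable calibration."""


class BelowDetectionError(ValueError):
    """Signal at or above the uninhibited plateau: concentration below detection."""


class AboveRangeError(ValueError):
    """Signal at or below the inhibited plateau: concentration above the range."""


@dataclass
class CalibrationCurve:
    """Fitted dose-response calibration plus blank-derived limits.

    Signals are whatever space the fit was done in (the pipeline uses
    residual activity, % of control); blank statistics may additionally be
    stored in raw RLU by the caller.
    """

    model: InhibitionModel
    r_squared: float
    conc: np.ndarray
    signal: np.ndarray
    residuals: np.ndarray
    residual_sd: float
    working_range: tuple[float, float]
    unit: str = "ppm"
    blank_mean: float | None = None
    blank_sd: float | None = None
    lod_signal: float | None = None
    loq_signal: float | None = None
    lod_conc: float | None = None
    loq_conc: float | None = None
    flags: list = field(default_factory=list)

    def predict(self, conc):
        return self.model.activity(conc)

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "r_squared": self.r_squared,
            "conc": list(map(float, self.conc)),
            "signal": list(map(float, self.signal)),
            "residuals": list(map(float, self.residuals)),
            "residual_sd": self.residual_sd,
            "working_range": list(self.working_range),
            "unit": self.unit,
            "blank_mean": self.blank_mean,
            "blank_sd": self.blank_sd,
            "lod_signal": self.lod_signal,
            "loq_signal": self.loq_signal,
            "lod_conc": self.lod_conc,
            "loq_conc": self.loq_conc,
            "flags": list(self.flags),
        }


@dataclass
class SampleResult:
    """Interpolated concentration of the unknown sample and its verdict."""

    concentration: float | None
    ci_95: tuple[float, float] | None
    status: str  # "Toxic" | "Safe"
    residual_activity_pct: float
    decision_threshold: float
    display: str
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "concentration": self.concentration,
            "ci_95": None if self.ci_95 is None else list(self.ci_95),
            "status": self.status,
            "residual_activity_pct": self.residual_activity_pct,
            "decision_threshold": self.decision_threshold,
            "display": self.display,
            "flags": list(self.flags),
        }


def _fit_4pl(conc: np.ndarray, signal: np.ndarray) -> InhibitionModel:
    """Deterministic 4PL least squares (trust-region, fixed initialization)."""

    def f(c, top, bottom, ec50, hill):
        return bottom + (top - bottom) / (1.0 + (c / ec50) ** hill)

    nz = conc[conc > 0]
    p0 = [
        float(signal.max()),
        max(float(signal.min()), 0.0),
        float(np.exp(np.mean(np.log(nz)))),
        1.0,
    ]
    lo = [0.0, 0.0, nz.min() / 100.0, 0.05]
    hi = [2.0 * signal.max(), float(signal.max()), nz.max() * 100.0, 10.0]
    p0 = np.clip(p0, lo, hi)
    popt, _ = optimize.curve_fit(
        f, conc, signal, p0=p0, bounds=(lo, hi), maxfev=20000
    )
    top, bottom, ec50, hill = map(float, popt)
    if not top > bottom:  # degenerate plateau ordering
        raise NoDoseResponseError("fitted curve has no decreasing span")
    return InhibitionModel(top=top, bottom=bottom, ec50=ec50, hill=hill)


def fit_dose_response(conc, signal, unit: str = "ppm") -> CalibrationCurve:
    """Fit the calibration curve to (concentration, signal) points.

    Requires at least four distinct concentrations including the zero-dose
    blank.  Signals that do not decrease with dose (Spearman rho > -0.5) or
    are flat are rejected as "no dose-response".
    """
    conc = np.asarray(conc, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if conc.shape != signal.shape:
        raise ValueError("conc and signal must have equal length")
    distinct = np.unique(conc)
    if len(distinct) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if 0.0 not in distinct:
        raise ValueError("calibration must include the zero-dose blank")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    if float(np.std(signal)) < 1e-12 * max(1.0, abs(float(np.mean(signal)))):
        raise NoDoseResponseError("flat signals: no dose-response")
    rho = stats.spearmanr(conc, signal).statistic
    if not (rho <= -0.5):
        raise NoDoseResponseError(
            f"signals do not decrease with dose (Spearman rho = {rho:.2f})"
        )

    model = _fit_4pl(conc, signal)
    fitted = model.activity(conc)
    resid = signal - fitted
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((signal - signal.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    dof = max(len(conc) - 4, 1)
    nz = conc[conc > 0]
    return CalibrationCurve(
        model=model,
        r_squared=r2,
        conc=conc,
        signal=signal,
        residuals=resid,
        residual_sd=math.sqrt(ss_res / dof),
        working_range=(float(nz.min()), float(nz.max())),
        unit=unit,
    )


def invert_curve(curve: CalibrationCurve | InhibitionModel, signal: float) -> float:
    """Closed-form inverse of the calibration at a signal value.

    Only defined strictly between the plateaus: signals at/above ``top`` are
    below detection, at/below ``bottom`` above the calibrated range.
    """
    model = curve.model if isinstance(curve, CalibrationCurve) else curve
    y = float(signal)
    if y >= model.top:
        raise BelowDetectionError(f"signal {y:.3g} >= top plateau {model.top:.3g}")
    if y <= model.bottom:
        raise AboveRangeError(f"signal {y:.3g} <= bottom plateau {model.bottom:.3g}")
    return model.inverse(y)


def compute_lod_loq(blank_replicates, curve: CalibrationCurve):
    """Blank-based limits of detection and quantification.

    ``blank_replicates`` must be in the same signal space as the curve and
    contain at least three values.  Signal-space limits follow the
    mean-minus-k-SD definition (k = 3 for LOD, 10 for LOQ); concentration
    equivalents invert the fitted curve, or are reported as out-of-range
    (``None``) when a limit falls outside the curve's span rather than being
    extrapolated.  The curve is updated in place and returned values are
    ``(lod_signal, loq_signal, lod_conc, loq_conc)``.
    """
    blanks = np.asarray(blank_replicates, dtype=float)
    if blanks.size < 3:
        raise ValueError("need at least 3 blank replicates")
    return lod_loq_from_stats(float(blanks.mean()), float(blanks.std(ddof=1)), curve)


def lod_loq_from_stats(m: float, sd: float, curve: CalibrationCurve):
    """Limits from a blank mean and SD already estimated elsewhere
    (e.g. the standard error of the control ROI mean on a single image)."""
    lod_s = m - 3.0 * sd
    loq_s = m - 10.0 * sd

    def _conc(sig):
        try:
            c = invert_curve(curve, sig)
        except BelowDetectionError:
            curve.flags.append(f"signal limit {sig:.4g} above curve top: out of range")
            return None
        except AboveRangeError:
            curve.flags.append(f"signal limit {sig:.4g} below curve bottom: out of range")
            return None
        return c

    curve.blank_mean = m
    curve.blank_sd = sd
    curve.lod_signal = lod_s
    curve.loq_signal = loq_s
    curve.lod_conc = _conc(lod_s)
    curve.loq_conc = _conc(loq_s)
    return lod_s, loq_s, curve.lod_conc, curve.loq_conc


def _bootstrap_ci(
    curve: CalibrationCurve,
    sample_signal: float,
    rng: np.random.Generator,
    n_boot: int,
) -> tuple[float, float] | None:
    """Parametric bootstrap of calibration + sample noise through the inverse."""
    sd = max(curve.residual_sd, 1e-9)
    fitted = curve.model.activity(curve.conc)
    ests = []
    for _ in range(n_boot):
        sig = fitted + rng.normal(0.0, sd, size=fitted.shape)
        try:
            m = _fit_4pl(curve.conc, sig)
            y = sample_signal + rng.normal(0.0, sd)
            if not (m.bottom < y < m.top):
                continue
            ests.append(m.inverse(y))
        except (RuntimeError, ValueError):
            continue
    if len(ests) < max(20, n_boot // 10):
        return None
    lo, hi = np.percentile(ests, [2.5, 97.5])
    return (float(lo), float(hi))


def analyze_sample(
    sample_quant,
    curve: CalibrationCurve,
    decision_threshold: float | None = None,
    seed: int = 0,
    n_boot: int = 500,
    labels: tuple[str, str] = ("Toxic", "Safe"),
) -> SampleResult:
    """Interpolate the sample concentration and classify the water sample.

    ``sample_quant`` is the sample's :class:`~luxpaper.quantify.WellQuant`
    (or any object with ``residual_activity_pct`` and ``saturated_fraction``).
    The default decision threshold is the concentration producing 20 %
    inhibition on the fitted curve; samples at or above it are labelled
    Toxic.  Signals above the blank (stimulation/hormesis) and signals above
    the LOD threshold are reported as "< LOD" with a Safe verdict.
    """
    toxic_label, safe_label = labels
    y = float(sample_quant.residual_activity_pct)
    flags: list[str] = []
    if getattr(sample_quant, "saturated_fraction", 0.0) > 0:
        flags.append("saturated")
    if getattr(sample_quant, "clamped", False):
        flags.append("signal clamped at zero")

    model = curve.model
    if decision_threshold is None:
        y20 = model.top - 0.20 * (model.top - model.bottom)
        decision_threshold = model.inverse(y20)

    # stimulation: sample brighter than blank beyond noise
    if curve.blank_sd is not None and curve.blank_mean is not None:
        if y > curve.blank_mean + 3.0 * curve.blank_sd:
            flags.append("stimulation (signal above control): hormesis suspected")
            return SampleResult(
                concentration=None, ci_95=None, status=safe_label,
                residual_activity_pct=y, decision_threshold=decision_threshold,
                display="< LOD", flags=flags,
            )

    lod_s = curve.lod_signal if curve.lod_signal is not None else model.top
    if y >= min(lod_s, model.top):
        flags.append("below LOD")
        return SampleResult(
            concentration=None, ci_95=None, status=safe_label,
            residual_activity_pct=y, decision_threshold=decision_threshold,
            display="< LOD", flags=flags,
        )
    if y <= model.bottom:
        flags.append("above calibrated range")
        return SampleResult(
            concentration=None, ci_95=None, status=toxic_label,
            residual_activity_pct=y, decision_threshold=decision_threshold,
            display=f"> {curve.working_range[1]:.4g} {curve.unit}", flags=flags,
        )

    conc = model.inverse(y)
    if conc > curve.working_range[1]:
        flags.append("above calibrated range (extrapolated)")
    rng = np.random.default_rng(seed)
    ci = _bootstrap_ci(curve, y, rng, n_boot) if n_boot > 0 else None
    status = toxic_label if conc >= decision_threshold else safe_label
    return SampleResult(
        concentration=float(conc),
        ci_95=ci,
        status=status,
        residual_activity_pct=y,
        decision_threshold=float(decision_threshold),
        display=f"{conc:.4g} {curve.unit}",
        flags=flags,
    )


def recovery_percent(measured: float, spiked: float) -> float:
    """Recovery of a spiked sample: 100 * measured / spiked."""
    if spiked <= 0:
        raise ValueError("spiked concentration must be positive")
    return 100.0 * float(measured) / float(spiked)
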