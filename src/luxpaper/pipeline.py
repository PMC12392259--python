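"""End-to-end analysis of one sensor photograph.

Chains detection -> confidence filter -> NMS -> role assignment -> RLU
extraction -> control normalization -> calibration fit -> LOD/LOQ ->
inverse prediction -> Toxic/Safe verdict, and packages everything into a
JSON-serializable report.
"""

from __future__ import annotations

import hashlib
import json
import time

import numpy as np

from . import __version__
from .calibrate import (
    NoDoseResponseError,
    analyze_sample,
    fit_dose_response,
    lod_loq_from_stats,
)
from .detect import (
    DetectorParams,
    RoleAssignmentError,
    assign_roles,
    detect_candidates,
    filter_by_confidence,
    non_maximum_suppression,
)
from .layout import SensorLayout, WellRole
from .quantify import AssayInvalidError, extract_rlu, normalize_to_control

__all__ = ["AnalysisError", "analyze_image"]


class AnalysisError(RuntimeError):
    """Pipeline failure with a machine-readable error code."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def analyze_image(
    image: np.ndarray,
    layout: SensorLayout,
    detector_params: DetectorParams | None = None,
    orientation_deg: float | None = None,
    decision_threshold: float | None = None,
    seed: int = 0,
    n_boot: int = 500,
    config: dict | None = None,
) -> dict:
    """Run the full pipeline on a flower-sensor image; returns the report.

    Raises :class:`AnalysisError` with codes ``no_wells_detected``,
    ``missing_wells``, ``control_failure``, ``no_dose_response`` or
    ``roi_error`` on assay-invalid conditions.
    """
    t0 = time.perf_counter()
    params = detector_params or DetectorParams()
    if layout.kind != "flower7":
        raise AnalysisError("bad_layout", "end-to-end analysis requires a flower7 layout")

    candidates = detect_candidates(image, params)
    confident = filter_by_confidence(candidates, params.probability_threshold)
    detections = non_maximum_suppression(confident, params.nms_overlap_threshold)
    if not detections:
        raise AnalysisError("no_wells_detected", "no wells detected in the image")

    if orientation_deg is None:
        orientation_deg = layout.orientation_deg
    orientation_deg_eff = orientation_deg
    try:
        assignment = assign_roles(
            detections, layout, orientation_deg=orientation_deg_eff, image=image
        )
    except RoleAssignmentError as e:
        raise AnalysisError("missing_wells", str(e)) from e

    all_dets = list(assignment.mapping.values())
    quants = []
    try:
        for label, det in assignment.mapping.items():
            quants.append(
                extract_rlu(image, det, label=label, role=assignment.roles[label],
                            others=all_dets)
            )
    except ValueError as e:
        raise AnalysisError("roi_error", str(e)) from e

    try:
        quants = normalize_to_control(quants)
    except AssayInvalidError as e:
        raise AnalysisError("control_failure", str(e)) from e

    cal = sorted(
        (q for q in quants if q.role is not WellRole.SAMPLE), key=lambda q: q.label
    )
    conc = [layout.concentrations[layout.index_of(q.label)] for q in cal]
    sig = [q.residual_activity_pct for q in cal]
    try:
        curve = fit_dose_response(conc, sig, unit=layout.unit)
    except (NoDoseResponseError, ValueError) as e:
        raise AnalysisError("no_dose_response", str(e)) from e

    # Single-image blank statistics: control mean and its standard error.
    control = next(q for q in quants if q.role is WellRole.CONTROL)
    sem_raw = control.pixel_sd / np.sqrt(control.n_pixels)
    sem_pct = 100.0 * sem_raw / control.rlu
    lod_loq_from_stats(100.0, sem_pct, curve)

    sample = next(q for q in quants if q.role is WellRole.SAMPLE)
    result = analyze_sample(
        sample, curve, decision_threshold=decision_threshold,
        seed=seed, n_boot=n_boot,
    )

    warnings = list(curve.flags) + list(result.flags)
    for q in quants:
        if q.saturated_fraction > 0:
            warnings.append(f"well {q.label}: {q.saturated_fraction:.0%} saturated pixels")

    report = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config or {}),
        "config": config or {},
        "layout": layout.to_dict(),
        "detections": [d.to_dict() for d in detections],
        "registration_residual_px": assignment.residual_px,
        "wells": [q.to_dict() for q in quants],
        "calibration": curve.to_dict(),
        "blank_raw": {"mean_rlu": control.rlu, "sem_rlu": float(sem_raw),
                      "lod_signal_rlu": control.rlu - 3 * sem_raw,
                      "loq_signal_rlu": control.rlu - 10 * sem_raw},
        "sample": result.to_dict(),
        "status": result.status,
        "warnings": warnings,
        "elapsed_s": time.perf_counter() - t0,
    }
    return report
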