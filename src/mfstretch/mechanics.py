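"""Engineering stress-strain analysis of one stretching experiment.

Given a calibrated cantilever (``k_p``), the measured aggregate geometry
(``R0``, ``L0``) and a deflection trace ``x(t)``, the aggregate is under

    sigma = F / (pi R0^2) = k_p x / (pi R0^2),
    eps   = dL / L0,       dL = x_s - x  (x_s = v t when not tracked),

using the engineering (initial-geometry) convention throughout.  The Young's
modulus is the slope of a line fitted to the first 10-30 points of the
stress-strain curve, the ultimate tensile strength is the maximum stress
sustained, and quality-control rules flag jumps, rotation, vertical drift,
slip (which discards the UTS but keeps E) and rupture at onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .calibration import CantileverCalibration
from .exceptions import InsufficientDataError, InvalidParameterError
from .tracking import GeometryMeasurement, TrackResult

__all__ = [
    "StretchRecording",
    "StressStrainCurve",
    "MechanicalProperties",
    "stress_strain",
    "propagate_errors",
    "fit_young_modulus",
    "ultimate_tensile_strength",
    "qc_validate",
    "analyze_recording",
    "double_stretch_analysis",
    "DoubleStretchResult",
]

#: QC flags that invalidate the modulus; "slip" only discards the UTS.
INVALIDATING_FLAGS = frozenset({"jump", "rotation", "no_stretch", "vertical_drift"})


@dataclass
class StretchRecording:
    """One experiment: calibration + geometry + deflection trace."""

    calibration: CantileverCalibration
    geometry: GeometryMeasurement
    trace: object                     # TrackResult or SimulatedTrace
    v: float = 20e-6                  # motor speed, m s^-1
    label: str = ""

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise InvalidParameterError("motor speed must be > 0")


@dataclass
class StressStrainCurve:
    eps: np.ndarray
    sigma: np.ndarray
    eps_err: np.ndarray
    sigma_err: np.ndarray
    frame_index: np.ndarray
    flags: set = field(default_factory=set)


@dataclass
class MechanicalProperties:
    E: float | None
    E_err: float | None
    fit_window: tuple[int, int] | None
    sigma_uts: float | None
    qc_flags: set
    valid: bool
    label: str = ""


def stress_strain(rec: StretchRecording) -> StressStrainCurve:
    """Engineering stress and strain per frame, with propagated errors."""
    if rec.calibration.k_p_mean <= 0:
        raise InvalidParameterError("calibration mean must be positive")
    if rec.geometry.R0_mean <= 0 or rec.geometry.L0_mean <= 0:
        raise InvalidParameterError("geometry means must be positive")
    t = np.asarray(rec.trace.t, dtype=float)
    x = np.asarray(rec.trace.x, dtype=float)
    x_s = getattr(rec.trace, "x_s", None)
    if x_s is None:
        x_s = rec.v * t
    else:
        x_s = np.asarray(x_s, dtype=float)

    area = math.pi * rec.geometry.R0_mean**2
    force = rec.calibration.k_p_mean * x
    sigma = force / area
    dL = x_s - x
    eps = dL / rec.geometry.L0_mean

    flags: set = set()
    if np.any(dL < -1e-3 * rec.geometry.L0_mean):
        flags.add("compressed")

    curve = StressStrainCurve(
        eps=eps,
        sigma=sigma,
        eps_err=np.zeros_like(eps),
        sigma_err=np.zeros_like(sigma),
        frame_index=np.arange(t.size),
        flags=flags,
    )
    return propagate_errors(curve, rec.calibration, rec.geometry)


def propagate_errors(
    curve: StressStrainCurve,
    calibration: CantileverCalibration,
    geometry: GeometryMeasurement,
) -> StressStrainCurve:
    """First-order error propagation from the SDs of k_p, R0 and L0.

    sigma_err/sigma = sqrt((sd_kp/kp)^2 + (2 sd_R0/R0)^2) and
    eps_err/eps = sd_L0/L0; the deflection measurement noise is excluded,
    matching the study's error bars which propagate only k_p, R0 and L0.
    """
    rel_sigma = math.sqrt(
        (calibration.k_p_sd / calibration.k_p_mean) ** 2
        + (2.0 * geometry.R0_sd / geometry.R0_mean) ** 2
    )
    rel_eps = geometry.L0_sd / geometry.L0_mean
    curve.sigma_err = np.abs(curve.sigma) * rel_sigma
    curve.eps_err = np.abs(curve.eps) * rel_eps
    return curve


def fit_young_modulus(
    curve: StressStrainCurve,
    window_policy: str = "max_r2",
    fixed_window: int = 20,
    w_min: int = 10,
    w_max: int = 30,
) -> tuple[float, float, tuple[int, int]]:
    """Young's modulus: OLS slope of stress on strain over the first points.

    ``max_r2`` (default) scans window lengths ``w_min..w_max`` and keeps the
    one maximising R^2, ties resolved towards the largest window; ``fixed``
    always uses ``fixed_window`` points.  An intercept is fitted but not
    reported.  Returns (E, standard error of E, (first, last) index).
    """
    n = curve.eps.size
    if n < w_min:
        raise InsufficientDataError(
            f"need at least {w_min} points for the modulus fit, have {n}"
        )
    if window_policy == "fixed":
        windows = [min(fixed_window, n)]
    elif window_policy == "max_r2":
        windows = list(range(w_min, min(w_max, n) + 1))
    else:
        raise InvalidParameterError(f"unknown window policy {window_policy!r}")

    results = []
    for w in windows:
        fit = stats.linregress(curve.eps[:w], curve.sigma[:w])
        results.append((w, fit.rvalue**2, fit.slope, fit.stderr))
    best_r2 = max(r2 for _, r2, _, _ in results)
    w, _, slope, stderr = max(
        (r for r in results if r[1] >= best_r2 - 1e-12), key=lambda r: r[0]
    )
    return float(slope), float(stderr), (0, w - 1)


def ultimate_tensile_strength(
    curve: StressStrainCurve, qc_flags: frozenset | set = frozenset()
) -> float | None:
    """Maximum engineering stress; withheld entirely when slip was annotated."""
    if curve.sigma.size == 0:
        raise InsufficientDataError("empty curve")
    if "slip" in qc_flags:
        return None
    return float(curve.sigma.max())


def qc_validate(
    rec: StretchRecording,
    curve: StressStrainCurve,
    annotations: tuple[str, ...] = (),
    jump_factor: float = 10.0,
    eps_min: float = 0.02,
    drift_threshold_px: float = 3.0,
) -> set:
    """Exclusion rules: stress jumps, rupture at onset, drift, annotations.

    A jump is a frame-to-frame stress step exceeding ``jump_factor`` times
    the median step over the loading portion of the curve (up to the stress
    maximum); the post-peak failure cascade is expected rupture physics, not
    a suction artifact, and is not screened.  ``no_stretch`` marks rupture
    before ``eps_min`` strain.  Rotation and slip are operator-supplied
    annotations.  Vertical drift comes from the tracking metric when
    available.
    """
    flags = set(a for a in annotations if a in {"rotation", "slip"})
    peak = int(np.argmax(curve.sigma)) if curve.sigma.size else 0
    d = np.abs(np.diff(curve.sigma[: peak + 1]))
    if d.size:
        med = float(np.median(d))
        if med <= 0:
            med = float(d.mean())
        if med > 0 and float(d.max()) > jump_factor * med:
            flags.add("jump")
    ruptured_at = getattr(rec.trace, "ruptured_at", None)
    if ruptured_at is not None:
        idx = min(int(ruptured_at), curve.eps.size - 1)
        if curve.eps[idx] < eps_min:
            flags.add("no_stretch")
    drift = getattr(rec.trace, "vertical_drift_px", 0.0)
    if drift > drift_threshold_px:
        flags.add("vertical_drift")
    return flags


def analyze_recording(
    rec: StretchRecording,
    annotations: tuple[str, ...] = (),
    window_policy: str = "max_r2",
) -> MechanicalProperties:
    """Full per-experiment pipeline: curve -> QC -> modulus fit -> UTS.

    QC-invalid experiments still produce a row (valid=False, E withheld)
    rather than disappearing from the output.
    """
    curve = stress_strain(rec)
    flags = qc_validate(rec, curve, annotations=annotations)
    valid = not (flags & INVALIDATING_FLAGS)
    E = E_err = None
    window = None
    if valid:
        try:
            E, E_err, window = fit_young_modulus(curve, window_policy=window_policy)
        except InsufficientDataError:
            valid = False
            flags.add("no_stretch")
    uts = ultimate_tensile_strength(curve, flags) if curve.sigma.size else None
    return MechanicalProperties(
        E=E, E_err=E_err, fit_window=window, sigma_uts=uts if valid else None,
        qc_flags=flags, valid=valid, label=rec.label,
    )


@dataclass(frozen=True)
class DoubleStretchResult:
    E1: float
    E2: float
    ratio: float
    eps1_max: float


def double_stretch_analysis(
    rec1: StretchRecording, rec2: StretchRecording
) -> DoubleStretchResult:
    """Moduli of two successive stretches of the same aggregate.

    Fits E independently on both recordings and reports the softening ratio
    E2/E1 together with the maximum strain reached during the pre-stretch.
    """
    curve1 = stress_strain(rec1)
    curve2 = stress_strain(rec2)
    E1, _, _ = fit_young_modulus(curve1)
    E2, _, _ = fit_young_modulus(curve2)
    return DoubleStretchResult(
        E1=E1, E2=E2, ratio=E2 / E1, eps1_max=float(curve1.eps.max())
    )
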