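"""Deflection tracking and aggregate geometry from frame stacks.

Replaces the study's in-house image analysis: the L-shaped sensor tip is
followed by normalized cross-correlation of a frame-0 template with
parabolic sub-pixel peak refinement, and the initial aggregate geometry
(R0, L0) is measured from the first frame with repeat-based uncertainties
(five samples across different positions of the cluster).

Coordinate convention: pixel (0, 0) is the image top-left, columns increase
rightward along the stretch axis.  All outputs are converted to metres via
the stack's pixel size at the module boundary.  The stretch pulls the sensor
tip leftward, and the reported deflection is positive in that direction;
vertical tip motion is reported as a drift metric, not subtracted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template
from skimage.filters import threshold_otsu

from .aggregate_sim import FrameStack
from .exceptions import NoAggregateError, TrackingError

__all__ = ["TrackResult", "GeometryMeasurement", "track_tip", "measure_geometry"]


@dataclass
class TrackResult:
    """Tip trajectory: per-frame position (px), deflection (m) and NCC quality."""

    t: np.ndarray
    tip_x: np.ndarray        # px, sub-pixel column of the tracked tip
    tip_y: np.ndarray        # px
    x: np.ndarray            # m, deflection relative to frame 0 (leftward > 0)
    quality: np.ndarray      # peak NCC per frame, in [0, 1]
    vertical_drift_px: float = 0.0


@dataclass
class GeometryMeasurement:
    """Initial aggregate geometry with repeat statistics (all metres)."""

    R0_mean: float
    R0_sd: float
    L0_mean: float
    L0_sd: float
    n_repeats: int = 5
    V: float = 0.0
    V_tot: float | None = None

    def __post_init__(self) -> None:
        if self.R0_mean <= 0 or self.L0_mean <= 0:
            raise NoAggregateError("geometry means must be positive")
        if self.R0_sd < 0 or self.L0_sd < 0 or self.n_repeats < 1:
            raise NoAggregateError("invalid geometry uncertainty")
        if self.V == 0.0:
            self.V = math.pi * self.R0_mean**2 * self.L0_mean
        if self.V_tot is not None and self.V > self.V_tot:
            raise NoAggregateError("V must not exceed V_tot")


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2.0 * c0 + cp1
    if abs(denom) < 1e-12:
        return 0.0
    off = 0.5 * (cm1 - cp1) / denom
    return float(np.clip(off, -0.5, 0.5))


def track_tip(
    frames: FrameStack,
    roi: tuple[int, int, int, int],
    search_pad: tuple[int, int, int] = (8, 160, 16),
    quality_threshold: float = 0.5,
    max_bad_fraction: float = 0.05,
) -> TrackResult:
    """Track the sensor tip by template NCC with sub-pixel refinement.

    ``roi = (row0, row1, col0, col1)`` must contain the tip in frame 0; the
    template cut there is correlated against a search window padded by
    ``search_pad = (vertical, left, right)`` pixels (the tip moves left under
    load).  The correlation peak is refined by parabolic interpolation in
    both axes.  Frames whose peak correlation falls below
    ``quality_threshold`` count as failures; more than ``max_bad_fraction``
    of them raises :class:`TrackingError` naming the first bad frame.
    """
    stack = frames.frames
    if stack.shape[0] < 2:
        raise TrackingError("need at least two frames")
    H, W = stack.shape[1:]
    r0, r1, c0, c1 = roi
    template = stack[0, r0:r1, c0:c1].astype(float)
    if template.size == 0:
        raise TrackingError("empty tracking ROI")

    pad_v, pad_l, pad_r = search_pad
    sr0, sr1 = max(0, r0 - pad_v), min(H, r1 + pad_v)
    sc0, sc1 = max(0, c0 - pad_l), min(W, c1 + pad_r)

    n = stack.shape[0]
    tip_x = np.empty(n)
    tip_y = np.empty(n)
    quality = np.empty(n)
    th, tw = template.shape

    for k in range(n):
        window = stack[k, sr0:sr1, sc0:sc1].astype(float)
        corr = match_template(window, template)
        iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
        dy = dx = 0.0
        if 0 < iy < corr.shape[0] - 1:
            dy = _parabolic_offset(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix])
        if 0 < ix < corr.shape[1] - 1:
            dx = _parabolic_offset(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1])
        tip_y[k] = sr0 + iy + dy + th / 2.0
        tip_x[k] = sc0 + ix + dx + tw / 2.0
        quality[k] = float(corr[iy, ix])

    bad = np.where(quality < quality_threshold)[0]
    if bad.size > max_bad_fraction * n:
        raise TrackingError(
            f"tracking quality below {quality_threshold} in {bad.size}/{n} frames "
            f"(first bad frame: {int(bad[0])})"
        )

    deflection = (tip_x[0] - tip_x) * frames.pixel_size  # leftward positive
    drift = float(np.abs(tip_y - tip_y[0]).max())
    return TrackResult(
        t=frames.timestamps.copy(),
        tip_x=tip_x,
        tip_y=tip_y,
        x=deflection,
        quality=quality,
        vertical_drift_px=drift,
    )


def _pipette_band(dark: np.ndarray) -> tuple[float, float]:
    """Centre row and half-thickness of the straight pipette at the left edge."""
    rows = np.where(dark[:, :4].any(axis=1))[0]
    if rows.size == 0:
        raise NoAggregateError("no straight pipette found at the left image edge")
    return float(rows.mean()), float(rows.size / 2.0)


def measure_geometry(
    frame0: np.ndarray,
    pixel_size: float,
    n_repeats: int = 5,
    seed: int = 0,
    V_tot: float | None = None,
) -> GeometryMeasurement:
    """Measure R0 and L0 from the first frame with repeat statistics.

    The frame is binarised (Otsu).  The aggregate is the only silhouette
    extending below the pipette axis, so the span of columns that are dark in
    the band below the straight pipette gives the gap between the two pipette
    openings, i.e. L0.  The silhouette height, sampled at ``n_repeats``
    axial stations across the cluster, gives R0 with an honest SD; L0 is
    re-detected ``n_repeats`` times with jittered binarisation thresholds.
    """
    img = np.asarray(frame0, dtype=float)
    base_thr = threshold_otsu(img)
    rng = np.random.default_rng(seed)

    def span_at(thr: float) -> tuple[int, int]:
        dark = img < thr
        cy, half = _pipette_band(dark)
        band0 = int(cy + half + 3)
        band = dark[band0:, :]
        cols = np.where(band.sum(axis=0) >= 3)[0]
        if cols.size == 0:
            raise NoAggregateError("aggregate silhouette segmentation is empty")
        return int(cols[0]), int(cols[-1])

    jitters = [0.0] + [float(rng.uniform(-0.08, 0.08)) for _ in range(n_repeats - 1)]
    spans = [span_at(base_thr * (1.0 + j)) for j in jitters]
    lengths = np.array([(right - left + 1) for left, right in spans], dtype=float)
    L0_mean = float(lengths.mean()) * pixel_size
    L0_sd = float(lengths.std(ddof=1)) * pixel_size if len(lengths) > 1 else 0.0

    left, right = spans[0]
    dark = img < base_thr
    stations = np.linspace(0.2, 0.8, n_repeats)
    radii = []
    for s in stations:
        col = int(round(left + s * (right - left)))
        height = float(dark[:, col].sum())
        radii.append(height / 2.0)
    radii = np.asarray(radii) * pixel_size
    R0_mean = float(radii.mean())
    R0_sd = float(radii.std(ddof=1)) if radii.size > 1 else 0.0
    if R0_mean <= 0:
        raise NoAggregateError("aggregate silhouette segmentation is empty")

    return GeometryMeasurement(
        R0_mean=R0_mean,
        R0_sd=R0_sd,
        L0_mean=L0_mean,
        L0_sd=L0_sd,
        n_repeats=n_repeats,
        V_tot=V_tot,
    )
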