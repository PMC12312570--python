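"""Synthetic stretching experiments: simulator, frame renderer, group generator.

Stands in for the wet-lab side of the pipeline.  Three layers:

* :func:`simulate_stretch` couples a Hookean cantilever (spring constant
  ``k_p``) quasi-statically to a ductile spring-network aggregate.  The motor
  pulls the straight pipette at ``x_s(t)`` (1 mm s^-2 acceleration ramp, then
  20 um s^-1); at every frame the deflection ``x`` balances ``k_p x =
  F_agg(x_s - x)``, with network bonds transitioning elastic -> yielded
  (stiffness x 0.1) -> broken at their per-bond strain thresholds.

* :func:`render_frames` draws microscopy-like frames: dark silhouettes of a
  straight pipette, an L-shaped sensor pipette and a textured cylindrical
  aggregate on a bright background, with sub-pixel object placement, blur
  and pixel noise, so the tracking module can be exercised end to end.

* :func:`generate_group_dataset` emulates the study's group structure:
  per-mouse log-normal baseline moduli (pooled mean ~= 248 Pa, SD ~= 234 Pa
  for the reference condition), condition ratios 2.8 (+W-7) and 0.30
  (anti-CD3), and within-mouse multiplicative measurement noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter, map_coordinates

from .exceptions import (
    InvalidConfigurationError,
    InvalidParameterError,
)
from .springmodel import (
    BROKEN,
    ELASTIC,
    YIELDED,
    CellModel,
    SpringNetwork,
    build_lattice_aggregate,
    solve_axial,
)

__all__ = [
    "ExperimentConfig",
    "CylinderGeometry",
    "SimulatedTrace",
    "GroundTruth",
    "FrameStack",
    "motor_position",
    "simulate_stretch",
    "simulate_experiment",
    "soften_network",
    "simulate_double_stretch",
    "render_frames",
    "default_tip_roi",
    "generate_group_dataset",
    "DEFAULT_GROUP_RATIOS",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Motor, cantilever, camera and noise settings for one experiment.

    Defaults follow the study's acquisition: motor speed 20 um s^-1 with a
    1 mm s^-2 acceleration ramp (lasting 20 ms, under one frame), 30 frames
    per second, and a cantilever in the calibrated 10-40 nN um^-1 range.
    """

    v: float = 20e-6                 # motor speed, m s^-1
    accel: float = 1e-3              # motor acceleration, m s^-2
    k_p: float = 20e-3               # cantilever spring constant, N m^-1
    frame_rate: float = 30.0         # s^-1
    pixel_size: float = 0.5e-6       # m per pixel
    noise_sd: float = 2e-8           # deflection measurement noise, m
    seed: int = 0
    t_max: float = 6.0               # s, hard stop if the aggregate never ruptures
    accel_phase: bool = True
    # rendering
    image_shape: tuple[int, int] = (256, 768)   # rows, cols
    background_level: float = 200.0
    foreground_level: float = 60.0
    texture_amplitude: float = 30.0
    blur_sigma: float = 1.0
    pixel_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.v <= 0 or self.accel <= 0 or self.k_p <= 0:
            raise InvalidParameterError("v, accel and k_p must be > 0")
        if self.frame_rate <= 0 or self.pixel_size <= 0:
            raise InvalidParameterError("frame_rate and pixel_size must be > 0")
        if self.noise_sd < 0 or self.t_max <= 0:
            raise InvalidParameterError("noise_sd >= 0 and t_max > 0 required")


@dataclass(frozen=True)
class CylinderGeometry:
    """Nominal aggregate geometry, m."""

    R0: float
    L0: float

    @property
    def volume(self) -> float:
        return math.pi * self.R0**2 * self.L0

    @property
    def cross_section(self) -> float:
        return math.pi * self.R0**2


@dataclass
class SimulatedTrace:
    """Per-frame kinematics of one simulated stretch."""

    t: np.ndarray          # s
    x_s: np.ndarray        # motor (straight pipette) position, m
    x: np.ndarray          # reported cantilever deflection (noise applied), m
    F: np.ndarray          # aggregate tension (noise-free), N
    ruptured_at: int | None = None
    x_true: np.ndarray | None = None  # noise-free deflection


@dataclass
class GroundTruth:
    """Recovery targets recorded by the simulator."""

    E_true: float          # Pa, from the pristine network
    sigma_uts_true: float  # Pa, realised peak engineering stress
    cell: CellModel
    R0: float
    L0: float
    k_eff0: float          # N m^-1, pristine network stiffness


@dataclass
class FrameStack:
    """A grayscale image sequence with physical pixel size and timestamps."""

    frames: np.ndarray       # (T, H, W) uint8
    pixel_size: float        # m
    timestamps: np.ndarray   # s

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be > 0")
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InvalidParameterError("frames must be a (T, H, W) array")

    def save(self, path: str | Path) -> None:
        """Write a multi-page TIFF plus a JSON sidecar with metadata."""
        path = Path(path)
        tifffile.imwrite(path, self.frames)
        meta = {"pixel_size_m": self.pixel_size, "timestamps_s": self.timestamps.tolist()}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "FrameStack":
        path = Path(path)
        frames = tifffile.imread(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            frames=frames,
            pixel_size=float(meta["pixel_size_m"]),
            timestamps=np.asarray(meta["timestamps_s"], dtype=float),
        )


def motor_position(t: np.ndarray | float, cfg: ExperimentConfig) -> np.ndarray:
    """Trapezoidal motor profile: acceleration ramp then constant speed."""
    t = np.asarray(t, dtype=float)
    if not cfg.accel_phase:
        return cfg.v * t
    t_a = cfg.v / cfg.accel
    ramp = 0.5 * cfg.accel * np.minimum(t, t_a) ** 2
    cruise = cfg.v * np.clip(t - t_a, 0.0, None)
    return ramp + cruise


def _solve_deflection(k_p: float, k_net: float, x_s: float, tol: float = 1e-15) -> float:
    """Bisection root of ``k_p x - F_agg(x_s - x)`` on ``x in [0, x_s]``.

    With frozen bond states the aggregate tension is linear in its extension,
    so the root coincides with the series coupling ``x = K x_s / (k_p + K)``;
    bisection is kept as the general root finder.
    """
    if x_s <= 0.0 or k_net <= 0.0:
        return 0.0
    lo, hi = 0.0, x_s

    def g(x: float) -> float:
        return k_p * x - k_net * (x_s - x)

    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if g(mid) <= 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(x_s, 1e-12):
            break
    return 0.5 * (lo + hi)


def simulate_stretch(
    net: SpringNetwork,
    cfg: ExperimentConfig,
    geometry: CylinderGeometry | None = None,
) -> tuple[SimulatedTrace, GroundTruth]:
    """Quasi-static stretch of a spring-network aggregate by a Hookean cantilever.

    Per frame the motor position follows the trapezoidal profile; the
    deflection solves the force balance against the network tension at
    extension ``dL = x_s - x``; bonds whose tensile strain exceeds their
    thresholds transition (elastic -> yielded -> broken) and the balance is
    re-solved until the state is stationary.  The trace ends at boundary
    disconnection (full rupture) or at ``t_max``.
    """
    if geometry is None:
        if net.R0 is None or net.L0 is None:
            raise InvalidParameterError(
                "geometry must be given when the network has no nominal R0/L0"
            )
        geometry = CylinderGeometry(R0=net.R0, L0=net.L0)

    cell = CellModel(
        r_c=(net.bonds[0].rest_length / 2.0) if net.bonds else 1e-6,
        k_c=net.bonds[0].stiffness if net.bonds else 0.0,
    )
    rng = np.random.default_rng(cfg.seed)
    area = geometry.cross_section

    sol = solve_axial(net)
    k_eff0 = sol.k_eff
    truth = GroundTruth(
        E_true=k_eff0 * geometry.L0 / area,
        sigma_uts_true=0.0,
        cell=cell,
        R0=geometry.R0,
        L0=geometry.L0,
        k_eff0=k_eff0,
    )

    n_frames = int(math.floor(cfg.t_max * cfg.frame_rate)) + 1
    times = np.arange(n_frames) / cfg.frame_rate
    xs_all = motor_position(times, cfg)

    t_out, xs_out, x_out, f_out = [], [], [], []
    ruptured_at: int | None = None

    for k in range(n_frames):
        xs = float(xs_all[k])
        while True:
            if not sol.connected:
                x = 0.0
                dL = xs
                force = 0.0
                changed = False
                break
            x = _solve_deflection(cfg.k_p, sol.k_eff, xs)
            dL = xs - x
            force = sol.k_eff * dL
            strains = sol.bond_strain_unit * dL
            changed = False
            for b, s in zip(net.bonds, strains):
                if b.state == BROKEN:
                    continue
                if s >= b.rupture_strain:
                    b.state = BROKEN
                    changed = True
                elif b.state == ELASTIC and s >= b.yield_strain:
                    b.state = YIELDED
                    changed = True
            if not changed:
                break
            sol = solve_axial(net)
        t_out.append(times[k])
        xs_out.append(xs)
        x_out.append(x)
        f_out.append(force)
        if not sol.connected and ruptured_at is None:
            ruptured_at = k
            break

    x_true = np.asarray(x_out)
    x_reported = x_true.copy()
    if cfg.noise_sd > 0:
        x_reported = x_true + rng.normal(0.0, cfg.noise_sd, size=x_true.shape)
    trace = SimulatedTrace(
        t=np.asarray(t_out),
        x_s=np.asarray(xs_out),
        x=x_reported,
        F=np.asarray(f_out),
        ruptured_at=ruptured_at,
        x_true=x_true,
    )
    truth.sigma_uts_true = float(trace.F.max() / area) if trace.F.size else 0.0
    return trace, truth


def simulate_experiment(
    R0: float,
    L0: float,
    cell: CellModel,
    cfg: ExperimentConfig,
    threshold_cv: float = 0.2,
) -> tuple[SpringNetwork, SimulatedTrace, GroundTruth]:
    """Build a lattice aggregate (seeded threshold disorder) and stretch it."""
    rng = np.random.default_rng(cfg.seed)
    net = build_lattice_aggregate(R0, L0, cell, threshold_cv=threshold_cv, rng=rng)
    trace, truth = simulate_stretch(net, cfg)
    return net, trace, truth


def soften_network(net: SpringNetwork, factor: float) -> SpringNetwork:
    """Scale every bond stiffness by ``factor`` (relaxation between stretches)."""
    if factor <= 0:
        raise InvalidParameterError("softening factor must be > 0")
    for b in net.bonds:
        b.stiffness *= factor
    return net


def simulate_double_stretch(
    R0: float,
    L0: float,
    cell: CellModel,
    cfg: ExperimentConfig,
    eps1_max: float = 0.3,
    softening: float = 0.7,
    threshold_cv: float = 0.2,
) -> tuple[tuple[SimulatedTrace, GroundTruth], tuple[SimulatedTrace, GroundTruth]]:
    """Two successive stretches with inter-stretch softening.

    The first stretch stops once the aggregate strain reaches ``eps1_max``;
    the aggregate then returns to its initial configuration and is stretched
    again until rupture.  The relaxation during the wait is not modelled
    mechanistically — the pre-stretch history is subsumed into one softening
    factor applied to every cell spring.
    """
    import dataclasses

    rng = np.random.default_rng(cfg.seed)
    net1 = build_lattice_aggregate(R0, L0, cell, threshold_cv=threshold_cv, rng=rng)
    # stop stretch 1 around eps1_max (deflection makes x_s slightly larger)
    t_stop = eps1_max * L0 * 1.5 / cfg.v
    cfg1 = dataclasses.replace(cfg, t_max=min(cfg.t_max, t_stop))
    trace1, truth1 = simulate_stretch(net1, cfg1)

    cell2 = dataclasses.replace(cell, k_c=cell.k_c * softening)
    rng2 = np.random.default_rng(cfg.seed + 1)
    net2 = build_lattice_aggregate(R0, L0, cell2, threshold_cv=threshold_cv, rng=rng2)
    trace2, truth2 = simulate_stretch(net2, cfg)
    return (trace1, truth1), (trace2, truth2)


# ---------------------------------------------------------------------------
# Rendering

_PIPETTE_HALF_THICKNESS = 6.0   # px, straight pipette bar half-height
_L_BAR_HALF_WIDTH = 5.0         # px, L-pipette vertical bar half-width
_L_ARM_Y = 32.0                 # px, height of the horizontal arm of the L
_L_ARM_HALF_THICKNESS = 4.0     # px
_RIGHT_MARGIN = 64              # px, initial gap between sensor tip and edge


def _coverage(coords: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Per-pixel coverage of the interval [lo, hi] (linear anti-aliasing)."""
    return np.clip(np.minimum(coords + 0.5, hi) - np.maximum(coords - 0.5, lo), 0.0, 1.0)


def _paint_rect(img, ys, xs, y0, y1, x0, x1, value):
    cov = np.outer(_coverage(ys, y0, y1), _coverage(xs, x0, x1))
    np.multiply(img, 1.0 - cov, out=img)
    img += cov * value


def default_tip_roi(
    geometry: CylinderGeometry, cfg: ExperimentConfig
) -> tuple[int, int, int, int]:
    """Pixel rectangle (row0, row1, col0, col1) around the sensor-tip elbow."""
    H, W = cfg.image_shape
    xr0 = W - _RIGHT_MARGIN
    r0 = max(0, int(_L_ARM_Y) - 14)
    r1 = min(H, int(_L_ARM_Y) + 22)
    c0 = max(0, xr0 - 18)
    c1 = min(W, xr0 + 26)
    return (r0, r1, c0, c1)


def render_frames(
    trace: SimulatedTrace,
    geometry: CylinderGeometry,
    cfg: ExperimentConfig,
) -> FrameStack:
    """Render microscopy-like frames of the stretching experiment.

    Dark silhouettes on a bright background: the straight pipette enters from
    the left and translates with the motor, the L-shaped sensor pipette (a
    vertical cantilever with a horizontal arm, forming a trackable elbow)
    translates with the deflection, and the aggregate spans the gap as a
    textured cylinder whose drawn area is conserved as it elongates.
    """
    if trace.t.size == 0:
        raise InvalidParameterError("trace is empty")
    H, W = cfg.image_shape
    px = cfg.pixel_size
    R0px = geometry.R0 / px
    L0px = geometry.L0 / px
    cy = H / 2.0

    x_render = trace.x_true if trace.x_true is not None else trace.x
    xs_px = trace.x_s / px
    x_px = x_render / px

    xr0 = float(W - _RIGHT_MARGIN)
    xl0 = xr0 - L0px
    if xl0 - xs_px.max() < 8.0:
        raise InvalidConfigurationError(
            "field of view too small: straight pipette leaves the frame "
            f"(needs {xs_px.max() + L0px + _RIGHT_MARGIN + 8:.0f} px, have {W})"
        )
    if cy - R0px < _L_ARM_Y + 8 or 2 * R0px < 4:
        raise InvalidConfigurationError("field of view too small for the aggregate")

    rng = np.random.default_rng(cfg.seed + 7919)
    texture_grid = gaussian_filter(rng.standard_normal((48, 192)), sigma=2.0)
    texture_grid /= max(np.abs(texture_grid).max(), 1e-12)

    ys = np.arange(H, dtype=float)
    xs_coords = np.arange(W, dtype=float)

    frames = np.empty((trace.t.size, H, W), dtype=np.uint8)
    for k in range(trace.t.size):
        ruptured = trace.ruptured_at is not None and k >= trace.ruptured_at
        xl = xl0 - xs_px[k]
        xr = xr0 - x_px[k]
        img = np.full((H, W), cfg.background_level, dtype=float)

        if not ruptured:
            L = xr - xl
            Rpx = R0px * (L0px / L)
            y0, y1 = cy - Rpx, cy + Rpx
            # textured aggregate, sampled in material coordinates so the
            # speckle pattern stretches with the cylinder
            c0 = max(0, int(math.floor(xl)) - 1)
            c1 = min(W, int(math.ceil(xr)) + 2)
            r0 = max(0, int(math.floor(y0)) - 1)
            r1 = min(H, int(math.ceil(y1)) + 2)
            sub_y = ys[r0:r1]
            sub_x = xs_coords[c0:c1]
            u = np.clip((sub_x - xl) / L, 0.0, 1.0)
            v = np.clip((sub_y - y0) / (2 * Rpx), 0.0, 1.0)
            uu, vv = np.meshgrid(u, v)
            tex = map_coordinates(
                texture_grid,
                [vv.ravel() * (texture_grid.shape[0] - 1),
                 uu.ravel() * (texture_grid.shape[1] - 1)],
                order=1,
            ).reshape(vv.shape)
            value = cfg.foreground_level + cfg.texture_amplitude * tex
            cov = np.outer(_coverage(sub_y, y0, y1), _coverage(sub_x, xl, xr))
            region = img[r0:r1, c0:c1]
            region *= 1.0 - cov
            region += cov * value

        # straight pipette: horizontal bar from the left edge to its opening
        _paint_rect(img, ys, xs_coords,
                    cy - _PIPETTE_HALF_THICKNESS, cy + _PIPETTE_HALF_THICKNESS,
                    -1.0, xl, cfg.foreground_level)
        # L-shaped sensor: vertical cantilever from the arm down to the axis,
        # plus the horizontal arm to the right edge (elbow is the tracked tip)
        _paint_rect(img, ys, xs_coords,
                    _L_ARM_Y, cy,
                    xr, xr + 2 * _L_BAR_HALF_WIDTH, cfg.foreground_level)
        _paint_rect(img, ys, xs_coords,
                    _L_ARM_Y - _L_ARM_HALF_THICKNESS, _L_ARM_Y + _L_ARM_HALF_THICKNESS,
                    xr, float(W), cfg.foreground_level)

        if cfg.blur_sigma > 0:
            img = gaussian_filter(img, sigma=cfg.blur_sigma)
        if cfg.pixel_noise_sd > 0:
            img += rng.normal(0.0, cfg.pixel_noise_sd, size=img.shape)
        frames[k] = np.clip(img, 0.0, 255.0).astype(np.uint8)

    return FrameStack(frames=frames, pixel_size=px, timestamps=trace.t.copy())


# ---------------------------------------------------------------------------
# Group-level dataset generator

#: Condition ratios relative to the PMA+ionomycin reference.
DEFAULT_GROUP_RATIOS: dict[str, float] = {
    "PMA+I": 1.0,
    "PMA+I+W7": 2.8,
    "anti-CD3": 0.30,
}

REFERENCE_MEAN_PA = 248.0
REFERENCE_SD_PA = 234.0
#: Between-mouse spread of the log-modulus; the within-mouse spread is
#: derived from the pooled total so the reference condition keeps the
#: 248 +/- 234 Pa shape.
BETWEEN_MOUSE_LOG_SD = 0.45
AGGREGATES_PER_MOUSE = 10


def generate_group_dataset(
    group_specs: dict[str, float] | list[str] | None = None,
    n_per_group: int = 15,
    seed: int = 0,
    n_aggregates_per_mouse: int = AGGREGATES_PER_MOUSE,
    mean_pa: float = REFERENCE_MEAN_PA,
    sd_pa: float = REFERENCE_SD_PA,
    between_mouse_log_sd: float = BETWEEN_MOUSE_LOG_SD,
) -> pd.DataFrame:
    """Synthetic per-aggregate modulus table with same-mouse group structure.

    Every mouse is measured under every condition (the study emphasised
    same-mouse comparisons).  The reference condition's pooled moduli are
    log-normal with mean ``mean_pa`` and SD ``sd_pa``; condition moduli are
    the mouse baseline times the condition ratio times within-mouse
    multiplicative noise.  Independent null covariates (volume, aspirated
    fraction, time post-activation) are attached for covariate checks.
    Deterministic for a fixed seed.
    """
    if group_specs is None:
        groups = dict(DEFAULT_GROUP_RATIOS)
    elif isinstance(group_specs, dict):
        groups = dict(group_specs)
    else:
        unknown = [g for g in group_specs if g not in DEFAULT_GROUP_RATIOS]
        if unknown:
            raise InvalidParameterError(f"unknown group name(s): {unknown}")
        groups = {g: DEFAULT_GROUP_RATIOS[g] for g in group_specs}
    if n_per_group < 2:
        raise InvalidParameterError("need at least two mice per group")
    for name, ratio in groups.items():
        if ratio <= 0:
            raise InvalidParameterError(f"ratio for group {name!r} must be > 0")

    sigma_tot2 = math.log(1.0 + (sd_pa / mean_pa) ** 2)
    sigma_m = between_mouse_log_sd
    if sigma_m**2 >= sigma_tot2:
        raise InvalidParameterError("between-mouse spread exceeds the pooled total")
    sigma_w = math.sqrt(sigma_tot2 - sigma_m**2)
    mu = math.log(mean_pa) - sigma_tot2 / 2.0

    rng = np.random.default_rng(seed)
    mouse_effect = rng.normal(0.0, sigma_m, size=n_per_group)
    rows = []
    for name in sorted(groups):
        ratio = groups[name]
        for m in range(n_per_group):
            noise = rng.normal(0.0, sigma_w, size=n_aggregates_per_mouse)
            e = np.exp(mu + mouse_effect[m] + noise) * ratio
            vol = np.exp(rng.uniform(math.log(1e4), math.log(7e5),
                                     size=n_aggregates_per_mouse))
            vfrac = rng.uniform(0.5, 0.95, size=n_aggregates_per_mouse)
            hours = rng.uniform(1.0, 12.0, size=n_aggregates_per_mouse)
            for i in range(n_aggregates_per_mouse):
                rows.append(
                    {
                        "group": name,
                        "mouse_id": f"m{m + 1:02d}",
                        "E_Pa": float(e[i]),
                        "V_um3": float(vol[i]),
                        "V_over_Vtot": float(vfrac[i]),
                        "hours_post_activation": float(hours[i]),
                    }
                )
    return pd.DataFrame(rows)
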