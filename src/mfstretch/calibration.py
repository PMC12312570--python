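"""Water-droplet calibration of the micropipette force sensor.

The L-shaped cantilever is calibrated by resting water droplets of known
size on its tip: the droplet silhouette is modelled as a spheroid (vertical
semi-axis ``b`` along gravity, horizontal semi-axis ``a``), its weight is
``W = rho g V`` with ``V = (4/3) pi a b^2``, and Hooke's law gives the
spring constant ``k_p = W / delta_x`` from the measured static deflection.
Repeating with droplets of different sizes yields a mean and SD for ``k_p``.
Cantilevers used for aggregate stretching fall in the 10-40 nN um^-1 range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError, InvalidParameterError

WATER_DENSITY = 1000.0  # kg m^-3
STANDARD_GRAVITY = 9.81  # m s^-2

__all__ = [
    "DropletObservation",
    "CantileverCalibration",
    "droplet_volume",
    "estimate_spring_constant",
    "synthetic_droplet_observations",
]


@dataclass(frozen=True)
class DropletObservation:
    """One droplet resting on the cantilever: semi-axes and deflection, all m."""

    a: float
    b: float
    delta_x: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.delta_x <= 0:
            raise InvalidParameterError("droplet semi-axes and deflection must be > 0")


@dataclass(frozen=True)
class CantileverCalibration:
    """Calibrated cantilever spring constant with repeat statistics."""

    k_p_mean: float
    k_p_sd: float
    n_obs: int
    rho: float = WATER_DENSITY
    g: float = STANDARD_GRAVITY
    low_replication: bool = False

    def __post_init__(self) -> None:
        if self.k_p_mean <= 0 or self.k_p_sd < 0 or self.n_obs < 1:
            raise InvalidParameterError("invalid calibration summary")


def droplet_volume(a: float, b: float) -> float:
    """Spheroid volume ``(4/3) pi a b^2`` (b is the vertical semi-axis), m^3."""
    if a <= 0 or b <= 0:
        raise InvalidParameterError("semi-axes must be > 0")
    return (4.0 / 3.0) * math.pi * a * b * b


def estimate_spring_constant(
    observations: list[DropletObservation],
    rho: float = WATER_DENSITY,
    g: float = STANDARD_GRAVITY,
) -> CantileverCalibration:
    """Per-droplet ``k_i = rho g V_i / delta_x_i``, summarised as mean and sample SD."""
    if not observations:
        raise InvalidInputError("need at least one droplet observation")
    k = np.array(
        [rho * g * droplet_volume(o.a, o.b) / o.delta_x for o in observations]
    )
    sd = float(k.std(ddof=1)) if k.size > 1 else 0.0
    return CantileverCalibration(
        k_p_mean=float(k.mean()),
        k_p_sd=sd,
        n_obs=k.size,
        rho=rho,
        g=g,
        low_replication=k.size == 1,
    )


def synthetic_droplet_observations(
    k_p_true: float,
    n: int = 10,
    axis_noise: float = 0.0,
    seed: int | np.random.Generator = 0,
    radius_range: tuple[float, float] = (3e-4, 7e-4),
    rho: float = WATER_DENSITY,
    g: float = STANDARD_GRAVITY,
) -> list[DropletObservation]:
    """Generate droplet observations consistent with a known spring constant.

    True axes are drawn over ``radius_range`` (slightly oblate, b <= a, as a
    resting drop flattens under gravity), the deflection follows exactly from
    ``k_p_true``, and relative Gaussian noise ``axis_noise`` is then applied
    to the *reported* axes, emulating image-measurement error.
    """
    if k_p_true <= 0:
        raise InvalidParameterError("k_p_true must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = radius_range
    obs = []
    for _ in range(n):
        a = float(rng.uniform(lo, hi))
        b = a * float(rng.uniform(0.85, 1.0))
        delta_x = rho * g * droplet_volume(a, b) / k_p_true
        am = a * (1.0 + axis_noise * float(rng.standard_normal()))
        bm = b * (1.0 + axis_noise * float(rng.standard_normal()))
        obs.append(DropletObservation(a=am, b=bm, delta_x=delta_x))
    return obs
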