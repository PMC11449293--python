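"""Two-dimensional Gaussian diffusion field of a photoreleased agonist.

A brief laser flash uncages ADP inside a circular spot with a Gaussian
intensity profile.  Because the uncaging is effectively instantaneous and the
sample is a thin liquid layer, the subsequent agonist concentration is the
free diffusion of a 2-D Gaussian peak:

    C(r, t) = ADP0 * t0 / (t + t0) * exp(-r^2 / (4 D (t + t0)))

where ``ADP0`` is the initial released concentration at the spot center,
``D`` the agonist diffusion coefficient, ``r`` the distance from the spot
center and ``t0`` a characteristic time chosen so that the profile width at
t = 0 matches the laser-beam width.  At fixed r > sqrt(4 D t0) the
concentration first rises (agonist diffusing outward) and then decays; a
cell at that radius sees a single concentration maximum

    C_peak(r) = ADP0 * t0 * 4 D / (e * r^2)      at  t* = r^2/(4 D) - t0,

which bounds whether a given activation threshold can ever be crossed.

Units throughout: lengths in micrometers, times in seconds, concentrations
in molar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import lambertw

__all__ = [
    "DEFAULT_ADP0",
    "DEFAULT_D",
    "DEFAULT_BEAM_DIAMETER",
    "DiffusionParams",
    "t0_from_beam",
    "adp_at",
    "peak_concentration",
    "peak_time",
    "crossing_time",
    "crossing_times",
    "plane_integral",
]

#: Initial released ADP concentration (M), measured by HPLC for the
#: reference experiment.
DEFAULT_ADP0 = 1.5e-5
#: ADP diffusion coefficient in aqueous buffer (um^2/s).
DEFAULT_D = 257.0
#: Observable laser-spot size (um), read as the 1/e-intensity diameter.
DEFAULT_BEAM_DIAMETER = 80.0

#: Absolute tolerance (s) of the bisection search in :func:`crossing_time`.
CROSSING_XTOL = 1e-6


def t0_from_beam(beam_diameter: float, D: float) -> float:
    """Characteristic time t0 matching the t = 0 profile to the beam width.

    The Gaussian ``exp(-r^2 / (4 D t0))`` has 1/e-diameter
    ``2 * sqrt(4 D t0)``; equating it to ``beam_diameter`` gives
    ``t0 = (beam_diameter / 2)^2 / (4 D)``.

    Parameters
    ----------
    beam_diameter : float
        1/e-intensity diameter of the laser spot (um).
    D : float
        Diffusion coefficient (um^2/s).
    """
    if beam_diameter <= 0:
        raise ValueError(f"beam_diameter must be positive, got {beam_diameter}")
    if D <= 0:
        raise ValueError(f"D must be positive, got {D}")
    return (beam_diameter / 2.0) ** 2 / (4.0 * D)


@dataclass(frozen=True)
class DiffusionParams:
    """Constants of the point-source agonist field.

    Attributes
    ----------
    adp0 : float
        Initial released concentration at the spot center (M).
    D : float
        Diffusion coefficient (um^2/s).
    t0 : float
        Characteristic time (s); see :func:`t0_from_beam`.
    center : tuple of float
        (x, y) position of the spot center (um).
    """

    adp0: float = DEFAULT_ADP0
    D: float = DEFAULT_D
    t0: float = t0_from_beam(DEFAULT_BEAM_DIAMETER, DEFAULT_D)
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.adp0 <= 0:
            raise ValueError(f"adp0 must be positive, got {self.adp0}")
        if self.D <= 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if self.t0 <= 0:
            raise ValueError(f"t0 must be positive, got {self.t0}")

    @classmethod
    def from_beam(
        cls,
        adp0: float = DEFAULT_ADP0,
        D: float = DEFAULT_D,
        beam_diameter: float = DEFAULT_BEAM_DIAMETER,
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "DiffusionParams":
        """Build parameters from a beam diameter instead of t0."""
        return cls(adp0=adp0, D=D, t0=t0_from_beam(beam_diameter, D), center=center)

    def radius_from(self, x, y):
        """Euclidean distance (um) of point(s) from the spot center."""
        return np.hypot(np.asarray(x) - self.center[0], np.asarray(y) - self.center[1])


def adp_at(params: DiffusionParams, r, t):
    """Agonist concentration (M) at distance ``r`` (um), time ``t`` (s).

    Vectorized over ``r`` and ``t`` with numpy broadcasting.
    """
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative (time since the flash)")
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    tau = t + params.t0
    out = params.adp0 * params.t0 / tau * np.exp(-(r**2) / (4.0 * params.D * tau))
    return out if out.ndim else float(out)


def peak_time(params: DiffusionParams, r):
    """Time (s) at which the concentration at radius ``r`` is maximal.

    Zero for r <= sqrt(4 D t0) (the concentration there only decays),
    r^2/(4 D) - t0 beyond.
    """
    a = np.asarray(r, dtype=float) ** 2 / (4.0 * params.D)
    out = np.maximum(a - params.t0, 0.0)
    return out if out.ndim else float(out)


def peak_concentration(params: DiffusionParams, r):
    """Maximum over time of the concentration (M) at radius ``r``.

    Closed form: for r^2 <= 4 D t0 the profile at r is monotone decreasing
    in t, so the maximum is the initial value; beyond, the maximum
    ADP0 * t0 * 4 D / (e r^2) is attained at t* = r^2/(4 D) - t0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    a = r**2 / (4.0 * params.D)
    initial = params.adp0 * np.exp(-np.divide(a, params.t0))
    with np.errstate(divide="ignore"):
        late = params.adp0 * params.t0 / (np.e * np.where(a > 0, a, np.inf))
    out = np.where(a <= params.t0, initial, late)
    return out if out.ndim else float(out)


def crossing_time(
    params: DiffusionParams, r: float, threshold: float
) -> Optional[float]:
    """First time t >= 0 with ``adp_at(r, t) >= threshold``, or None.

    Returns 0.0 if the cell is already above threshold at t = 0, None if
    the peak concentration at r never reaches the threshold, and otherwise
    the crossing on the rising branch of the concentration transient,
    located by bracketing and bisection (absolute tolerance 1e-6 s).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if r < 0:
        raise ValueError(f"r must be non-negative, got {r}")
    if adp_at(params, r, 0.0) >= threshold:
        return 0.0
    if peak_concentration(params, r) < threshold:
        return None
    t_peak = peak_time(params, r)
    # rising branch: concentration is strictly increasing on [0, t_peak]
    return float(
        brentq(
            lambda t: adp_at(params, r, t) - threshold,
            0.0,
            t_peak,
            xtol=CROSSING_XTOL,
        )
    )


def crossing_times(params: DiffusionParams, r, thresholds) -> np.ndarray:
    """Vectorized threshold-crossing times; NaN where the peak never suffices.

    Closed form used for whole populations: writing a = r^2/(4 D) and
    v = a/(t + t0), the crossing condition becomes v e^{-v} = c with
    c = threshold * a / (ADP0 * t0); the rising branch is the v > 1 root,
    v = -W_{-1}(-c) (secondary real branch of the Lambert W function).
    Agrees with :func:`crossing_time` to its bisection tolerance.
    """
    r = np.asarray(r, dtype=float)
    thr = np.asarray(thresholds, dtype=float)
    if np.any(thr <= 0):
        raise ValueError("thresholds must be positive")
    r, thr = np.broadcast_arrays(r, thr)
    a = r**2 / (4.0 * params.D)

    out = np.full(r.shape, np.nan)
    instant = params.adp0 * np.exp(-a / params.t0) >= thr
    out[instant] = 0.0
    reachable = (peak_concentration(params, r) >= thr) & ~instant
    if np.any(reachable):
        c = thr[reachable] * a[reachable] / (params.adp0 * params.t0)
        v = -lambertw(-np.minimum(c, 1.0 / np.e), k=-1).real
        out[reachable] = a[reachable] / v - params.t0
    return out


def plane_integral(params: DiffusionParams) -> float:
    """Exact 2-D plane integral of the field (M um^2), constant in time.

    Integrating the Gaussian profile over the plane gives
    4 pi D t0 ADP0 — the conserved total amount of released agonist per
    unit sample depth.
    """
    return 4.0 * math.pi * params.D * params.t0 * params.adp0
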