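"""Platelet agent population: thresholds, activation times, annulus binning.

Computational nodes representing platelets (or small ensembles of platelets)
are scattered uniformly over a field of view.  Each node i carries an ADP
sensitivity threshold TR_i drawn from a log-normal distribution
LogN(mu, sigma^2); it activates at the first time TA_i when the local
agonist concentration exceeds TR_i, and emits its first calcium spike at
TS_i = TA_i + TD_i with a log-normally distributed delay TD_i.

Cells whose local concentration never reaches their threshold carry NaN
activation/spike times; aggregations account for them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .diffusion import DiffusionParams, crossing_times

__all__ = [
    "ThresholdDistribution",
    "DelayDistribution",
    "Population",
    "ActivationResult",
    "AnnulusScheme",
    "lognormal_stats",
    "square_fov",
    "sample_population",
    "compute_activation",
    "add_spike_delays",
    "assign_areas",
    "SpikeHistograms",
    "spike_time_histograms",
    "fraction_activated",
]


@dataclass(frozen=True)
class ThresholdDistribution:
    """Log-normal ADP activation-threshold distribution.

    ``mu`` and ``sigma`` are the location and scale of ln(TR) with TR in
    molar; e.g. mu = -14.5 puts the population median at
    exp(-14.5) ~ 5e-7 M.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))

    @property
    def mode(self) -> float:
        return float(np.exp(self.mu - self.sigma**2))

    @property
    def mean(self) -> float:
        return float(np.exp(self.mu + self.sigma**2 / 2.0))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.exp(self.mu + self.sigma * rng.standard_normal(n))

    def cdf(self, x) -> np.ndarray:
        """P(TR <= x); fraction of the population with threshold below x."""
        x = np.asarray(x, dtype=float)
        out = np.zeros(x.shape)
        pos = x > 0
        out[pos] = norm.cdf((np.log(x[pos]) - self.mu) / self.sigma)
        return out if out.ndim else float(out)

    def from_standard_normal(self, z) -> np.ndarray:
        """Map standard-normal draws to thresholds (common random numbers)."""
        return np.exp(self.mu + self.sigma * np.asarray(z, dtype=float))


@dataclass(frozen=True)
class DelayDistribution:
    """Log-normal activation-to-first-spike delay TD (seconds)."""

    mu_d: float
    sigma_d: float

    def __post_init__(self) -> None:
        if self.sigma_d < 0:
            raise ValueError(f"sigma_d must be non-negative, got {self.sigma_d}")

    @property
    def median(self) -> float:
        return float(np.exp(self.mu_d))

    @property
    def mean(self) -> float:
        return float(np.exp(self.mu_d + self.sigma_d**2 / 2.0))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sigma_d == 0:
            return np.full(n, np.exp(self.mu_d))
        return np.exp(self.mu_d + self.sigma_d * rng.standard_normal(n))


def lognormal_stats(dist: ThresholdDistribution) -> dict[str, float]:
    """Closed-form median, mode and mean of a log-normal threshold law.

    median = exp(mu); mode = exp(mu - sigma^2); mean = exp(mu + sigma^2/2).
    """
    return {"median": dist.median, "mode": dist.mode, "mean": dist.mean}


@dataclass(frozen=True)
class Population:
    """Immobile point-like platelet agents with per-cell thresholds."""

    x: np.ndarray
    y: np.ndarray
    tr: np.ndarray
    seed: Optional[int] = None

    @property
    def n(self) -> int:
        return self.x.size

    def __post_init__(self) -> None:
        if not (self.x.shape == self.y.shape == self.tr.shape):
            raise ValueError("x, y and tr must have identical shapes")
        if np.any(self.tr <= 0):
            raise ValueError("all thresholds must be positive")


@dataclass(frozen=True)
class ActivationResult:
    """Per-cell activation time TA and first-spike time TS (seconds).

    NaN encodes a cell that never activates; a NaN TA always propagates to
    a NaN TS.  ``ts`` is None until delays have been added.
    """

    ta: np.ndarray
    ts: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.ts is not None:
            if self.ts.shape != self.ta.shape:
                raise ValueError("ta and ts must have identical shapes")
            both = ~np.isnan(self.ta) & ~np.isnan(self.ts)
            if np.any(self.ts[both] < self.ta[both]):
                raise ValueError("ts must be >= ta wherever both are defined")
            if np.any(np.isnan(self.ta) & ~np.isnan(self.ts)):
                raise ValueError("a never-activated cell cannot have a spike time")

    @property
    def activated(self) -> np.ndarray:
        return ~np.isnan(self.ta)

    @property
    def n_activated(self) -> int:
        return int(np.count_nonzero(self.activated))


def square_fov(
    half_side: float, center: tuple[float, float] = (0.0, 0.0)
) -> tuple[float, float, float, float]:
    """(xmin, xmax, ymin, ymax) of a square field of view (um)."""
    cx, cy = center
    return (cx - half_side, cx + half_side, cy - half_side, cy + half_side)


def _rng_streams(seed, n: int) -> list[np.random.Generator]:
    """Independent child generators (positions / thresholds / delays ...)."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def sample_population(
    n: int,
    fov: tuple[float, float, float, float],
    dist: ThresholdDistribution,
    seed,
) -> Population:
    """Scatter ``n`` cells uniformly over ``fov`` with log-normal thresholds.

    Positions and thresholds come from separate named RNG streams spawned
    from ``seed``, so re-running either component alone is reproducible.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    xmin, xmax, ymin, ymax = fov
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate field of view {fov}")
    rng_pos, rng_thr = _rng_streams(seed, 2)
    x = rng_pos.uniform(xmin, xmax, n)
    y = rng_pos.uniform(ymin, ymax, n)
    tr = dist.sample(n, rng_thr)
    stored = seed if isinstance(seed, (int, np.integer)) else None
    return Population(x=x, y=y, tr=tr, seed=stored)


def compute_activation(pop: Population, field: DiffusionParams) -> ActivationResult:
    """Activation time of every cell under the diffusion field (ts unset)."""
    r = field.radius_from(pop.x, pop.y)
    return ActivationResult(ta=crossing_times(field, r, pop.tr))


def add_spike_delays(
    act: ActivationResult, delay: DelayDistribution, seed
) -> ActivationResult:
    """Fill first-spike times TS = TA + TD with i.i.d. log-normal delays."""
    (rng,) = _rng_streams(seed, 1)
    td = delay.sample(act.ta.size, rng)
    ts = act.ta + td  # NaN propagates
    return ActivationResult(ta=act.ta, ts=ts)


@dataclass(frozen=True)
class AnnulusScheme:
    """Concentric analysis regions around the stimulation spot.

    Area 1 is the central disc of radius ``central_radius``; area k >= 2 is
    the half-open ring [central_radius + (k-2) * ring_thickness,
    central_radius + (k-1) * ring_thickness).  Defaults: a 108 um diameter
    central circle and 36 um rings, six areas in total.
    """

    central_radius: float = 54.0
    ring_thickness: float = 36.0
    n_areas: int = 6

    def __post_init__(self) -> None:
        if self.central_radius <= 0 or self.ring_thickness <= 0:
            raise ValueError("annulus radii must be positive")
        if self.n_areas < 1:
            raise ValueError("n_areas must be >= 1")

    @property
    def outer_radius(self) -> float:
        return self.central_radius + (self.n_areas - 1) * self.ring_thickness

    def bounds(self, k: int) -> tuple[float, float]:
        """[r_in, r_out) of 1-based area ``k``."""
        if not 1 <= k <= self.n_areas:
            raise ValueError(f"area index {k} outside 1..{self.n_areas}")
        if k == 1:
            return (0.0, self.central_radius)
        r_in = self.central_radius + (k - 2) * self.ring_thickness
        return (r_in, r_in + self.ring_thickness)

    def assign(self, r) -> np.ndarray:
        """Area index (1..n_areas) per radius; 0 beyond the last ring."""
        r = np.asarray(r, dtype=float)
        ring = 2 + np.floor((r - self.central_radius) / self.ring_thickness)
        idx = np.where(r < self.central_radius, 1, ring).astype(int)
        idx[idx > self.n_areas] = 0
        return idx


def assign_areas(
    pop: Population, scheme: AnnulusScheme, center: tuple[float, float] = (0.0, 0.0)
) -> np.ndarray:
    """Per-cell annulus index (1-based); 0 marks cells beyond the last ring."""
    r = np.hypot(pop.x - center[0], pop.y - center[1])
    return scheme.assign(r)


@dataclass(frozen=True)
class SpikeHistograms:
    """Per-area first-spike-time histograms plus never-activated counts."""

    edges: np.ndarray
    counts: dict[int, np.ndarray] = field(default_factory=dict)
    never_activated: dict[int, int] = field(default_factory=dict)
    n_cells: dict[int, int] = field(default_factory=dict)


def spike_time_histograms(
    act: ActivationResult,
    areas: np.ndarray,
    bins,
    area_indices: Optional[Sequence[int]] = None,
) -> SpikeHistograms:
    """Histogram first-spike times per annulus.

    Never-activated cells are excluded from the histograms and reported
    separately, so counts + never_activated = cells per area.
    """
    if act.ts is None:
        raise ValueError("spike times not computed; call add_spike_delays first")
    if area_indices is None:
        area_indices = sorted(k for k in np.unique(areas) if k > 0)
    edges = np.histogram_bin_edges(act.ts[~np.isnan(act.ts)], bins=bins)
    counts, never, n_cells = {}, {}, {}
    for k in area_indices:
        in_area = areas == k
        ts_k = act.ts[in_area]
        ok = ~np.isnan(ts_k)
        counts[k], _ = np.histogram(ts_k[ok], bins=edges)
        never[k] = int(np.count_nonzero(~ok))
        n_cells[k] = int(np.count_nonzero(in_area))
    return SpikeHistograms(
        edges=edges, counts=counts, never_activated=never, n_cells=n_cells
    )


def fraction_activated(
    act: ActivationResult,
    areas: np.ndarray,
    time_grid,
    area_indices: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Cumulative activated fraction per annulus on ``time_grid``.

    Column ``area_k`` holds |{i in area k : TA_i <= t}| / N_k — a
    non-decreasing curve in [0, 1]; never-activated cells stay in the
    denominator and cap the plateau below 1.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if area_indices is None:
        area_indices = sorted(k for k in np.unique(areas) if k > 0)
    out = {"time_s": time_grid}
    for k in area_indices:
        ta_k = act.ta[areas == k]
        n_k = ta_k.size
        if n_k == 0:
            out[f"area_{k}"] = np.zeros_like(time_grid)
            continue
        ta_sorted = np.sort(ta_k[~np.isnan(ta_k)])
        out[f"area_{k}"] = np.searchsorted(ta_sorted, time_grid, side="right") / n_k
    return pd.DataFrame(out)
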