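"""Synthetic calcium-imaging experiments with known ground truth.

Generates the full observable layer of a laser-uncaging experiment —
per-cell Fluo-4-like traces at a fixed frame rate, their per-annulus means,
and the underlying population/activation truth — so the forward model and
every inverse procedure can be exercised and validated without any
microscopy data.

Emulated features: uniform scatter of platelets over the field of view,
log-normal activation thresholds, diffusion-driven activation with
log-normally delayed first spikes, a difference-of-exponentials spike
transient inserted at each first-spike time, i.i.d. Gaussian frame noise
around a flat baseline, and occasional spontaneous pre-flash activations
(Poisson per cell).  Deliberately NOT emulated: photobleaching (beyond an
optional linear drift), camera shot noise, cell motion, and optical
blurring.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .diffusion import DiffusionParams, t0_from_beam
from .population import (
    ActivationResult,
    AnnulusScheme,
    DelayDistribution,
    Population,
    ThresholdDistribution,
    add_spike_delays,
    assign_areas,
    compute_activation,
    sample_population,
    square_fov,
)
from .signals import TraceSet

__all__ = [
    "SyntheticConfig",
    "SyntheticExperiment",
    "spike_template",
    "spike_template_peak_offset",
    "generate_experiment",
    "dilution_concentration",
]


def dilution_concentration(
    stock_concentration: float, stock_volume: float, total_volume: float
) -> float:
    """Final concentration after diluting a stock into a total volume.

    Plain C_stock * V_stock / V_total arithmetic, e.g. 3 uL of a 10 mM
    caged-ADP stock in an 80 uL well gives 0.375 mM.
    """
    if stock_volume < 0 or total_volume <= 0 or stock_concentration < 0:
        raise ValueError("volumes/concentrations must be non-negative, total > 0")
    if stock_volume > total_volume:
        raise ValueError("stock volume exceeds total volume")
    return stock_concentration * stock_volume / total_volume


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated world of a synthetic uncaging experiment.

    Units: um, s, M; intensities in arbitrary normalized units.  Defaults
    follow the reference experiment: ADP0 = 1.5e-5 M released in an 80 um
    spot, D = 257 um^2/s, a 108 um central analysis circle with 36 um
    rings, 3 frames/s, flash at 60 s, and a reference threshold law
    LogN(-14.5, 1.7^2).  The delay law LogN(0.7, 0.3^2) (median ~2 s) is a
    package default, chosen once as a typical seconds-scale first-spike lag.
    """

    adp0_M: float = 1.5e-5
    D_um2_s: float = 257.0
    beam_diameter_um: float = 80.0
    center_x_um: float = 0.0
    center_y_um: float = 0.0
    mu: float = -14.5
    sigma: float = 1.7
    mu_d: float = 0.7
    sigma_d: float = 0.3
    central_radius_um: float = 54.0
    ring_thickness_um: float = 36.0
    n_areas: int = 6
    fov_half_um: Optional[float] = None  # default: cover all annuli
    n_cells: int = 50_000
    frame_rate: float = 3.0
    duration_s: float = 180.0
    flash_time_s: float = 60.0
    baseline: float = 1.0
    noise_sigma: float = 0.05
    spike_rise_s: float = 0.5
    spike_decay_s: float = 5.0
    spike_amplitude: float = 5.0
    spontaneous_rate: float = 1e-4  # events / cell / s before the flash
    drift_per_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= self.flash_time_s:
            raise ValueError("duration_s must exceed flash_time_s")
        for name in ("adp0_M", "D_um2_s", "beam_diameter_um", "central_radius_um",
                     "ring_thickness_um", "sigma", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("noise_sigma", "spontaneous_rate", "flash_time_s",
                     "spike_rise_s", "spike_decay_s", "spike_amplitude", "sigma_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_cells < 1 or self.n_areas < 1:
            raise ValueError("n_cells and n_areas must be >= 1")
        if self.spike_rise_s >= self.spike_decay_s:
            raise ValueError("spike_rise_s must be smaller than spike_decay_s")

    @property
    def field(self) -> DiffusionParams:
        return DiffusionParams(
            adp0=self.adp0_M,
            D=self.D_um2_s,
            t0=t0_from_beam(self.beam_diameter_um, self.D_um2_s),
            center=(self.center_x_um, self.center_y_um),
        )

    @property
    def thresholds(self) -> ThresholdDistribution:
        return ThresholdDistribution(mu=self.mu, sigma=self.sigma)

    @property
    def delays(self) -> DelayDistribution:
        return DelayDistribution(mu_d=self.mu_d, sigma_d=self.sigma_d)

    @property
    def scheme(self) -> AnnulusScheme:
        return AnnulusScheme(
            central_radius=self.central_radius_um,
            ring_thickness=self.ring_thickness_um,
            n_areas=self.n_areas,
        )

    @property
    def fov(self) -> tuple[float, float, float, float]:
        half = self.fov_half_um if self.fov_half_um is not None else self.scheme.outer_radius
        return square_fov(half, (self.center_x_um, self.center_y_um))

    @property
    def times(self) -> np.ndarray:
        n_frames = int(round(self.duration_s * self.frame_rate)) + 1
        return np.arange(n_frames) / self.frame_rate

    def truth(self) -> dict:
        return asdict(self)


def spike_template(
    t, rise: float = 0.5, decay: float = 5.0, amplitude: float = 5.0
) -> np.ndarray:
    """Difference-of-exponentials calcium-spike transient, peak-normalized.

    shape(t) = exp(-t/decay) - exp(-t/rise) for t >= 0, scaled so its
    maximum equals ``amplitude``; zero before the spike.
    """
    if rise <= 0 or decay <= rise:
        raise ValueError("need 0 < rise < decay")
    t = np.asarray(t, dtype=float)
    pos = np.clip(t, 0.0, None)
    shape = np.where(t < 0, 0.0, np.exp(-pos / decay) - np.exp(-pos / rise))
    t_peak = np.log(decay / rise) / (1.0 / rise - 1.0 / decay)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    out = amplitude * shape / peak
    return out if out.ndim else float(out)


def spike_template_peak_offset(rise: float = 0.5, decay: float = 5.0) -> float:
    """Lag (s) between spike onset and the template's peak.

    Peak detectors report this later time; delay fits to detected spike
    times absorb the offset.
    """
    if rise <= 0 or decay <= rise:
        raise ValueError("need 0 < rise < decay")
    return float(np.log(decay / rise) / (1.0 / rise - 1.0 / decay))


@dataclass(frozen=True)
class SyntheticExperiment:
    """Everything a real experiment would yield, plus the generating truth."""

    population: Population
    activation: ActivationResult
    areas: np.ndarray
    area_traces: pd.DataFrame
    cell_traces: Optional[TraceSet]
    spontaneous_times: list[np.ndarray]
    truth: dict


def generate_experiment(
    cfg: SyntheticConfig,
    seed: Optional[int] = None,
    traces: str = "both",
) -> SyntheticExperiment:
    """Run the generative model end to end.

    ``traces`` is "both", "area" or "none"; "area" computes per-annulus
    means without materializing the full cell-by-frame matrix (same RNG
    consumption, so area traces are identical across modes).

    Spike transients are inserted at absolute time flash + TS_i; spontaneous
    pre-flash events (Poisson with rate ``spontaneous_rate`` per cell per
    second over [0, flash)) insert the same transient and do not alter the
    cell's later ADP response.
    """
    if traces not in ("both", "area", "none"):
        raise ValueError(f"traces must be 'both', 'area' or 'none', got {traces!r}")
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence(seed)
    ss_pop, ss_delay, ss_spont, ss_noise = ss.spawn(4)

    pop = sample_population(cfg.n_cells, cfg.fov, cfg.thresholds, ss_pop)
    act = compute_activation(pop, cfg.field)
    act = add_spike_delays(act, cfg.delays, ss_delay)
    areas = assign_areas(pop, cfg.scheme, cfg.field.center)

    rng_spont = np.random.default_rng(ss_spont)
    n_events = rng_spont.poisson(cfg.spontaneous_rate * cfg.flash_time_s, cfg.n_cells)
    spont: list[np.ndarray] = [
        np.sort(rng_spont.uniform(0.0, cfg.flash_time_s, k)) if k else np.empty(0)
        for k in n_events
    ]

    times = cfg.times
    area_labels = sorted(k for k in np.unique(areas) if k > 0)
    area_sum = {k: np.zeros_like(times) for k in area_labels}
    area_n = {k: int(np.count_nonzero(areas == k)) for k in area_labels}
    keep_cells = traces == "both"
    cell_values = np.empty((cfg.n_cells, times.size)) if keep_cells else None

    rng_noise = np.random.default_rng(ss_noise)
    chunk = max(1, int(4e6 // times.size))
    for start in range(0, cfg.n_cells, chunk):
        stop = min(start + chunk, cfg.n_cells)
        block = np.full((stop - start, times.size), cfg.baseline)
        if cfg.drift_per_s:
            block += cfg.drift_per_s * times
        block += rng_noise.normal(0.0, cfg.noise_sigma, block.shape)
        ts_chunk = act.ts[start:stop]
        has_spike = ~np.isnan(ts_chunk)
        if np.any(has_spike):
            dt = times[None, :] - (cfg.flash_time_s + ts_chunk[has_spike, None])
            block[has_spike] += spike_template(
                dt, cfg.spike_rise_s, cfg.spike_decay_s, cfg.spike_amplitude
            )
        for i in range(start, stop):  # spontaneous events are rare
            for t_ev in spont[i]:
                block[i - start] += spike_template(
                    times - t_ev,
                    cfg.spike_rise_s, cfg.spike_decay_s, cfg.spike_amplitude,
                )
        areas_chunk = areas[start:stop]
        for k in area_labels:
            sel = areas_chunk == k
            if np.any(sel):
                area_sum[k] += block[sel].sum(axis=0)
        if keep_cells:
            cell_values[start:stop] = block

    area_df = pd.DataFrame({"time_s": times})
    for k in area_labels:
        area_df[f"area_{k}"] = area_sum[k] / max(area_n[k], 1)

    cell_traces = None
    if keep_cells:
        cell_traces = TraceSet(
            times=times, values=cell_values, kind="per-cell",
            columns=list(range(cfg.n_cells)),
        )

    return SyntheticExperiment(
        population=pop,
        activation=act,
        areas=areas,
        area_traces=area_df,
        cell_traces=cell_traces,
        spontaneous_times=spont,
        truth=cfg.truth(),
    )
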