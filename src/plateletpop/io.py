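"""Config parsing, CSV/JSON readers-writers, logging and run provenance.

File conventions: CSV with a header row, '.' decimal separator, UTF-8, no
index column; missing activation/spike times as empty fields.  All lengths
are in um, times in s, concentrations in M, in files and configs alike.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .population import ActivationResult, Population
from .synthetic import SyntheticConfig

__all__ = [
    "CONFIG_UNITS",
    "load_config",
    "dump_config",
    "setup_logging",
    "write_cells_csv",
    "read_cells_csv",
    "write_traces_csv",
    "read_traces_csv",
    "write_spikes_csv",
    "read_spikes_csv",
    "write_json",
    "RunManifest",
]

logger = logging.getLogger("plateletpop")

#: Unit/meaning of every recognized config key (all of SyntheticConfig).
CONFIG_UNITS: dict[str, str] = {
    "adp0_M": "initial released ADP concentration, M",
    "D_um2_s": "ADP diffusion coefficient, um^2/s",
    "beam_diameter_um": "1/e laser-spot diameter, um",
    "center_x_um": "spot center x, um",
    "center_y_um": "spot center y, um",
    "mu": "threshold log-location, ln(M)",
    "sigma": "threshold log-scale, dimensionless",
    "mu_d": "delay log-location, ln(s)",
    "sigma_d": "delay log-scale, dimensionless",
    "central_radius_um": "central analysis circle radius, um",
    "ring_thickness_um": "analysis ring thickness, um",
    "n_areas": "number of analysis areas, count",
    "fov_half_um": "half side of the square field of view, um (null = cover annuli)",
    "n_cells": "number of simulated cells, count",
    "frame_rate": "acquisition rate, frames/s",
    "duration_s": "recording duration, s",
    "flash_time_s": "uncaging flash time, s",
    "baseline": "resting intensity, normalized units",
    "noise_sigma": "per-frame Gaussian noise sd, normalized units",
    "spike_rise_s": "spike-template rise time, s",
    "spike_decay_s": "spike-template decay time, s",
    "spike_amplitude": "spike-template peak amplitude, normalized units",
    "spontaneous_rate": "spontaneous pre-flash activations, events/cell/s",
    "drift_per_s": "linear intensity drift, units/s",
    "seed": "base RNG seed, integer",
}

_INT_KEYS = {"n_areas", "n_cells", "seed"}


def load_config(path) -> SyntheticConfig:
    """Read a flat key-value YAML config, validate, apply defaults.

    Unknown keys are rejected; invalid values raise an error naming the key
    and its expected unit.  An empty file yields all documented defaults.
    The resolved configuration is echoed to the package logger.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    unknown = set(raw) - set(CONFIG_UNITS)
    if unknown:
        raise ValueError(
            f"{path}: unknown config keys {sorted(unknown)}; "
            f"recognized keys: {sorted(CONFIG_UNITS)}"
        )
    clean: dict = {}
    for key, value in raw.items():
        if value is None and key == "fov_half_um":
            clean[key] = None
            continue
        try:
            clean[key] = int(value) if key in _INT_KEYS else float(value)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: invalid value {value!r} for {key} ({CONFIG_UNITS[key]})"
            ) from exc
    try:
        cfg = SyntheticConfig(**clean)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    for key in sorted(CONFIG_UNITS):
        logger.debug("config %-20s = %r", key, getattr(cfg, key))
    return cfg


def dump_config(cfg: SyntheticConfig, path) -> None:
    """Write a config as flat YAML; round-trips through :func:`load_config`."""
    data = dataclasses.asdict(cfg)
    Path(path).write_text(
        yaml.safe_dump(data, sort_keys=True, default_flow_style=False),
        encoding="utf-8",
    )


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def _time_fields(values: Optional[np.ndarray], n: int) -> pd.Series:
    if values is None:
        return pd.Series([np.nan] * n)
    return pd.Series(values)


def write_cells_csv(
    path,
    pop: Population,
    areas: np.ndarray,
    act: Optional[ActivationResult] = None,
) -> None:
    """cells.csv: id, x_um, y_um, threshold_M, area, ta_s, ts_s.

    Missing activation/spike times (never-activated cells) are written as
    empty fields; cells beyond the last ring get an empty area field.
    """
    n = pop.n
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "x_um": pop.x,
            "y_um": pop.y,
            "threshold_M": pop.tr,
            "area": pd.Series(areas).replace(0, np.nan).astype("Int64"),
            "ta_s": _time_fields(act.ta if act is not None else None, n),
            "ts_s": _time_fields(act.ts if act is not None else None, n),
        }
    )
    df.to_csv(path, index=False)


def read_cells_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_traces_csv(path, df: pd.DataFrame) -> None:
    """Per-area or per-cell trace table: time_s then one column per series."""
    df.to_csv(path, index=False)


def read_traces_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_spikes_csv(path, df: pd.DataFrame) -> None:
    """spikes.csv: cell_id, x_um, y_um, ts_s (detected first-spike times)."""
    df.to_csv(path, index=False)


def read_spikes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


@dataclass
class RunManifest:
    """Provenance of one CLI run: enough to reproduce every output file."""

    command: str
    seed: Optional[int]
    config: dict
    outputs: list[str]
    version: str
    started: str
    finished: str = ""

    @classmethod
    def start(cls, command: str, seed: Optional[int], config: dict) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            seed=seed,
            config=config,
            outputs=[],
            version=__version__,
            started=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def write(self, out_dir) -> Path:
        """Atomically write manifest.json into ``out_dir`` (tmp + rename)."""
        self.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        target = out_dir / "manifest.json"
        tmp = out_dir / ".manifest.json.tmp"
        tmp.write_text(
            json.dumps(dataclasses.asdict(self), indent=2) + "\n", encoding="utf-8"
        )
        os.replace(tmp, target)
        return target
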