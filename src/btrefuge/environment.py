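"""Daily temperature forcing and degree-day accumulation.

Temperature is the only climatic driver in the model: it sets the pace of
egg and larval/pupal development and of cane growth through simple
degree-day accumulation (``max(0, T - base)`` per day).  A series can be
read from a two-column text file (day, mean temperature in deg C) or
generated synthetically as a sinusoidal annual cycle plus Gaussian noise,
emulating a subtropical coastal climate.  Series shorter than the
simulation horizon are tiled cyclically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "DegreeDayModel",
    "synth_temperature",
    "read_temperature",
    "write_temperature",
    "degree_days",
]

_PLAUSIBLE = (-5.0, 45.0)


@dataclass(frozen=True)
class TemperatureSeries:
    """Ordered daily mean temperatures (deg C); day 0 is the first sim day."""

    daily_mean: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.daily_mean, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("daily_mean must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError("temperature series contains non-finite values")
        if arr.min() < _PLAUSIBLE[0] or arr.max() > _PLAUSIBLE[1]:
            warnings.warn(
                "temperature series outside plausible range "
                f"[{_PLAUSIBLE[0]}, {_PLAUSIBLE[1]}] deg C",
                stacklevel=3,
            )
        object.__setattr__(self, "daily_mean", arr)

    def __len__(self) -> int:
        return self.daily_mean.size

    def at(self, day: int) -> float:
        """Temperature on a simulation day, tiling cyclically past the end."""
        return float(self.daily_mean[day % self.daily_mean.size])

    def tiled(self, n_days: int) -> np.ndarray:
        """The first ``n_days`` of the cyclically repeated series."""
        reps = -(-n_days // self.daily_mean.size)
        return np.tile(self.daily_mean, reps)[:n_days]


@dataclass(frozen=True)
class DegreeDayModel:
    """Base temperatures and stage thresholds for development and growth.

    Defaults give, under the default synthetic climate, roughly 4-7 days of
    egg development and 30-55 days from hatch to adult eclosion depending on
    season, consistent with a multivoltine stalk borer.  The values are
    package defaults, not measured rates, and are fully configurable.
    """

    egg_base: float = 10.0
    egg_threshold: float = 60.0  # degree-days to hatch
    larva_base: float = 10.0
    larva_threshold: float = 500.0  # degree-days from hatch to eclosion
    cane_base: float = 16.0

    def __post_init__(self):
        for name in ("egg_base", "larva_base", "cane_base"):
            if getattr(self, name) >= 45.0:
                raise ValueError(f"{name} must be below 45 deg C")
        for name in ("egg_threshold", "larva_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def degree_days(temp, base):
    """One day's degree-day contribution: ``max(0, temp - base)``."""
    return np.maximum(0.0, np.asarray(temp, dtype=float) - base)


def synth_temperature(
    n_days: int,
    mean: float = 21.0,
    amplitude: float = 5.0,
    noise_sd: float = 1.5,
    phase_day: int = 15,
    seed=None,
) -> TemperatureSeries:
    """Sinusoidal annual temperature cycle with i.i.d. Gaussian noise.

    The cycle peaks on ``phase_day`` (default mid-January, i.e. a southern-
    hemisphere summer with simulation day 0 on 1 January).  Deterministic
    for a given ``seed``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if amplitude < 0 or noise_sd < 0:
        raise ValueError("amplitude and noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    days = np.arange(n_days)
    cycle = mean + amplitude * np.cos(2 * np.pi * (days - phase_day) / 365.0)
    noise = rng.normal(0.0, noise_sd, size=n_days) if noise_sd > 0 else 0.0
    return TemperatureSeries(cycle + noise)


def read_temperature(path) -> TemperatureSeries:
    """Read a two-column delimited file ``day,temp_c`` (header optional).

    Days must be consecutive integers starting at 0 or 1; the file may be
    comma-, tab- or whitespace-delimited.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse temperature file {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (day, temp_c)")
    # an optional header row is detected by its non-numeric first cell
    try:
        float(df.iloc[0, 0])
    except (ValueError, TypeError):
        df = df.iloc[1:].reset_index(drop=True)
    try:
        days = pd.to_numeric(df.iloc[:, 0]).to_numpy()
        temps = pd.to_numeric(df.iloc[:, 1]).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric value ({exc})") from exc
    if days.size == 0:
        raise ValueError(f"{path}: empty temperature file")
    start = int(days[0])
    if start not in (0, 1):
        raise ValueError(f"{path}: days must start at 0 or 1, got {start}")
    expected = np.arange(start, start + days.size)
    bad = np.nonzero(days != expected)[0]
    if bad.size:
        line = bad[0] + 1
        raise ValueError(
            f"{path}: non-consecutive day at data line {line} "
            f"(expected {expected[bad[0]]}, got {int(days[bad[0]])})"
        )
    return TemperatureSeries(temps)


def write_temperature(series: TemperatureSeries, path) -> None:
    """Write a series in the same ``day,temp_c`` CSV form read back by
    :func:`read_temperature`."""
    df = pd.DataFrame(
        {"day": np.arange(1, len(series) + 1), "temp_c": series.daily_mean}
    )
    df.to_csv(path, index=False)
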