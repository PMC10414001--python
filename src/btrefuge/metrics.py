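"""Resistance metrics over replicated runs.

A replicate counts as having *developed resistance* when, inside the final
six months (180 days) of its horizon, the fully resistant adult population
reaches at least 1,000 individuals — a threshold chosen because every run
crossing it goes on to build a large resistant population.  Over a set of
replicates the two headline statistics are ``eta``, the number of
resistance-developed runs, and ``mu_r``, the mean fully resistant adult
count on the final day across all replicates.

Spatial diagnostics locate where resistance ignites: the sky-cell grid of
fully resistant counts on the first day the total exceeds 1,000, and the
critical-ratio statistics — the maximum per-sky-cell resistant count and
the maximum resistant:susceptible ratio among cells holding at least 50
moths — taken over every day and cell of a run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import RunResult

__all__ = [
    "ExperimentResult",
    "is_resistant_run",
    "eta_mu",
    "resistance_map",
    "critical_ratio_stats",
    "ratio_as_one_to",
    "RESISTANCE_THRESHOLD",
    "RESISTANCE_WINDOW_DAYS",
]

RESISTANCE_THRESHOLD = 1000
RESISTANCE_WINDOW_DAYS = 180


@dataclass(frozen=True)
class ExperimentResult:
    """Summary of one parameter combination across its replicates."""

    eta: int
    mu_r: float
    n_replicates: int
    flags: tuple[bool, ...]
    first_crossing_days: tuple[int | None, ...]
    final_resistant: tuple[int, ...]

    def __post_init__(self):
        if not 0 <= self.eta <= self.n_replicates:
            raise ValueError("eta outside [0, n_replicates]")


def is_resistant_run(
    daily_resistant_counts,
    horizon: int | None = None,
    window_days: int = RESISTANCE_WINDOW_DAYS,
    threshold: int = RESISTANCE_THRESHOLD,
) -> bool:
    """Classify one run from its daily fully-resistant adult series.

    True iff the count reaches ``threshold`` at any point inside the final
    ``window_days`` of the horizon.
    """
    counts = np.asarray(daily_resistant_counts)
    horizon = counts.size - 1 if horizon is None else horizon
    if counts.size <= horizon:
        raise ValueError(
            f"series of length {counts.size} does not cover horizon {horizon}"
        )
    window = counts[max(0, horizon - window_days + 1) : horizon + 1]
    if window.size < min(window_days, horizon + 1):
        raise ValueError("series shorter than the classification window")
    return bool(window.max() >= threshold)


def eta_mu(results: list[RunResult], **kwargs) -> ExperimentResult:
    """Compute eta and mu_r for a batch of replicates.

    ``mu_r`` averages the final-day fully resistant adult count over *all*
    replicates, resistant or not.
    """
    if not results:
        raise ValueError("eta_mu requires at least one run")
    flags, firsts, finals = [], [], []
    for r in results:
        flags.append(is_resistant_run(r.resistant_adults, r.horizon_days, **kwargs))
        firsts.append(r.first_crossing(RESISTANCE_THRESHOLD))
        finals.append(int(r.resistant_adults[-1]))
    return ExperimentResult(
        eta=int(sum(flags)),
        mu_r=float(np.mean(finals)),
        n_replicates=len(results),
        flags=tuple(flags),
        first_crossing_days=tuple(firsts),
        final_resistant=tuple(finals),
    )


def resistance_map(
    run: RunResult, threshold: int = RESISTANCE_THRESHOLD
) -> tuple[np.ndarray | None, bool]:
    """Sky grid of fully resistant counts at first resistance development.

    Returns ``(grid, crossed)``: the per-sky-cell resistant counts on the
    first day the run's total exceeds ``threshold``, or ``(None, False)``
    for runs that never cross.
    """
    day = run.first_crossing(threshold)
    if day is None:
        return None, False
    return run.resistant_by_sky[day].reshape(run.sky_shape).copy(), True


def critical_ratio_stats(run: RunResult, min_total: int = 50) -> dict:
    """Per-sky-cell concentration extremes over every day of a run.

    ``max_resistant_per_cell``: largest fully resistant count ever seen in
    one sky cell.  ``max_ratio``: largest resistant:susceptible ratio among
    day-cells with at least ``min_total`` moths (``inf`` if such a cell had
    no susceptibles, ``None`` if no cell ever reached ``min_total``).
    """
    res = run.resistant_by_sky
    sus = run.susceptible_by_sky()
    total = run.adults_by_sky
    max_res = int(res.max()) if res.size else 0
    eligible = total >= min_total
    if not eligible.any():
        return {"max_resistant_per_cell": max_res, "max_ratio": None,
                "ratio_defined": False}
    r = res[eligible].astype(float)
    s = sus[eligible].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(s > 0, r / np.maximum(s, 1e-300), np.where(r > 0, np.inf, 0.0))
    return {
        "max_resistant_per_cell": max_res,
        "max_ratio": float(ratios.max()),
        "ratio_defined": True,
    }


def ratio_as_one_to(ratio: float) -> str:
    """Render a resistant/susceptible ratio in the field's '1 to n' style."""
    if ratio is None or ratio <= 0:
        return "0"
    if math.isinf(ratio):
        return "all resistant"
    return f"1 to {1.0 / ratio:.0f}" if ratio < 1 else f"{ratio:.0f} to 1"
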