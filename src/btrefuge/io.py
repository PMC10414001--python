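"""Output writers: census CSVs, layout grids, metadata and metrics files.

Each run is written to its own subdirectory keyed by layout, refuge
proportion and seed, so replicates never clobber each other and re-running
an identical (config, seed) pair reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import config_to_dict
from .engine import RunResult, SimConfig
from .landscape import Layout
from .metrics import ExperimentResult

__all__ = [
    "run_dir_name",
    "write_layout",
    "write_run",
    "write_outputs",
    "write_metrics",
    "save_heatmap",
    "config_hash",
]


def config_hash(config: SimConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_dir_name(result: RunResult) -> str:
    return f"{result.layout_kind}_h{result.h_target:g}_seed{result.seed}"


def write_layout(layout: Layout, out_dir) -> tuple[Path, Path]:
    """Write the B/R text grid plus a CSV of refuge cell indices."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid_path = out_dir / "layout.txt"
    grid_path.write_text(layout.to_text() + "\n")
    rows, cols = np.nonzero(layout.mask)
    idx_path = out_dir / "refuge_cells.csv"
    pd.DataFrame({"row": rows, "col": cols}).to_csv(idx_path, index=False)
    return grid_path, idx_path


def write_run(result: RunResult, out_dir, config: SimConfig | None = None) -> Path:
    """Write one run: census.csv, resistant_by_sky.csv, metadata.json."""
    out_dir = Path(out_dir) / run_dir_name(result)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.census_frame().to_csv(out_dir / "census.csv", index=False)
    sky_cols = [f"cell{i}" for i in range(result.resistant_by_sky.shape[1])]
    pd.DataFrame(result.resistant_by_sky, columns=sky_cols).to_csv(
        out_dir / "resistant_by_sky.csv", index_label="day"
    )
    meta = {
        "seed": result.seed,
        "layout_kind": result.layout_kind,
        "h_target": result.h_target,
        "achieved_fraction": result.achieved_fraction,
        "horizon_days": result.horizon_days,
        "warmup_days": result.warmup_days,
        "sky_shape": list(result.sky_shape),
    }
    if config is not None:
        meta["config"] = config_to_dict(config)
        meta["config_hash"] = config_hash(config)
    (out_dir / "metadata.json").write_text(json.dumps(meta, indent=2, default=str))
    return out_dir


def write_outputs(results, out_dir, config: SimConfig | None = None) -> list[Path]:
    """Write a batch of runs under ``out_dir`` (one subdirectory each)."""
    return [write_run(r, out_dir, config) for r in results]


def write_metrics(summary: ExperimentResult, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "eta": summary.eta,
        "mu_r": summary.mu_r,
        "n_replicates": summary.n_replicates,
        "flags": list(summary.flags),
        "first_crossing_days": list(summary.first_crossing_days),
        "final_resistant": list(summary.final_resistant),
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def save_heatmap(grid: np.ndarray, path, title: str = "") -> Path:
    """Save a sky-grid heatmap (e.g. a resistance concentration map)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(grid, cmap="viridis")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
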