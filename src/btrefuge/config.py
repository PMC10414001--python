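"""Run-configuration parsing, validation and the case-study presets.

Configurations are nested key-value YAML; every omitted key falls back to
the study defaults baked into the dataclasses (the bold column of the
parameter table: 2 MOA at 95% efficacy, recessive resistance, average
movement, 24-month harvest cycle, 0.5% initial resistance, and so on).
Unknown keys are rejected with their full path so typos cannot silently
revert a parameter to its default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import yaml

from .behavior import MovementParams, OvipositionParams
from .engine import EnvConfig, SimConfig
from .environment import DegreeDayModel
from .genetics import BtParams
from .landscape import GridGeometry, GrowthParams, LayoutSpec
from .lifecycle import MortalityParams

__all__ = ["load_config", "config_from_dict", "config_to_dict",
           "scale_config", "ExperimentPreset", "preset_case_study"]


class ConfigError(ValueError):
    pass


def _build(cls, data: dict, path: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under '{path}'")
    kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value under '{path}': {exc}") from exc


_SIM_KEYS = {
    "horizon_days", "warmup_days", "harvest_cycle_months", "n_replicates",
    "init_batches", "batch_size", "init_proportions", "init_exact_quota",
    "initial_cane_age_days", "seed",
}


def config_from_dict(data: dict | None) -> SimConfig:
    """Build a validated :class:`~btrefuge.engine.SimConfig` from nested keys."""
    data = dict(data or {})
    sections = {
        "simulation", "landscape", "geometry", "growth", "bt", "mortality",
        "movement", "oviposition", "degree_days", "environment",
    }
    unknown = set(data) - sections
    if unknown:
        raise ConfigError(f"unknown section(s) {sorted(unknown)}")

    sim = dict(data.get("simulation") or {})
    bad = set(sim) - _SIM_KEYS
    if bad:
        raise ConfigError(f"unknown key(s) {sorted(bad)} under 'simulation'")
    if "init_proportions" in sim:
        sim["init_proportions"] = tuple(sim["init_proportions"])

    land = dict(data.get("landscape") or {})
    layout = _build(
        LayoutSpec,
        {k: land.pop(k) for k in ("kind", "h") if k in land},
        "landscape",
    ) if ("kind" in land or "h" in land) else LayoutSpec("single_block", 0.2)
    if land:
        raise ConfigError(f"unknown key(s) {sorted(land)} under 'landscape'")

    move = dict(data.get("movement") or {})
    level = move.pop("level", None)
    if level is not None:
        base = MovementParams.from_level(level)
        move = {**dataclasses.asdict(base), **move}
    movement = _build(MovementParams, move, "movement")

    return _build(SimConfig, {
        **sim,
        "layout": layout,
        "geometry": _build(GridGeometry, data.get("geometry") or {}, "geometry"),
        "growth": _build(GrowthParams, data.get("growth") or {}, "growth"),
        "bt": _build(BtParams, data.get("bt") or {}, "bt"),
        "mortality": _build(MortalityParams, data.get("mortality") or {}, "mortality"),
        "movement": movement,
        "oviposition": _build(OvipositionParams, data.get("oviposition") or {}, "oviposition"),
        "degree_days": _build(DegreeDayModel, data.get("degree_days") or {}, "degree_days"),
        "env": _build(EnvConfig, data.get("environment") or {}, "environment"),
    }, "simulation")


def load_config(path) -> SimConfig:
    """Read a YAML config file; an empty file yields the full default config."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(data)


def config_to_dict(config: SimConfig) -> dict:
    """Flatten a config back into the nested-dict form (for metadata echo)."""
    d = dataclasses.asdict(config)
    layout = d.pop("layout")
    return {
        "simulation": {k: d[k] for k in _SIM_KEYS},
        "landscape": layout,
        "geometry": d["geometry"],
        "growth": d["growth"],
        "bt": d["bt"],
        "mortality": d["mortality"],
        "movement": d["movement"],
        "oviposition": d["oviposition"],
        "degree_days": d["degree_days"],
        "environment": d["env"],
    }


def scale_config(config: SimConfig, factor: float) -> SimConfig:
    """Shrink a config for desk-scale smoke runs (NOT the study conditions).

    Total area, horizon, warm-up and founder population are scaled by
    ``factor``; the area snaps to the nearest value that still tiles the
    nested grids.
    """
    if not 0 < factor <= 1:
        raise ConfigError("scale factor must be in (0, 1]")
    geom = config.geometry
    sky_ha = geom.sky_cell_area / 1e4
    n_sky = max(1, round(config.geometry.total_area_ha * factor / sky_ha))
    new_geom = replace(geom, total_area_ha=n_sky * sky_ha)
    horizon = max(1, round(config.horizon_days * factor))
    return replace(
        config,
        geometry=new_geom,
        horizon_days=horizon,
        warmup_days=min(round(config.warmup_days * factor), horizon - 1),
        init_batches=max(1, min(round(config.init_batches * factor), n_sky)),
        batch_size=max(1, round(config.batch_size * factor)),
    )


# ---------------------------------------------------------------------------
# case-study presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentPreset:
    """A named grid of run configurations (layouts x h x movement levels)."""

    name: str
    configs: tuple[SimConfig, ...]
    replicates: int = 15


_CASE1_KINDS = ("single_block", "blocks4", "blocks16")
_CASE1_H = (0.10, 0.20, 0.30)
_CASE2_KINDS = ("linear1", "linear2", "border1", "border2",
                "border_block", "border_block_revised")
_CASE2_H = 0.20


def preset_case_study(
    which: str,
    movement_levels: tuple[str, ...] = ("low", "average", "high"),
    base: SimConfig | None = None,
) -> ExperimentPreset:
    """The two study designs: refuge size/distribution, and refuge shape.

    Case "one" crosses the fractal block layouts (1/4/16 blocks) with
    h in {10%, 20%, 30%}; case "two" tests the six linear/border/hybrid
    shapes at the median h of 20%.  Both cross the requested movement
    levels, at 15 replicates per combination.
    """
    base = base or SimConfig()
    configs = []
    if which in ("one", "1"):
        grid = [(k, h) for k in _CASE1_KINDS for h in _CASE1_H]
        name = "case-study-1-distribution"
    elif which in ("two", "2"):
        grid = [(k, _CASE2_H) for k in _CASE2_KINDS]
        name = "case-study-2-shape"
    else:
        raise ConfigError("case study must be 'one' or 'two'")
    for kind, h in grid:
        for level in movement_levels:
            configs.append(replace(
                base,
                layout=LayoutSpec(kind, h),
                movement=MovementParams.from_level(level),
                n_replicates=15,
            ))
    return ExperimentPreset(name=name, configs=tuple(configs))
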