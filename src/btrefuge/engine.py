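"""Simulation orchestration: world state, the daily scheduler, replication.

A run advances in daily steps over a fixed horizon (default 10 years).
Within a day the phases are fixed: (1) temperature and degree-days,
(2) cane growth and, on cycle days, harvest; (3) the ground layer — egg
mortality and hatch, larval establishment under Bt selection and stalk
capacity, in-stalk development and eclosion; (4) the sky layer — adult
mortality, biased movement, lek-gated mating and descent; (5) oviposition
into ground cells.  Within each phase every agent reads the same
start-of-phase state (movement biases and lek eligibility are computed
from a snapshot), matching a simultaneous-update schedule.

The population is initialised with evenly spaced batches of adults whose
genotype composition is assigned by exact quota, so the default 20 batches
of 1,000 moths contain exactly 100 fully resistant founders (0.5%).
The first 4 years are a warm-up: Bt and resistance are present from day 0
but resistance metrics are read from the post-warm-up period only.

Every source of randomness flows from one ``numpy`` Generator seeded per
run, so a (config, seed) pair fully determines every output; replicates
use consecutive seeds.  A per-day tally ledger (births, deaths by cause,
stage promotions) is recorded so that exact conservation of individuals
can be audited after the fact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior
from .behavior import MovementParams, OvipositionParams
from .environment import DegreeDayModel, TemperatureSeries, degree_days, synth_temperature, read_temperature
from .genetics import BtParams, class_to_string, fully_resistant_classes, initial_class_quota
from .landscape import Field, GridGeometry, GrowthParams, Layout, LayoutSpec, make_layout
from .lifecycle import (
    CohortTable,
    MortalityParams,
    egg_step,
    hatch_and_establish,
    larva_step,
)

__all__ = ["EnvConfig", "SimConfig", "RunResult", "World", "initialize", "step_day", "run", "replicate"]

_TALLY_KEYS = (
    "eggs_laid", "egg_deaths", "hatched", "outside_deaths", "bt_deaths",
    "overflow_deaths", "larva_deaths", "emerged", "moth_deaths", "ovi_spent",
    "harvest_egg_kills", "harvest_larva_kills",
)


@dataclass(frozen=True)
class EnvConfig:
    """Temperature forcing: a file path or the synthetic generator."""

    source: str = "synthetic"  # "synthetic" | "file"
    path: str | None = None
    n_days: int = 730
    mean: float = 21.0
    amplitude: float = 5.0
    noise_sd: float = 1.5
    phase_day: int = 15
    seed: int | None = None  # None: derived from the run config's base seed

    def __post_init__(self):
        if self.source not in ("synthetic", "file"):
            raise ValueError("environment source must be 'synthetic' or 'file'")
        if self.source == "file" and not self.path:
            raise ValueError("environment source 'file' requires a path")


@dataclass(frozen=True)
class SimConfig:
    """Full run configuration; defaults reproduce the study conditions."""

    horizon_days: int = 3650
    warmup_days: int = 1460
    harvest_cycle_months: int = 24
    n_replicates: int = 15
    init_batches: int = 20
    batch_size: int = 1000
    init_proportions: tuple[float, float, float] = (0.995, 0.0, 0.005)
    init_exact_quota: bool = True
    initial_cane_age_days: int = 180
    seed: int = 0
    layout: LayoutSpec = field(default_factory=lambda: LayoutSpec("single_block", 0.2))
    geometry: GridGeometry = field(default_factory=GridGeometry)
    bt: BtParams = field(default_factory=BtParams)
    mortality: MortalityParams = field(default_factory=MortalityParams)
    movement: MovementParams = field(default_factory=MovementParams)
    oviposition: OvipositionParams = field(default_factory=OvipositionParams)
    degree_days: DegreeDayModel = field(default_factory=DegreeDayModel)
    growth: GrowthParams = field(default_factory=GrowthParams)
    env: EnvConfig = field(default_factory=EnvConfig)

    def __post_init__(self):
        if not 0 <= self.warmup_days < self.horizon_days + 1:
            raise ValueError("warmup_days must be smaller than horizon_days")
        if abs(sum(self.init_proportions) - 1.0) > 1e-9:
            raise ValueError("init_proportions must sum to 1")
        if self.init_batches < 1 or self.batch_size < 1:
            raise ValueError("init_batches and batch_size must be positive")

    @property
    def harvest_cycle_days(self) -> int:
        return round(self.harvest_cycle_months * 365 / 12)


# ---------------------------------------------------------------------------
# adult population, struct-of-arrays
# ---------------------------------------------------------------------------

_MCOLS = ("female", "g", "age", "sky", "ground", "state", "fert0", "fert",
          "ovi_day", "mate_g", "times_mated")
_MDTYPES = dict(
    female=bool, g=np.int8, age=np.int16, sky=np.int32, ground=np.int32,
    state=np.int8, fert0=np.int32, fert=np.int32, ovi_day=np.int8,
    mate_g=np.int8, times_mated=np.int16,
)

FLYING, OVIPOSITING = 0, 1


class MothArrays:
    """All live adults as parallel arrays (one row per moth)."""

    def __init__(self, **cols):
        n = len(cols["g"]) if cols else 0
        for name in _MCOLS:
            default = np.zeros(n)
            arr = np.asarray(cols.get(name, default), dtype=_MDTYPES[name])
            setattr(self, name, arr)

    @classmethod
    def empty(cls) -> "MothArrays":
        return cls(**{c: np.array([], dtype=_MDTYPES[c]) for c in _MCOLS})

    def __len__(self) -> int:
        return self.g.size

    def select(self, mask) -> "MothArrays":
        return MothArrays(**{c: getattr(self, c)[mask] for c in _MCOLS})

    @staticmethod
    def concat(pops) -> "MothArrays":
        pops = [p for p in pops if len(p)]
        if not pops:
            return MothArrays.empty()
        return MothArrays(
            **{c: np.concatenate([getattr(p, c) for p in pops]) for c in _MCOLS}
        )

    def count_by_sky(self, n_sky: int, mask=None) -> np.ndarray:
        sky = self.sky if mask is None else self.sky[mask]
        return np.bincount(sky, minlength=n_sky).astype(np.int64)


# ---------------------------------------------------------------------------
# world and results
# ---------------------------------------------------------------------------

class World:
    """Mutable state of one run: field, temperature, cohorts, adults, RNG."""

    def __init__(self, config: SimConfig, layout: Layout, temps: np.ndarray,
                 rng: np.random.Generator):
        self.config = config
        self.geom = config.geometry
        self.layout = layout
        self.temps = temps
        self.rng = rng
        ddm = config.degree_days
        # cane age at day 0, with height matching the degree-days the stand
        # would have accumulated over that many preceding days of the series
        age0 = config.initial_cane_age_days
        pre = temps[np.arange(-age0, 0) % len(temps)] if age0 > 0 else np.array([])
        h0 = min(
            float(degree_days(pre, ddm.cane_base).sum()) * config.growth.growth_rate,
            config.growth.max_height,
        )
        self.field = Field(layout, self.geom, config.growth,
                           initial_age=age0, initial_height=h0)
        self.eggs = CohortTable.empty()
        self.larvae = CohortTable.empty()
        self.moths = MothArrays.empty()
        self.day = 0

    @property
    def n_sky(self) -> int:
        return self.geom.n_sky

    def ground_to_sky(self, ground_flat: np.ndarray) -> np.ndarray:
        k = self.geom.nesting
        _, gc = self.geom.ground_shape
        _, sc = self.geom.sky_shape
        return (ground_flat // gc // k) * sc + (ground_flat % gc) // k


@dataclass
class RunResult:
    """Per-day census, spatial snapshots and the conservation ledger."""

    seed: int
    layout_kind: str
    h_target: float
    achieved_fraction: float
    horizon_days: int
    warmup_days: int
    eggs_total: np.ndarray
    larvae_total: np.ndarray
    adults_total: np.ndarray
    adults_by_class: np.ndarray  # (days+1, 9)
    resistant_adults: np.ndarray
    adults_by_sky: np.ndarray  # (days+1, n_sky)
    resistant_by_sky: np.ndarray  # (days+1, n_sky)
    tallies: dict[str, np.ndarray]
    sky_shape: tuple[int, int]

    def susceptible_by_sky(self) -> np.ndarray:
        return self.adults_by_sky - self.resistant_by_sky

    def first_crossing(self, threshold: int) -> int | None:
        """First day the fully resistant adult count exceeds ``threshold``."""
        over = np.nonzero(self.resistant_adults > threshold)[0]
        return int(over[0]) if over.size else None

    def census_frame(self) -> pd.DataFrame:
        """Tidy per-day census: day, stage, genotype_class, layer, count."""
        days = np.arange(self.adults_total.size)
        rows = []
        for stage, layer, series in (
            ("egg", "ground", self.eggs_total),
            ("larva", "ground", self.larvae_total),
        ):
            rows.append(pd.DataFrame({
                "day": days, "stage": stage, "genotype_class": "unresolved",
                "layer": layer, "count": series,
            }))
        for cls in range(self.adults_by_class.shape[1]):
            rows.append(pd.DataFrame({
                "day": days, "stage": "adult",
                "genotype_class": class_to_string(cls), "layer": "sky",
                "count": self.adults_by_class[:, cls],
            }))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def _batch_lattice(n_batches: int, sky_shape: tuple[int, int]) -> np.ndarray:
    """Evenly spaced sky cells for the founder batches (a near-square a x b
    lattice mapped onto the grid; e.g. 20 batches on 10 x 10 -> 4 x 5)."""
    sr, sc = sky_shape
    if n_batches > sr * sc:
        raise ValueError("more founder batches than sky cells")
    best = None
    for a in range(1, n_batches + 1):
        if n_batches % a:
            continue
        b = n_batches // a
        score = abs(a / b - sr / sc)
        if best is None or score < best[0]:
            best = (score, a, b)
    _, a, b = best
    rows = np.floor((np.arange(a) + 0.5) * sr / a).astype(int)
    cols = np.floor((np.arange(b) + 0.5) * sc / b).astype(int)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    flat = rr.ravel() * sc + cc.ravel()
    if np.unique(flat).size != n_batches:
        raise ValueError("batch lattice collapsed; grid too small for batches")
    return flat


def initialize(config: SimConfig, layout: Layout | None = None,
               seed: int | None = None) -> World:
    """Build the initial world: field state plus the founder adult batches.

    Each batch holds ``batch_size`` adults split evenly between the sexes,
    with genotype classes assigned by largest-remainder quota (exact counts)
    by default, or binomially when ``init_exact_quota`` is off.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    layout = layout or make_layout(config.layout, config.geometry)
    temps = _build_temperature(config)
    world = World(config, layout, temps, rng)

    cells = _batch_lattice(config.init_batches, config.geometry.sky_shape)
    batches = []
    for cell in cells:
        n = config.batch_size
        if config.init_exact_quota:
            classes = initial_class_quota(n, config.init_proportions)
        else:
            classes = rng.choice(
                np.array([0, 4, 8]), size=n, p=np.asarray(config.init_proportions)
            )
        classes = rng.permutation(classes)
        female = np.zeros(n, dtype=bool)
        female[: n // 2] = True
        female = rng.permutation(female)
        batches.append(MothArrays(
            female=female, g=classes, age=np.zeros(n), sky=np.full(n, cell),
            ground=np.full(n, -1), state=np.full(n, FLYING),
            fert0=np.zeros(n), fert=np.zeros(n), ovi_day=np.zeros(n),
            mate_g=np.full(n, -1), times_mated=np.zeros(n),
        ))
    world.moths = MothArrays.concat(batches)
    return world


def _build_temperature(config: SimConfig) -> np.ndarray:
    env = config.env
    if env.source == "file":
        series = read_temperature(env.path)
    else:
        tseed = env.seed if env.seed is not None else config.seed
        series = synth_temperature(
            env.n_days, mean=env.mean, amplitude=env.amplitude,
            noise_sd=env.noise_sd, phase_day=env.phase_day, seed=tseed,
        )
    return series.daily_mean


# ---------------------------------------------------------------------------
# daily step
# ---------------------------------------------------------------------------

def step_day(world: World, day: int) -> dict[str, int]:
    """Advance the world one day; returns the day's conservation tallies."""
    cfg = world.config
    rng = world.rng
    tally = dict.fromkeys(_TALLY_KEYS, 0)
    temp = world.temps[day % len(world.temps)]
    ddm = cfg.degree_days
    dd_egg = float(degree_days(temp, ddm.egg_base))
    dd_larva = float(degree_days(temp, ddm.larva_base))
    dd_cane = float(degree_days(temp, ddm.cane_base))

    # --- field growth / harvest -------------------------------------------
    world.field.grow(dd_cane)
    cycle = cfg.harvest_cycle_days
    if cycle > 0 and day > 0 and day % cycle == 0:
        tally["harvest_egg_kills"] = world.eggs.total()
        world.eggs = CohortTable.empty()
        surv = cfg.growth.harvest_larva_survival
        if surv > 0 and len(world.larvae):
            kept = rng.binomial(world.larvae.number, surv)
            tally["harvest_larva_kills"] = int(world.larvae.number.sum() - kept.sum())
            world.larvae.number = kept.astype(np.int64)
            world.larvae = world.larvae.select(world.larvae.number > 0)
        else:
            tally["harvest_larva_kills"] = world.larvae.total()
            world.larvae = CohortTable.empty()
        world.field.harvest_reset()

    # --- ground layer ------------------------------------------------------
    world.eggs, hatched, deaths = egg_step(
        world.eggs, dd_egg, ddm.egg_threshold, cfg.mortality, rng
    )
    tally["egg_deaths"] = deaths
    tally["hatched"] = hatched.total()

    in_stalk = world.larvae.count_by_cell(world.geom.n_ground)
    remaining = np.maximum(world.field.stalk_capacity() - in_stalk, 0).astype(float)
    new_larvae, est = hatch_and_establish(
        hatched, world.field.is_bt_flat(), remaining, cfg.bt, cfg.mortality, rng
    )
    tally["outside_deaths"] = est["outside"]
    tally["bt_deaths"] = est["bt"]
    tally["overflow_deaths"] = est["overflow"]
    world.larvae = CohortTable.concat([world.larvae, new_larvae])

    world.larvae, emerged, deaths = larva_step(
        world.larvae, dd_larva, ddm.larva_threshold, cfg.mortality, rng
    )
    tally["larva_deaths"] = deaths

    if len(emerged):
        n_f = rng.binomial(emerged.number, 0.5)
        n_m = emerged.number - n_f
        sky = world.ground_to_sky(emerged.cell)
        parts = []
        for counts, female in ((n_f, True), (n_m, False)):
            tot = int(counts.sum())
            if tot == 0:
                continue
            parts.append(MothArrays(
                female=np.full(tot, female),
                g=np.repeat(emerged.genotype, counts),
                age=np.zeros(tot),
                sky=np.repeat(sky, counts),
                ground=np.full(tot, -1),
                state=np.full(tot, FLYING),
                fert0=np.zeros(tot), fert=np.zeros(tot), ovi_day=np.zeros(tot),
                mate_g=np.full(tot, -1), times_mated=np.zeros(tot),
            ))
        tally["emerged"] = int(emerged.total())
        world.moths = MothArrays.concat([world.moths] + parts)

    # --- sky layer ---------------------------------------------------------
    m = world.moths
    if len(m):
        alive = rng.random(len(m)) >= cfg.mortality.moth_daily
        tally["moth_deaths"] = int(len(m) - alive.sum())
        m = m.select(alive)
        m.age += 1
        world.moths = m

    if len(m):
        _sky_phase(world, tally)
    _oviposition_phase(world, tally)
    world.day = day
    return tally


def _sky_phase(world: World, tally: dict) -> None:
    cfg, rng, m = world.config, world.rng, world.moths
    sky_shape = world.geom.sky_shape
    n_sky = world.geom.n_sky
    mv = cfg.movement

    flying = m.state == FLYING
    density = m.count_by_sky(n_sky, flying).reshape(sky_shape)
    heights = world.field.mean_height_by_sky()

    fly_f = flying & m.female
    fly_m = flying & ~m.female
    new_sky = m.sky.copy()
    # movement: all moths in a source cell share one destination kernel,
    # computed from the start-of-phase density/height snapshot
    for mask, dist_fn, grid in (
        (fly_f, behavior.female_move_distribution, density),
        (fly_m, behavior.male_move_distribution, heights),
    ):
        idx = np.nonzero(mask)[0]
        if not idx.size:
            continue
        for cell in np.unique(m.sky[idx]):
            members = idx[m.sky[idx] == cell]
            rc = (int(cell) // sky_shape[1], int(cell) % sky_shape[1])
            p = dist_fn(rc, grid, mv)
            new_sky[members] = rng.choice(n_sky, size=members.size, p=p)
    m.sky = new_sky

    # lek check and mating, from post-movement positions; eligibility is a
    # start-of-phase snapshot (males picked twice today both count)
    eligible = (~m.female) & (m.times_mated < behavior.MATING_CAP)
    unmated_f = np.nonzero(m.female & (m.state == FLYING))[0]
    ages = world.field.age.reshape(world.geom.ground_shape)
    ovi = cfg.oviposition
    k = world.geom.nesting
    gc = world.geom.ground_shape[1]
    for cell in np.unique(m.sky[unmated_f]):
        females = unmated_f[m.sky[unmated_f] == cell]
        males = np.nonzero(eligible & (m.sky == cell))[0]
        rc = (int(cell) // sky_shape[1], int(cell) % sky_shape[1])
        if males.size >= behavior.LEK_SIZE:
            chosen = males[rng.integers(0, males.size, size=females.size)]
            np.add.at(m.times_mated, chosen, 1)
            m.mate_g[females] = m.g[chosen]
            m.fert0[females] = rng.integers(
                ovi.fecundity_min, ovi.fecundity_max + 1, size=females.size
            )
            m.fert[females] = m.fert0[females]
            m.state[females] = OVIPOSITING
            m.ovi_day[females] = 0
            # descent: ground cell beneath the sky cell, biased by cane age
            r0, c0 = rc[0] * k, rc[1] * k
            block = ages[r0 : r0 + k, c0 : c0 + k]
            p = behavior.descend_distribution(block)
            flat = rng.choice(k * k, size=females.size, p=p)
            m.ground[females] = (r0 + flat // k) * gc + (c0 + flat % k)
        else:
            # no lek: relocate to a uniform reflected neighbour
            offs = behavior.ring_offsets(1)
            pick = offs[rng.integers(0, len(offs), size=females.size)]
            nr = behavior.reflect(rc[0] + pick[:, 0], sky_shape[0])
            nc = behavior.reflect(rc[1] + pick[:, 1], sky_shape[1])
            m.sky[females] = nr * sky_shape[1] + nc


def _oviposition_phase(world: World, tally: dict) -> None:
    cfg, rng, m = world.config, world.rng, world.moths
    ovi_idx = np.nonzero(m.state == OVIPOSITING)[0]
    if not ovi_idx.size:
        return
    geom = world.geom
    gr, gc = geom.ground_shape
    ovi = cfg.oviposition

    # ground-cell move (probability mf) when the cell's stalk capacity is full
    in_stalk = world.larvae.count_by_cell(geom.n_ground)
    free = world.field.stalk_capacity() - in_stalk
    full = free[m.ground[ovi_idx]] <= 0
    movers = ovi_idx[full & (rng.random(ovi_idx.size) < cfg.movement.mf)]
    if movers.size:
        offs = behavior.ring_offsets(1)
        pick = offs[rng.integers(0, len(offs), size=movers.size)]
        nr = behavior.reflect(m.ground[movers] // gc + pick[:, 0], gr)
        nc = behavior.reflect(m.ground[movers] % gc + pick[:, 1], gc)
        m.ground[movers] = nr * gc + nc
        # oviposition stays within the natal sky neighbourhood; update layer link
        m.sky[movers] = world.ground_to_sky(m.ground[movers])

    amounts = behavior.oviposition_amount(
        m.fert0[ovi_idx], m.fert[ovi_idx], m.ovi_day[ovi_idx], ovi
    )
    m.fert[ovi_idx] -= amounts
    laying = amounts > 0
    if laying.any():
        src = ovi_idx[laying]
        amt = amounts[laying]
        key = (m.ground[src].astype(np.int64) * 81
               + m.g[src].astype(np.int64) * 9 + m.mate_g[src])
        uniq, inv = np.unique(key, return_inverse=True)
        sums = np.bincount(inv, weights=amt).astype(np.int64)
        tally["eggs_laid"] = int(sums.sum())
        new_eggs = CohortTable(
            stage=np.zeros(uniq.size),
            cell=uniq // 81,
            mother=(uniq % 81) // 9,
            father=uniq % 9,
            genotype=np.full(uniq.size, -1),
            number=sums,
            age=np.zeros(uniq.size),
            dd=np.zeros(uniq.size),
        )
        world.eggs = CohortTable.concat([world.eggs, new_eggs])

    m.ovi_day[ovi_idx] += 1
    spent = np.zeros(len(m), dtype=bool)
    spent[ovi_idx] = (m.ovi_day[ovi_idx] >= ovi.max_days) | (m.fert[ovi_idx] <= 0)
    tally["ovi_spent"] = int(spent.sum())
    if spent.any():
        world.moths = m.select(~spent)


# ---------------------------------------------------------------------------
# run / replicate
# ---------------------------------------------------------------------------

def run(config: SimConfig, seed: int | None = None) -> RunResult:
    """Execute one full run and collect the daily census.

    ``seed`` overrides ``config.seed`` for the agent RNG (the synthetic
    temperature series stays tied to the config's base seed so replicates
    share one weather realisation, as with a fixed station record).
    """
    seed = config.seed if seed is None else seed
    layout = make_layout(config.layout, config.geometry)
    world = initialize(config, layout, seed=seed)
    n_days = config.horizon_days
    n_sky = config.geometry.n_sky

    eggs_total = np.zeros(n_days + 1, dtype=np.int64)
    larvae_total = np.zeros(n_days + 1, dtype=np.int64)
    adults_total = np.zeros(n_days + 1, dtype=np.int64)
    adults_by_class = np.zeros((n_days + 1, 9), dtype=np.int64)
    adults_by_sky = np.zeros((n_days + 1, n_sky), dtype=np.int32)
    resistant_by_sky = np.zeros((n_days + 1, n_sky), dtype=np.int32)
    tallies = {k: np.zeros(n_days + 1, dtype=np.int64) for k in _TALLY_KEYS}
    res_mask = fully_resistant_classes(config.bt)

    def record(day: int) -> None:
        eggs_total[day] = world.eggs.total()
        larvae_total[day] = world.larvae.total()
        m = world.moths
        adults_total[day] = len(m)
        if len(m):
            adults_by_class[day] = np.bincount(m.g, minlength=9)
            adults_by_sky[day] = m.count_by_sky(n_sky)
            resistant = res_mask[m.g]
            resistant_by_sky[day] = m.count_by_sky(n_sky, resistant)

    record(0)
    for day in range(1, n_days + 1):
        day_tally = step_day(world, day)
        for k, v in day_tally.items():
            tallies[k][day] = v
        record(day)

    return RunResult(
        seed=seed,
        layout_kind=config.layout.kind,
        h_target=config.layout.h,
        achieved_fraction=layout.achieved,
        horizon_days=n_days,
        warmup_days=config.warmup_days,
        eggs_total=eggs_total,
        larvae_total=larvae_total,
        adults_total=adults_total,
        adults_by_class=adults_by_class,
        resistant_adults=adults_by_class[:, res_mask].sum(axis=1),
        adults_by_sky=adults_by_sky,
        resistant_by_sky=resistant_by_sky,
        tallies=tallies,
        sky_shape=config.geometry.sky_shape,
    )


def replicate(config: SimConfig, n: int | None = None) -> list[RunResult]:
    """Run ``n`` independent replicates with seeds ``seed, seed+1, ...``."""
    n = config.n_replicates if n is None else n
    return [run(config, seed=config.seed + i) for i in range(n)]
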