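"""Immature-stage dynamics: egg and larval cohorts, selection, emergence.

Eggs and larvae are not individual agents: clutches laid in the same ground
cell on the same day by the same parental pairing are pooled into *cohorts*
that carry a count.  Egg cohorts keep the parental genotypes; offspring
genotypes are realised (multinomially over the Mendelian cross classes) at
hatch, so that Bt selection — applied once, at stalk entry — acts on actual
genotypes.  Daily mortalities are binomial thinnings, which keeps counts
integral and preserves demographic stochasticity.

Stage transitions are driven by accumulated degree-days.  The whole-stage
in-stalk larval mortality is spread over the stage in degree-day time:
each day a cohort survives with probability ``(1 - m) ** (dd / threshold)``
so that the product over a completed stage is exactly ``1 - m``.

Two interfaces are provided: single-cohort/single-moth operations
(:func:`update_eggs`, :func:`establish_larvae`, :func:`emerge_moths`,
:func:`update_moth`) built on the same vectorised kernels the simulation
engine applies to whole tables of cohorts at once (:class:`CohortTable`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genetics import (
    BtParams,
    CROSS_TABLE,
    Genotype,
    class_counts,
    class_index,
    survival_by_class,
)

__all__ = [
    "MortalityParams",
    "Cohort",
    "Moth",
    "CohortTable",
    "update_eggs",
    "establish_larvae",
    "emerge_moths",
    "update_moth",
    "egg_step",
    "hatch_and_establish",
    "larva_step",
]

EGG, LARVA = 0, 1


@dataclass(frozen=True)
class MortalityParams:
    """Background (non-Bt) mortalities.

    ``egg_daily`` and ``moth_daily`` are per-day probabilities;
    ``larva_outside`` applies once at hatch (establishment failure before
    boring into a stalk) and ``larva_inside_stage`` is a whole-stage
    mortality for the in-stalk larval + pupal period.
    """

    egg_daily: float = 0.03
    larva_outside: float = 0.90
    larva_inside_stage: float = 0.10
    moth_daily: float = 0.20

    def __post_init__(self):
        for name in ("egg_daily", "larva_outside", "larva_inside_stage", "moth_daily"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class Cohort:
    """A batch of same-age immatures sharing parental genomes and a cell.

    ``genotype`` is None while unresolved (egg stage); resolved larval
    cohorts are homogeneous in genotype.  ``stage2`` marks larvae that have
    entered a stalk and count against the cell's stalk capacity.
    """

    stage: str  # "egg" | "larva"
    female_gene: Genotype
    male_gene: Genotype
    number: int
    age: int = 0
    dd: float = 0.0  # degree-days accumulated in the current stage
    stage2: bool = False
    genotype: Genotype | None = None
    survival_rate: float = 0.97  # daily egg survival (1 - egg_daily)

    def __post_init__(self):
        if self.number < 0:
            raise ValueError("cohort number must be non-negative")


@dataclass
class Moth:
    """An individual adult: the only individually represented life stage."""

    gender: str  # "F" | "M"
    genotype: Genotype
    age: int = 0
    fertility: int = 0  # remaining eggs (females)
    times_mated: int = 0  # males
    state: str = "flying"  # flying | ovipositing | dead
    mate_genotype: Genotype | None = None


# ---------------------------------------------------------------------------
# vectorised cohort table
# ---------------------------------------------------------------------------

_COLS = ("stage", "cell", "mother", "father", "genotype", "number", "age", "dd")
_DTYPES = dict(
    stage=np.int8, cell=np.int64, mother=np.int8, father=np.int8,
    genotype=np.int8, number=np.int64, age=np.int32, dd=np.float64,
)


class CohortTable:
    """Struct-of-arrays store for cohorts; the engine's working container.

    Egg rows use ``mother``/``father`` genotype classes (0..8) and carry
    ``genotype = -1``; larval rows have a resolved ``genotype`` class.
    """

    def __init__(self, **cols):
        n = len(cols["number"]) if cols else 0
        for name in _COLS:
            arr = np.asarray(cols.get(name, np.zeros(n)), dtype=_DTYPES[name])
            setattr(self, name, arr)

    @classmethod
    def empty(cls) -> "CohortTable":
        return cls(**{name: np.array([], dtype=_DTYPES[name]) for name in _COLS})

    def __len__(self) -> int:
        return self.number.size

    def select(self, mask) -> "CohortTable":
        return CohortTable(**{c: getattr(self, c)[mask] for c in _COLS})

    @staticmethod
    def concat(tables) -> "CohortTable":
        tables = [t for t in tables if len(t)]
        if not tables:
            return CohortTable.empty()
        return CohortTable(
            **{c: np.concatenate([getattr(t, c) for t in tables]) for c in _COLS}
        )

    def total(self) -> int:
        return int(self.number.sum())

    def count_by_cell(self, n_cells: int) -> np.ndarray:
        out = np.zeros(n_cells, dtype=np.int64)
        np.add.at(out, self.cell, self.number)
        return out


# ---------------------------------------------------------------------------
# daily kernels
# ---------------------------------------------------------------------------

def egg_step(
    eggs: CohortTable,
    day_dd: float,
    hatch_threshold: float,
    mort: MortalityParams,
    rng: np.random.Generator,
) -> tuple[CohortTable, CohortTable, int]:
    """One day for all egg cohorts.

    Applies daily binomial mortality, ages cohorts and accumulates
    degree-days; cohorts reaching the hatch threshold are split off.
    Returns ``(still_eggs, hatched, deaths)``; empty cohorts are dropped.
    """
    if not len(eggs):
        return eggs, CohortTable.empty(), 0
    survivors = rng.binomial(eggs.number, 1.0 - mort.egg_daily)
    deaths = int(eggs.number.sum() - survivors.sum())
    eggs = CohortTable(
        stage=eggs.stage, cell=eggs.cell, mother=eggs.mother, father=eggs.father,
        genotype=eggs.genotype, number=survivors, age=eggs.age + 1,
        dd=eggs.dd + day_dd,
    )
    eggs = eggs.select(eggs.number > 0)
    ready = eggs.dd >= hatch_threshold
    return eggs.select(~ready), eggs.select(ready), deaths


def hatch_and_establish(
    hatched: CohortTable,
    is_bt: np.ndarray,
    remaining_capacity: np.ndarray,
    bt: BtParams,
    mort: MortalityParams,
    rng: np.random.Generator,
) -> tuple[CohortTable, dict]:
    """Turn hatched egg cohorts into established in-stalk larval cohorts.

    Three filters act in sequence on each hatchling: (i) establishment
    mortality outside the stalk, (ii) on Bt cells, per-genotype Bt kill at
    first feeding (the high-dose event), (iii) the cell's remaining stalk
    capacity — overflow individuals die.  Genotypes are realised here by a
    multinomial draw over the parental cross distribution, so selection
    acts on realised genotypes.  When a cell's same-day arrivals exceed its
    remaining capacity the survivors are drawn uniformly at random from all
    arrivals (multivariate hypergeometric), which keeps the cap exactly
    genotype-neutral even for rare classes.

    ``remaining_capacity`` (per ground cell) is reduced in place.
    Returns the new larval rows and a tally dict of deaths by cause.
    """
    tally = dict(outside=0, bt=0, overflow=0)
    if not len(hatched):
        return CohortTable.empty(), tally

    n0 = hatched.number
    n1 = rng.binomial(n0, 1.0 - mort.larva_outside)
    tally["outside"] = int(n0.sum() - n1.sum())

    pvals = CROSS_TABLE[hatched.mother, hatched.father]
    counts = rng.multinomial(n1, pvals)  # (rows, 9)

    on_bt = is_bt[hatched.cell]
    if on_bt.any():
        surv = survival_by_class(bt)
        kept = counts.copy()
        kept[on_bt] = rng.binomial(counts[on_bt], surv[None, :])
        tally["bt"] = int(counts.sum() - kept.sum())
        counts = kept

    entering = counts.sum(axis=1)
    cell_tot = np.zeros(remaining_capacity.size, dtype=np.int64)
    np.add.at(cell_tot, hatched.cell, entering)
    counts_kept = counts
    over = cell_tot > remaining_capacity
    if over.any():
        counts_kept = counts.copy()
        row_over = np.nonzero(over[hatched.cell])[0]
        order = row_over[np.argsort(hatched.cell[row_over], kind="stable")]
        cells, starts = np.unique(hatched.cell[order], return_index=True)
        bounds = np.append(starts, order.size)
        for ci, cell in enumerate(cells):
            rows = order[bounds[ci] : bounds[ci + 1]]
            room = int(min(remaining_capacity[cell], cell_tot[cell]))
            colors = counts[rows].ravel()
            kept = rng.multivariate_hypergeometric(colors, room)
            counts_kept[rows] = kept.reshape(-1, 9)
    tally["overflow"] = int(counts.sum() - counts_kept.sum())

    placed = np.zeros_like(cell_tot)
    np.add.at(placed, hatched.cell, counts_kept.sum(axis=1))
    remaining_capacity -= placed

    rows, classes = np.nonzero(counts_kept)
    larvae = CohortTable(
        stage=np.full(rows.size, LARVA),
        cell=hatched.cell[rows],
        mother=hatched.mother[rows],
        father=hatched.father[rows],
        genotype=classes,
        number=counts_kept[rows, classes],
        age=np.zeros(rows.size),
        dd=np.zeros(rows.size),
    )
    return larvae, tally


def larva_step(
    larvae: CohortTable,
    day_dd: float,
    eclosion_threshold: float,
    mort: MortalityParams,
    rng: np.random.Generator,
) -> tuple[CohortTable, CohortTable, int]:
    """One day for all in-stalk larval/pupal cohorts.

    The whole-stage mortality is applied as a daily thinning with survival
    ``(1 - m) ** (day_dd / threshold)``, whose product over a completed
    stage equals ``1 - m`` regardless of how temperature paces the stage.
    Returns ``(still_larvae, emerged, deaths)``.
    """
    if not len(larvae):
        return larvae, CohortTable.empty(), 0
    p_surv = (1.0 - mort.larva_inside_stage) ** (day_dd / eclosion_threshold)
    survivors = rng.binomial(larvae.number, p_surv)
    deaths = int(larvae.number.sum() - survivors.sum())
    larvae = CohortTable(
        stage=larvae.stage, cell=larvae.cell, mother=larvae.mother,
        father=larvae.father, genotype=larvae.genotype, number=survivors,
        age=larvae.age + 1, dd=larvae.dd + day_dd,
    )
    larvae = larvae.select(larvae.number > 0)
    ready = larvae.dd >= eclosion_threshold
    return larvae.select(~ready), larvae.select(ready), deaths


# ---------------------------------------------------------------------------
# single-cohort / single-moth API
# ---------------------------------------------------------------------------

def _class_of(g: Genotype) -> int:
    return int(class_index(*g.r_counts))


def update_eggs(
    cohort: Cohort,
    rng: np.random.Generator,
    day_dd: float = 0.0,
    hatch_threshold: float = 60.0,
    mort: MortalityParams | None = None,
) -> Cohort | None:
    """One day for a single egg cohort; returns None once empty.

    The cohort is promoted to a (not yet established) larval cohort when its
    accumulated degree-days reach the hatch threshold.
    """
    if cohort.stage != "egg":
        raise ValueError("update_eggs requires an egg cohort")
    mort = mort or MortalityParams(egg_daily=1.0 - cohort.survival_rate)
    n = int(rng.binomial(cohort.number, 1.0 - mort.egg_daily))
    if n == 0:
        return None
    dd = cohort.dd + day_dd
    if dd >= hatch_threshold:
        return replace(cohort, stage="larva", number=n, age=0, dd=0.0, stage2=False)
    return replace(cohort, number=n, age=cohort.age + 1, dd=dd)


def establish_larvae(
    cohort: Cohort,
    cell,
    bt: BtParams,
    rng: np.random.Generator,
    mort: MortalityParams | None = None,
) -> list[Cohort]:
    """Establishment of a newly hatched cohort on a field cell.

    Returns the resulting in-stalk cohorts, one per realised genotype
    class (possibly empty).  ``cell`` must expose ``variety`` and
    ``stalk_capacity``.
    """
    if cohort.stage2:
        raise ValueError("cohort already established")
    mort = mort or MortalityParams()
    is_bt = np.array([cell.variety == "bt"])
    capacity = np.array([int(cell.stalk_capacity)], dtype=np.float64)
    table = CohortTable(
        stage=[EGG], cell=[0],
        mother=[_class_of(cohort.female_gene)],
        father=[_class_of(cohort.male_gene)],
        genotype=[-1], number=[cohort.number], age=[0], dd=[0.0],
    )
    larvae, _ = hatch_and_establish(table, is_bt, capacity, bt, mort, rng)
    out = []
    for i in range(len(larvae)):
        r1, r2 = class_counts(int(larvae.genotype[i]))
        out.append(
            replace(
                cohort,
                stage="larva",
                number=int(larvae.number[i]),
                stage2=True,
                genotype=Genotype.from_counts(int(r1), int(r2)),
                age=0,
                dd=0.0,
            )
        )
    return out


def emerge_moths(cohort: Cohort, rng: np.random.Generator) -> list[Moth]:
    """Eclosion: every survivor becomes an adult with a 1:1 sex ratio.

    Cohorts whose genotype was never resolved (no Bt selection en route)
    draw each emergent's genotype from the parental cross here.
    """
    moths = []
    for _ in range(cohort.number):
        if cohort.genotype is not None:
            g = cohort.genotype
        else:
            from .genetics import inherit

            g = inherit(cohort.female_gene, cohort.male_gene, rng)
        gender = "F" if rng.random() < 0.5 else "M"
        moths.append(Moth(gender=gender, genotype=g))
    return moths


def update_moth(
    moth: Moth, rng: np.random.Generator, mort: MortalityParams | None = None
) -> Moth | None:
    """Daily adult survival check; returns None if the moth dies."""
    mort = mort or MortalityParams()
    if rng.random() < mort.moth_daily:
        return None
    moth.age += 1
    return moth
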