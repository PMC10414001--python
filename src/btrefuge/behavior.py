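"""Adult moth behaviour: biased flight, lek-gated mating, oviposition.

Flight is a biased random walk on the coarse sky grid with a hard
reflective boundary.  Females drift towards moth-dense cells (a proxy for
following male pheromone plumes): each day they jump one sky cell with
probability ``ms1`` or two with ``ms2``, choosing the destination within
the ring with probability proportional to ``(1 + moth count)``.  Males move
one cell with probability ``mm``, weighted by the mean cane height beneath
the candidate cells (taller cane is older and preferred for lekking).

A female mates only in a cell holding a lek — at least 6 males that have
each mated fewer than 5 times; otherwise she relocates to a uniformly
chosen neighbouring cell and tries again the next day.  Males past the
5-mating cap stay in the model and keep contributing to the density bias.
On mating the female is fertilised with a uniform 300-350 egg complement,
descends to a ground cell beneath her sky cell (weighted by cane age), and
lays over up to five days on a fixed share schedule that puts half of her
complement on day 2, with daily clutches clipped to 30-150 eggs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lifecycle import Cohort, Moth

__all__ = [
    "MovementParams",
    "OvipositionParams",
    "MOVEMENT_LEVELS",
    "reflect",
    "ring_offsets",
    "female_move_distribution",
    "male_move_distribution",
    "descend_distribution",
    "move_female_sky",
    "move_male_sky",
    "seek_lek_and_mate",
    "descend",
    "oviposition_amount",
    "oviposit_day",
    "LEK_SIZE",
    "MATING_CAP",
]

LEK_SIZE = 6
MATING_CAP = 5

#: movement-likelihood triples (ms1, ms2, mf, mm) by level; 'average' is default
MOVEMENT_LEVELS = {
    "low": (0.09, 0.01, 0.10, 0.10),
    "average": (0.18, 0.02, 0.20, 0.20),
    "high": (0.40, 0.10, 0.30, 0.30),
}


@dataclass(frozen=True)
class MovementParams:
    """Daily movement probabilities for adults.

    ms1/ms2: female one-/two-sky-cell jump probabilities; mf: female
    ground-cell move likelihood during oviposition; mm: male sky move
    likelihood.  ``bias_exponent`` sharpens (>1) or flattens (<1) the
    softened-linear ``(1 + x)`` attraction weights.
    """

    ms1: float = 0.18
    ms2: float = 0.02
    mf: float = 0.20
    mm: float = 0.20
    bias_exponent: float = 1.0

    def __post_init__(self):
        for name in ("ms1", "ms2", "mf", "mm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ms1 + self.ms2 > 1.0:
            raise ValueError("ms1 + ms2 must not exceed 1")

    @classmethod
    def from_level(cls, level: str, bias_exponent: float = 1.0) -> "MovementParams":
        try:
            ms1, ms2, mf, mm = MOVEMENT_LEVELS[level]
        except KeyError:
            raise ValueError(
                f"movement level must be one of {sorted(MOVEMENT_LEVELS)}"
            ) from None
        return cls(ms1=ms1, ms2=ms2, mf=mf, mm=mm, bias_exponent=bias_exponent)


@dataclass(frozen=True)
class OvipositionParams:
    """Fecundity draw and the five-day laying schedule.

    The share schedule (15/50/15/10/10 % of the initial complement) is the
    simplest one placing half the eggs on day 2 while every daily clutch
    stays inside the 30-150 bounds for the 300-350 fecundity range.
    """

    fecundity_min: int = 300
    fecundity_max: int = 350
    daily_min: int = 30
    daily_max: int = 150
    max_days: int = 5
    shares: tuple[float, ...] = (0.15, 0.50, 0.15, 0.10, 0.10)

    def __post_init__(self):
        if len(self.shares) != self.max_days:
            raise ValueError("shares must have max_days entries")
        if abs(sum(self.shares) - 1.0) > 1e-9:
            raise ValueError("day shares must sum to 1")
        if not 0 < self.fecundity_min <= self.fecundity_max:
            raise ValueError("invalid fecundity range")


# ---------------------------------------------------------------------------
# movement kernels
# ---------------------------------------------------------------------------

def reflect(idx: np.ndarray, n: int) -> np.ndarray:
    """Mirror out-of-range indices back into [0, n) (hard reflective wall)."""
    idx = np.asarray(idx)
    idx = np.where(idx < 0, -idx - 1, idx)
    idx = np.where(idx >= n, 2 * n - idx - 1, idx)
    return idx


def ring_offsets(dist: int) -> np.ndarray:
    """All (dr, dc) offsets at Chebyshev distance exactly ``dist``."""
    offs = [
        (dr, dc)
        for dr in range(-dist, dist + 1)
        for dc in range(-dist, dist + 1)
        if max(abs(dr), abs(dc)) == dist
    ]
    return np.array(offs)


def _ring_distribution(rc, weight_grid, dist, p_ring, beta, out):
    """Add p_ring spread over the reflected ring-``dist`` neighbours of rc,
    weighted by (1 + weight)^beta, into the flat distribution ``out``."""
    R, C = weight_grid.shape
    offs = ring_offsets(dist)
    rr = reflect(rc[0] + offs[:, 0], R)
    cc = reflect(rc[1] + offs[:, 1], C)
    w = (1.0 + weight_grid[rr, cc]) ** beta
    w /= w.sum()
    np.add.at(out, rr * C + cc, p_ring * w)


def female_move_distribution(
    rc: tuple[int, int], density: np.ndarray, params: MovementParams
) -> np.ndarray:
    """Flat destination distribution over sky cells for one flying female.

    Stays put with probability ``1 - ms1 - ms2``; otherwise jumps to a
    ring-1 or ring-2 neighbour weighted by (1 + moth density).  Reflection
    can fold several candidates onto one in-grid cell, whose probabilities
    add.
    """
    R, C = density.shape
    out = np.zeros(R * C)
    out[rc[0] * C + rc[1]] = 1.0 - params.ms1 - params.ms2
    if params.ms1 > 0:
        _ring_distribution(rc, density, 1, params.ms1, params.bias_exponent, out)
    if params.ms2 > 0:
        _ring_distribution(rc, density, 2, params.ms2, params.bias_exponent, out)
    return out


def male_move_distribution(
    rc: tuple[int, int], mean_heights: np.ndarray, params: MovementParams
) -> np.ndarray:
    """Flat destination distribution for one male: ring-1 moves with
    probability ``mm``, weighted by mean cane height below each candidate."""
    R, C = mean_heights.shape
    out = np.zeros(R * C)
    out[rc[0] * C + rc[1]] = 1.0 - params.mm
    if params.mm > 0:
        _ring_distribution(rc, mean_heights, 1, params.mm, params.bias_exponent, out)
    return out


def descend_distribution(ages: np.ndarray) -> np.ndarray:
    """Ground-cell choice under a sky cell: probability prop. to (1 + age)."""
    w = 1.0 + np.asarray(ages, dtype=float).ravel()
    return w / w.sum()


def _sample_flat(p: np.ndarray, shape, rng) -> tuple[int, int]:
    flat = rng.choice(p.size, p=p)
    return int(flat // shape[1]), int(flat % shape[1])


def move_female_sky(cell_rc, sky_density, params, rng) -> tuple[int, int]:
    """Sample one day's sky move for a flying female at ``cell_rc``."""
    p = female_move_distribution(cell_rc, sky_density, params)
    return _sample_flat(p, sky_density.shape, rng)


def move_male_sky(cell_rc, sky_density, mean_heights, params, rng) -> tuple[int, int]:
    """Sample one day's sky move for a male at ``cell_rc``."""
    p = male_move_distribution(cell_rc, mean_heights, params)
    return _sample_flat(p, mean_heights.shape, rng)


# ---------------------------------------------------------------------------
# mating, descent, oviposition
# ---------------------------------------------------------------------------

def uniform_neighbor(rc, shape, rng) -> tuple[int, int]:
    """A uniformly chosen reflected ring-1 neighbour (lek-search move)."""
    offs = ring_offsets(1)
    dr, dc = offs[rng.integers(len(offs))]
    return (
        int(reflect(np.array(rc[0] + dr), shape[0])),
        int(reflect(np.array(rc[1] + dc), shape[1])),
    )


def seek_lek_and_mate(
    female: Moth,
    cell_rc: tuple[int, int],
    males: list[Moth],
    sky_shape: tuple[int, int],
    rng: np.random.Generator,
    ovi: OvipositionParams | None = None,
):
    """Lek check and mating for one female.

    If her cell holds at least ``LEK_SIZE`` males below the ``MATING_CAP``
    she picks one uniformly, is fertilised with a uniform integer
    complement, and switches to the oviposition phase; otherwise she moves
    to a uniform neighbouring sky cell without mating.  Returns
    ``(mated, new_cell_rc)``.
    """
    ovi = ovi or OvipositionParams()
    eligible = [m for m in males if m.times_mated < MATING_CAP]
    if len(eligible) >= LEK_SIZE:
        mate = eligible[rng.integers(len(eligible))]
        mate.times_mated += 1
        female.fertility = int(rng.integers(ovi.fecundity_min, ovi.fecundity_max + 1))
        female.mate_genotype = mate.genotype
        female.state = "ovipositing"
        return True, cell_rc
    return False, uniform_neighbor(cell_rc, sky_shape, rng)


def descend(sky_rc, ground_ages: np.ndarray, geom, rng) -> tuple[int, int]:
    """Pick the ground cell a newly mated female descends to.

    ``ground_ages`` is the full ground-grid age array; the choice is among
    the cells beneath her sky cell, biased towards older cane.
    """
    k = geom.nesting
    r0, c0 = sky_rc[0] * k, sky_rc[1] * k
    block = np.asarray(ground_ages)[r0 : r0 + k, c0 : c0 + k]
    p = descend_distribution(block)
    flat = rng.choice(k * k, p=p)
    return r0 + int(flat // k), c0 + int(flat % k)


def oviposition_amount(initial_fertility, remaining, day_index, params=None):
    """Eggs laid on oviposition day ``day_index`` (0-based); vectorised.

    The day's share of the *initial* complement is clipped to the daily
    bounds, then to the remaining fertility.  Past the last schedule day
    the amount is zero.
    """
    params = params or OvipositionParams()
    F = np.asarray(initial_fertility, dtype=np.int64)
    rem = np.asarray(remaining, dtype=np.int64)
    day = np.asarray(day_index)
    share = np.zeros(day.shape if day.shape else (1,))
    valid = day < params.max_days
    shares = np.asarray(params.shares)
    share = np.where(valid, shares[np.minimum(day, params.max_days - 1)], 0.0)
    amt = np.rint(share * F).astype(np.int64)
    amt = np.clip(amt, params.daily_min, params.daily_max)
    amt = np.where(valid, np.minimum(amt, rem), 0)
    return amt if amt.shape else int(amt)


def oviposit_day(
    female: Moth,
    cell_rc: tuple[int, int],
    params: OvipositionParams,
    rng: np.random.Generator,
    day_index: int | None = None,
    initial_fertility: int | None = None,
) -> Cohort | None:
    """Lay one day's clutch for an ovipositing female into her ground cell.

    Returns the new egg :class:`~btrefuge.lifecycle.Cohort` (or None once
    spent).  The female dies after the last schedule day or when her
    fertility is exhausted; the engine handles the accompanying ground-cell
    move (probability ``mf``) when the current cell's stalk capacity is
    full.
    """
    if female.state != "ovipositing" or female.mate_genotype is None:
        raise ValueError("female is not in the ovipositing state")
    if female.fertility <= 0:
        female.state = "dead"
        return None
    day = female.age if day_index is None else day_index
    F0 = initial_fertility if initial_fertility is not None else female.fertility
    amt = int(
        oviposition_amount(
            np.array([F0]), np.array([female.fertility]), np.array([day]), params
        )[0]
    )
    female.fertility -= amt
    if day + 1 >= params.max_days or female.fertility <= 0:
        female.state = "dead"
    if amt <= 0:
        return None
    return Cohort(
        stage="egg",
        female_gene=female.genotype,
        male_gene=female.mate_genotype,
        number=amt,
    )
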