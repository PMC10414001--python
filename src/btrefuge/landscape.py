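"""Two-layer field geometry, refuge layout generators, and cane state.

The simulated farm is a rectangle of sugarcane tiled twice: a fine *ground*
grid (100 m2 cells by default) holding field state, eggs, larvae and
ovipositing females, and a coarse *sky* grid (2,500 m2 cells, each exactly
atop a 5 x 5 block of ground cells) in which adult moths fly and mate.  The
boundary is a hard reflective wall.

Each ground cell is planted either with Bt cane or with conventional
(refuge) cane.  The refuge mask is produced by one of a family of
deterministic layout generators — a single centred block, fractally
distributed 4/16 blocks, full-height linear "bracket" bars, quadrant /
sub-square border frames, and border-plus-block hybrids — parameterised by
the total refuge proportion ``h``.  Because blocks are rounded to whole
cells the achieved refuge fraction can differ slightly from ``h``; it is
always computed from the generated mask and reported alongside it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GridGeometry",
    "FieldCell",
    "GrowthParams",
    "LayoutSpec",
    "Layout",
    "LAYOUT_KINDS",
    "make_layout",
    "sky_of",
    "grounds_of",
    "grow_cell",
    "harvest",
    "Field",
]

LAYOUT_KINDS = (
    "single_block",
    "blocks4",
    "blocks16",
    "linear1",
    "linear2",
    "border1",
    "border2",
    "border_block",
    "border_block_revised",
)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _near_square_factors(n: int) -> tuple[int, int]:
    """Factor n as rows*cols with rows <= cols and rows as large as possible."""
    r = int(math.isqrt(n))
    while r > 0 and n % r:
        r -= 1
    return r, n // r


@dataclass(frozen=True)
class GridGeometry:
    """Nested ground/sky grid dimensions derived from cell and total areas.

    The default 25 ha farm with 100 m2 ground cells and 2,500 m2 sky cells
    yields a 50 x 50 ground grid under a 10 x 10 sky grid with a 5 x 5
    nesting.  Other total areas are laid out as near-square rectangles that
    preserve the nesting exactly.
    """

    ground_cell_area: float = 100.0
    sky_cell_area: float = 2500.0
    total_area_ha: float = 25.0

    def __post_init__(self):
        ratio = self.sky_cell_area / self.ground_cell_area
        k = round(math.sqrt(ratio))
        if k * k != ratio:
            raise ValueError(
                "sky_cell_area / ground_cell_area must be a perfect square, "
                f"got {ratio}"
            )
        n_ground = self.total_area_ha * 1e4 / self.ground_cell_area
        if abs(n_ground - round(n_ground)) > 1e-9:
            raise ValueError("ground cells must exactly tile the total area")
        n_sky = round(n_ground) / (k * k)
        if abs(n_sky - round(n_sky)) > 1e-9:
            raise ValueError("sky cells must exactly tile the total area")

    @property
    def nesting(self) -> int:
        """Side of the square of ground cells beneath one sky cell."""
        return round(math.sqrt(self.sky_cell_area / self.ground_cell_area))

    @property
    def sky_shape(self) -> tuple[int, int]:
        n_sky = round(self.total_area_ha * 1e4 / self.sky_cell_area)
        return _near_square_factors(n_sky)

    @property
    def ground_shape(self) -> tuple[int, int]:
        sr, sc = self.sky_shape
        return sr * self.nesting, sc * self.nesting

    @property
    def n_ground(self) -> int:
        r, c = self.ground_shape
        return r * c

    @property
    def n_sky(self) -> int:
        r, c = self.sky_shape
        return r * c


def sky_of(ground_rc: tuple[int, int], geom: GridGeometry) -> tuple[int, int]:
    """Sky cell above a ground cell (integer division by the nesting side)."""
    r, c = ground_rc
    gr, gc = geom.ground_shape
    if not (0 <= r < gr and 0 <= c < gc):
        raise IndexError(f"ground index {ground_rc} outside {geom.ground_shape}")
    k = geom.nesting
    return (r // k, c // k)


def grounds_of(sky_rc: tuple[int, int], geom: GridGeometry) -> list[tuple[int, int]]:
    """The nesting x nesting ground cells beneath a sky cell."""
    r, c = sky_rc
    sr, sc = geom.sky_shape
    if not (0 <= r < sr and 0 <= c < sc):
        raise IndexError(f"sky index {sky_rc} outside {geom.sky_shape}")
    k = geom.nesting
    return [(r * k + i, c * k + j) for i in range(k) for j in range(k)]


# ---------------------------------------------------------------------------
# refuge layouts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayoutSpec:
    kind: str
    h: float

    def __post_init__(self):
        if self.kind not in LAYOUT_KINDS:
            raise ValueError(f"unknown layout kind {self.kind!r}")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError(f"refuge proportion h must be in [0, 1], got {self.h}")


@dataclass(frozen=True)
class Layout:
    """A generated refuge mask plus the refuge fraction it actually achieves."""

    spec: LayoutSpec
    mask: np.ndarray  # bool, True = refuge
    achieved: float

    def to_text(self) -> str:
        """Plain-text grid, one row per line, 'R' refuge / 'B' Bt."""
        chars = np.where(self.mask, "R", "B")
        return "\n".join("".join(row) for row in chars)


def _block_side(target_cells: float, n_blocks: int, kind: str) -> int:
    side = round(math.sqrt(target_cells / n_blocks))
    if side < 1:
        raise ValueError(
            f"h too small for this distribution at this resolution ({kind})"
        )
    return side


def _place_square(mask, r0, c0, height, width, side):
    """Centred side x side square inside the [r0:r0+height, c0:c0+width] box.

    Half-cell offsets round half-to-even on the global coordinate, which
    makes mirrored boxes place mirrored blocks (so the fractal layouts stay
    symmetric under grid rotation).
    """
    side_r = min(side, height)
    side_c = min(side, width)
    top = round((2 * r0 + height - side_r) / 2)
    left = round((2 * c0 + width - side_c) / 2)
    mask[top : top + side_r, left : left + side_c] = True


def _place_square_at(mask, rc, cc, side):
    """side x side square centred at (rc, cc), clipped to the grid."""
    R, C = mask.shape
    top = int(round(rc - side / 2.0))
    left = int(round(cc - side / 2.0))
    top = min(max(top, 0), R - min(side, R))
    left = min(max(left, 0), C - min(side, C))
    mask[top : top + min(side, R), left : left + min(side, C)] = True


def _cuts(n: int, parts: int) -> list[int]:
    return [round(i * n / parts) for i in range(parts + 1)]


def _fractal_blocks(mask, target, parts, kind):
    """Centred square of equal area in each of parts x parts sub-rectangles."""
    R, C = mask.shape
    side = _block_side(target, parts * parts, kind)
    rcuts, ccuts = _cuts(R, parts), _cuts(C, parts)
    for i in range(parts):
        for j in range(parts):
            _place_square(
                mask,
                rcuts[i],
                ccuts[j],
                rcuts[i + 1] - rcuts[i],
                ccuts[j + 1] - ccuts[j],
                side,
            )


def _bars(mask, centers_cols, rows, width):
    R, C = mask.shape
    r0, r1 = rows
    for cc in centers_cols:
        left = int(round(cc - width / 2.0))
        left = min(max(left, 0), C - width)
        mask[r0:r1, left : left + width] = True


def _lattice(shape, parts, width) -> np.ndarray:
    """Frames around every parts x parts sub-square, drawn as shared lines of
    the given width along the sub-square boundaries (outer border included)."""
    R, C = shape
    mask = np.zeros(shape, dtype=bool)
    for cuts, axis_len, axis in ((_cuts(R, parts), R, 0), (_cuts(C, parts), C, 1)):
        for idx, cut in enumerate(cuts):
            if idx == 0:
                lo = 0
            elif idx == len(cuts) - 1:
                lo = axis_len - width
            else:
                lo = min(max(cut - width // 2, 0), axis_len - width)
            sl = slice(lo, lo + width)
            if axis == 0:
                mask[sl, :] = True
            else:
                mask[:, sl] = True
    return mask


def make_layout(spec: LayoutSpec, geom: GridGeometry) -> Layout:
    """Generate the refuge mask for a layout family member.

    All generators are deterministic (no RNG): the same (kind, h, geometry)
    always yields the identical mask.  Raises if ``h`` is too small for any
    single block of the requested distribution to span at least one cell.
    """
    R, C = geom.ground_shape
    n = R * C
    target = spec.h * n
    mask = np.zeros((R, C), dtype=bool)
    kind = spec.kind

    if spec.h == 0.0:
        return Layout(spec, mask, 0.0)

    if kind == "single_block":
        _place_square(mask, 0, 0, R, C, _block_side(target, 1, kind))
    elif kind == "blocks4":
        _fractal_blocks(mask, target, 2, kind)
    elif kind == "blocks16":
        _fractal_blocks(mask, target, 4, kind)
    elif kind == "linear1":
        width = max(1, round(target / (2 * R)))
        _bars(mask, [C / 3.0, 2 * C / 3.0], (0, R), width)
    elif kind == "linear2":
        # four half-height bars, the lower pair staggered into the gaps
        width = max(1, round(target / (4 * (R // 2))))
        _bars(mask, [C / 3.0, 2 * C / 3.0], (0, R // 2), width)
        _bars(mask, [C / 6.0, 5 * C / 6.0], (R // 2, R), width)
    elif kind == "border1":
        # frame width chosen to best match h among feasible widths
        best = None
        for w in range(1, max(2, R // 4)):
            cand = _lattice((R, C), 2, w)
            err = abs(cand.mean() - spec.h)
            if best is None or err < best[0]:
                best = (err, cand)
        mask = best[1]
    elif kind == "border2":
        mask = _lattice((R, C), 4, 1)
    elif kind in ("border_block", "border_block_revised"):
        corners = kind == "border_block_revised"
        n_blocks = 20 if corners else 16
        side = _block_side(target, n_blocks, kind)
        rcuts, ccuts = _cuts(R, 4), _cuts(C, 4)
        # 12 edge blocks flush with the boundary at the internal cut positions
        for cc in ccuts[1:4]:
            _place_square_at(mask, side / 2.0, cc, side)
            _place_square_at(mask, R - side / 2.0, cc, side)
        for rc in rcuts[1:4]:
            _place_square_at(mask, rc, side / 2.0, side)
            _place_square_at(mask, rc, C - side / 2.0, side)
        # 4 central blocks at the quadrant centres
        for rc in (R / 4.0, 3 * R / 4.0):
            for cc in (C / 4.0, 3 * C / 4.0):
                _place_square_at(mask, rc, cc, side)
        if corners:
            for rc in (side / 2.0, R - side / 2.0):
                for cc in (side / 2.0, C - side / 2.0):
                    _place_square_at(mask, rc, cc, side)
    else:  # pragma: no cover - guarded by LayoutSpec
        raise ValueError(kind)

    return Layout(spec, mask, float(mask.mean()))


# ---------------------------------------------------------------------------
# cane state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthParams:
    """Cane growth and carrying-capacity parameters.

    Capacities scale linearly with height: a fully grown cell supports at
    most ``stalk_capacity_max`` larvae in its stalks; ``moth_capacity_max``
    is carried for completeness but not used as a hard cap.
    """

    growth_rate: float = 0.1  # cm per degree-day above cane_base
    max_height: float = 300.0  # cm
    stalk_capacity_max: int = 120  # larvae per ground cell at full height
    moth_capacity_max: int = 60
    harvest_larva_survival: float = 0.0


@dataclass(frozen=True)
class FieldCell:
    """A single 100 m2 cell of cane: its age, variety, height and capacities."""

    variety: str  # "bt" | "refuge"
    age: int = 0  # days since planting / last harvest
    height: float = 0.0  # cm
    growth: GrowthParams = field(default_factory=GrowthParams)
    stressed_rating: float = 0.0  # carried but fixed at 0 by default

    def __post_init__(self):
        if self.variety not in ("bt", "refuge"):
            raise ValueError("variety must be 'bt' or 'refuge'")
        if self.height < 0:
            raise ValueError("height must be non-negative")

    @property
    def stalk_capacity(self) -> int:
        g = self.growth
        return math.ceil(g.stalk_capacity_max * min(self.height, g.max_height) / g.max_height)

    @property
    def moth_capacity(self) -> int:
        g = self.growth
        return math.ceil(g.moth_capacity_max * min(self.height, g.max_height) / g.max_height)


def grow_cell(cell: FieldCell, day_dd: float) -> FieldCell:
    """One day of growth: height rises by growth_rate x degree-days (capped)."""
    if day_dd < 0:
        raise ValueError("day_dd must be non-negative")
    g = cell.growth
    new_height = min(cell.height + g.growth_rate * day_dd, g.max_height)
    return replace(cell, height=new_height, age=cell.age + 1)


def harvest(cell: FieldCell, cohorts: list, rng=None) -> tuple[FieldCell, list]:
    """Cut the cell: age and height reset, resident immatures destroyed.

    With the default harvest survival of 0 every egg and larval cohort in
    the cell is removed; a non-zero survival thins larval cohorts
    binomially instead (eggs on cut cane are always lost).
    """
    reset = replace(cell, age=0, height=0.0)
    surv = cell.growth.harvest_larva_survival
    if surv <= 0.0:
        return reset, []
    out = []
    for coh in cohorts:
        if getattr(coh, "stage", "larva") == "egg":
            continue
        n = rng.binomial(coh.number, surv) if rng is not None else round(coh.number * surv)
        if n > 0:
            out.append(replace(coh, number=int(n)))
    return reset, out


class Field:
    """Vectorised cane state over the whole ground grid.

    Thin array-of-cells counterpart of :class:`FieldCell` used by the
    simulation engine; all cells share one planting/harvest calendar.
    """

    def __init__(self, layout: Layout, geom: GridGeometry,
                 growth: GrowthParams | None = None,
                 initial_age: int = 0, initial_height: float = 0.0):
        self.geom = geom
        self.layout = layout
        self.growth = growth or GrowthParams()
        R, C = geom.ground_shape
        self.refuge = layout.mask.reshape(R, C).copy()
        self.age = np.full(R * C, initial_age, dtype=np.int32)
        self.height = np.full(R * C, float(initial_height))

    def grow(self, day_dd: float) -> None:
        g = self.growth
        np.minimum(self.height + g.growth_rate * day_dd, g.max_height, out=self.height)
        self.age += 1

    def harvest_reset(self) -> None:
        self.age[:] = 0
        self.height[:] = 0.0

    def stalk_capacity(self) -> np.ndarray:
        g = self.growth
        frac = np.minimum(self.height, g.max_height) / g.max_height
        return np.ceil(g.stalk_capacity_max * frac).astype(np.int64)

    def moth_capacity(self) -> np.ndarray:
        g = self.growth
        frac = np.minimum(self.height, g.max_height) / g.max_height
        return np.ceil(g.moth_capacity_max * frac).astype(np.int64)

    def is_bt_flat(self) -> np.ndarray:
        return ~self.refuge.ravel()

    def mean_height_by_sky(self) -> np.ndarray:
        """Mean cane height beneath each sky cell (male movement bias)."""
        k = self.geom.nesting
        sr, sc = self.geom.sky_shape
        R, C = self.geom.ground_shape
        h = self.height.reshape(R, C)
        return h.reshape(sr, k, sc, k).mean(axis=(1, 3))
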