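"""Two-locus resistance genetics for a Bt-exposed insect population.

A genotype carries one pair of alleles (``S`` susceptible / ``R`` resistant)
at each of two loci, one locus per Bt mode of action (MOA).  Selection on a
Bt plant acts independently per mode of action: an individual that does not
express resistance at a locus survives that toxin only with probability
``1 - efficacy_per_moa``, so a pyramided two-MOA plant at 95% efficacy per
toxin kills a fully susceptible individual with probability
``1 - 0.05**2 = 0.9975``.

Inheritance is plain Mendelian segregation: at each locus the offspring
receives one allele drawn uniformly from each parent's pair, with no
linkage, mutation, or sex effects.  The dominance of the resistance trait is
configurable; under the default recessive setting a heterozygote dies on Bt
at the same rate as a susceptible homozygote.

Genotypes are represented compactly as the number of ``R`` alleles per locus
(0, 1 or 2).  The module exposes both a small frozen :class:`Genotype` value
type for single individuals and vectorised kernels (suffix ``_classes``)
that the simulation engine applies to whole cohorts at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Genotype",
    "BtParams",
    "kill_probability",
    "inherit",
    "is_fully_resistant",
    "initial_genotype",
    "N_LOCI",
    "N_CLASSES",
    "class_index",
    "class_counts",
    "class_to_string",
    "survival_by_class",
    "cross_distribution",
    "CROSS_TABLE",
]

N_LOCI = 2
#: number of two-locus genotype classes: 3 per locus (SS, RS, RR)
N_CLASSES = 9

_ALLELES = frozenset("SR")


def _norm_locus(pair) -> tuple[str, str]:
    a, b = pair
    if a not in _ALLELES or b not in _ALLELES:
        raise ValueError(f"alleles must be 'S' or 'R', got {pair!r}")
    # canonical order: R before S, so heterozygotes print as "RS"
    return (a, b) if (a, b) in (("R", "S"), ("R", "R"), ("S", "S")) else (b, a)


@dataclass(frozen=True)
class Genotype:
    """Immutable two-locus genotype; allele order within a locus is irrelevant."""

    locus1: tuple[str, str]
    locus2: tuple[str, str]

    def __post_init__(self):
        object.__setattr__(self, "locus1", _norm_locus(self.locus1))
        object.__setattr__(self, "locus2", _norm_locus(self.locus2))

    @classmethod
    def from_counts(cls, r1: int, r2: int) -> "Genotype":
        """Build from the number of R alleles at each locus (0, 1 or 2)."""
        pairs = {0: ("S", "S"), 1: ("R", "S"), 2: ("R", "R")}
        return cls(pairs[int(r1)], pairs[int(r2)])

    @classmethod
    def from_string(cls, s: str) -> "Genotype":
        """Parse the serialised ``'RS|SS'`` form (locus1|locus2)."""
        l1, l2 = s.split("|")
        return cls(tuple(l1), tuple(l2))

    @property
    def r_counts(self) -> tuple[int, int]:
        return (self.locus1.count("R"), self.locus2.count("R"))

    def to_string(self) -> str:
        return f"{''.join(self.locus1)}|{''.join(self.locus2)}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


@dataclass(frozen=True)
class BtParams:
    """Bt crop toxicology: MOA count, per-MOA efficacy, trait dominance."""

    moa_count: int = 2
    efficacy_per_moa: float = 0.95
    dominance: str = "recessive"

    def __post_init__(self):
        if not 1 <= self.moa_count <= N_LOCI:
            raise ValueError(
                f"moa_count must be between 1 and {N_LOCI}, got {self.moa_count}"
            )
        if not 0.0 <= self.efficacy_per_moa <= 1.0:
            raise ValueError("efficacy_per_moa must be a probability")
        if self.dominance not in ("recessive", "dominant"):
            raise ValueError("dominance must be 'recessive' or 'dominant'")


# ---------------------------------------------------------------------------
# class-index encoding used by the vectorised engine
# ---------------------------------------------------------------------------

def class_index(r1, r2):
    """Map per-locus R-allele counts to a flat genotype class in 0..8."""
    return 3 * np.asarray(r1) + np.asarray(r2)


def class_counts(idx):
    """Inverse of :func:`class_index`: flat class -> (r1, r2)."""
    idx = np.asarray(idx)
    return idx // 3, idx % 3


_PAIR_STR = {0: "SS", 1: "RS", 2: "RR"}


def class_to_string(idx: int) -> str:
    r1, r2 = int(idx) // 3, int(idx) % 3
    return f"{_PAIR_STR[r1]}|{_PAIR_STR[r2]}"


def _locus_survival(r_count, bt: BtParams):
    """Per-locus survival probability against that locus's toxin."""
    r = np.asarray(r_count)
    if bt.dominance == "dominant":
        expressed = r >= 1
    else:
        expressed = r == 2
    return np.where(expressed, 1.0, 1.0 - bt.efficacy_per_moa)


def survival_by_class(bt: BtParams) -> np.ndarray:
    """Survival probability on a Bt plant for each of the 9 genotype classes.

    Only the first ``moa_count`` loci are under selection; with a single MOA
    the second locus is neutral.
    """
    r1, r2 = class_counts(np.arange(N_CLASSES))
    surv = _locus_survival(r1, bt)
    if bt.moa_count >= 2:
        surv = surv * _locus_survival(r2, bt)
    return surv


def kill_probability(genotype: Genotype, bt: BtParams) -> float:
    """Probability that a Bt plant kills an individual of this genotype.

    Mortality per mode of action is independent; overall kill is
    ``1 - prod(per-locus survival)`` over the active loci.
    """
    r1, r2 = genotype.r_counts
    return float(1.0 - survival_by_class(bt)[class_index(r1, r2)])


def is_fully_resistant(genotype: Genotype, bt: BtParams) -> bool:
    """True iff homozygous R at every locus under selection (active MOA)."""
    counts = genotype.r_counts
    return all(c == 2 for c in counts[: bt.moa_count])


def fully_resistant_classes(bt: BtParams) -> np.ndarray:
    """Boolean mask over the 9 classes marking the fully resistant ones."""
    r1, r2 = class_counts(np.arange(N_CLASSES))
    mask = r1 == 2
    if bt.moa_count >= 2:
        mask &= r2 == 2
    return mask


# ---------------------------------------------------------------------------
# Mendelian inheritance
# ---------------------------------------------------------------------------

def _locus_cross() -> np.ndarray:
    """P(offspring R count | mother R count, father R count) per locus.

    Offspring count is the sum of two independent Bernoulli draws with
    success probabilities m/2 and f/2 (one allele sampled uniformly from
    each parent's pair).
    """
    tab = np.zeros((3, 3, 3))
    for m in range(3):
        for f in range(3):
            pm, pf = m / 2.0, f / 2.0
            tab[m, f, 0] = (1 - pm) * (1 - pf)
            tab[m, f, 1] = pm * (1 - pf) + (1 - pm) * pf
            tab[m, f, 2] = pm * pf
    return tab


_LOCUS_CROSS = _locus_cross()


def _cross_table() -> np.ndarray:
    """(9, 9, 9) table: P(offspring class | mother class, father class)."""
    tab = np.zeros((N_CLASSES, N_CLASSES, N_CLASSES))
    for mi in range(N_CLASSES):
        m1, m2 = mi // 3, mi % 3
        for fi in range(N_CLASSES):
            f1, f2 = fi // 3, fi % 3
            tab[mi, fi] = np.outer(
                _LOCUS_CROSS[m1, f1], _LOCUS_CROSS[m2, f2]
            ).ravel()
    return tab


#: precomputed offspring-class distribution for every parental pairing
CROSS_TABLE = _cross_table()


def cross_distribution(mother_class, father_class) -> np.ndarray:
    """Offspring genotype-class distribution(s) for parental class pairs."""
    return CROSS_TABLE[np.asarray(mother_class), np.asarray(father_class)]


def inherit(mother: Genotype, father: Genotype, rng: np.random.Generator) -> Genotype:
    """Draw one offspring genotype by Mendelian segregation at each locus."""
    m1, m2 = mother.r_counts
    f1, f2 = father.r_counts
    c1 = rng.binomial(1, m1 / 2.0) + rng.binomial(1, f1 / 2.0)
    c2 = rng.binomial(1, m2 / 2.0) + rng.binomial(1, f2 / 2.0)
    return Genotype.from_counts(c1, c2)


# ---------------------------------------------------------------------------
# population initialisation
# ---------------------------------------------------------------------------

_CLASS_OF_GROUP = {
    "susceptible": 0,  # SS|SS
    "heterozygote": 4,  # RS|RS
    "resistant": 8,  # RR|RR
}


def initial_genotype(
    proportions: tuple[float, float, float], rng: np.random.Generator
) -> Genotype:
    """Draw a founder genotype from (susceptible, heterozygote, resistant).

    The drawn class applies identically at both loci, so an initial
    "resistant" founder is homozygous R at every locus (fully resistant).
    """
    p = np.asarray(proportions, dtype=float)
    if p.shape != (3,):
        raise ValueError("proportions must have three entries")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
    group = rng.choice(3, p=p)
    cls = (0, 4, 8)[group]
    return Genotype.from_counts(*class_counts(cls))


def initial_class_quota(n: int, proportions: tuple[float, float, float]) -> np.ndarray:
    """Deterministic founder classes for a batch of ``n`` individuals.

    Largest-remainder apportionment of ``n`` over the three founder groups
    (SS|SS, RS|RS, RR|RR), so e.g. 0.5% resistant in a batch of 1,000 yields
    exactly 5 fully resistant founders.  Returns an array of class indices.
    """
    p = np.asarray(proportions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
    exact = p * n
    counts = np.floor(exact).astype(int)
    short = n - counts.sum()
    if short:
        order = np.argsort(-(exact - counts))
        counts[order[:short]] += 1
    return np.repeat(np.array([0, 4, 8]), counts)
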