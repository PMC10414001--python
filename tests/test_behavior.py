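"""Movement kernels, lek mating, descent and the oviposition schedule."""

import numpy as np
import pytest
from scipy import stats

from btrefuge.behavior import (
    LEK_SIZE,
    MATING_CAP,
    MOVEMENT_LEVELS,
    MovementParams,
    OvipositionParams,
    descend,
    descend_distribution,
    female_move_distribution,
    male_move_distribution,
    move_female_sky,
    oviposit_day,
    oviposition_amount,
    reflect,
    ring_offsets,
    seek_lek_and_mate,
    uniform_neighbor,
)
from btrefuge.genetics import Genotype
from btrefuge.landscape import GridGeometry
from btrefuge.lifecycle import Moth

SS = Genotype.from_string("SS|SS")


def female(state="flying"):
    return Moth("F", SS, state=state)


class TestMovementParams:
    def test_level_triples(self):
        p = MovementParams.from_level("high")
        assert (p.ms1, p.ms2, p.mf, p.mm) == (0.40, 0.10, 0.30, 0.30)
        assert MovementParams.from_level("average") == MovementParams()

    def test_validation(self):
        with pytest.raises(ValueError):
            MovementParams(ms1=0.9, ms2=0.2)
        with pytest.raises(ValueError):
            MovementParams.from_level("extreme")


class TestKernels:
    def test_rings(self):
        assert len(ring_offsets(1)) == 8
        assert len(ring_offsets(2)) == 16

    def test_no_move_probability(self):
        density = np.zeros((10, 10))
        p = female_move_distribution((4, 4), density, MovementParams(ms1=0, ms2=0))
        assert p[4 * 10 + 4] == 1.0

    @pytest.mark.parametrize("rc", [(0, 0), (0, 9), (9, 0), (9, 9), (5, 5)])
    def test_proper_distribution_everywhere(self, rc, rng):
        density = rng.integers(0, 50, (10, 10)).astype(float)
        p = female_move_distribution(rc, density, MovementParams.from_level("high"))
        assert p.min() >= 0
        assert p.sum() == pytest.approx(1.0)

    def test_uniform_density_uniform_ring(self, rng):
        """With flat density the ring-1 destinations are equiprobable."""
        density = np.full((10, 10), 7.0)
        p = female_move_distribution((5, 5), density, MovementParams(ms1=0.4, ms2=0))
        ring = [(5 + dr) * 10 + (5 + dc) for dr, dc in ring_offsets(1)]
        np.testing.assert_allclose(p[ring], 0.05)
        # and sampled counts pass a chi-square uniformity test
        draws = rng.choice(100, size=100_000, p=p)
        counts = np.bincount(draws, minlength=100)[ring]
        _, pval = stats.chisquare(counts)
        assert pval > 1e-3

    def test_density_bias_prefers_crowded_cell(self):
        density = np.zeros((5, 5))
        density[2, 3] = 99.0
        p = female_move_distribution((2, 2), density, MovementParams(ms1=1.0, ms2=0))
        ring = [(2 + dr) * 5 + (2 + dc) for dr, dc in ring_offsets(1)]
        assert p[2 * 5 + 3] == max(p[ring])
        assert p[2 * 5 + 3] / p[2 * 5 + 1] == pytest.approx(100.0)

    def test_male_height_bias(self):
        heights = np.zeros((5, 5))
        heights[1, 1] = 300.0
        p = male_move_distribution((2, 2), heights, MovementParams(mm=0.5))
        ring = [(2 + dr) * 5 + (2 + dc) for dr, dc in ring_offsets(1)]
        assert p[1 * 5 + 1] == max(p[ring])

    def test_male_no_move(self):
        p = male_move_distribution((1, 1), np.zeros((3, 3)), MovementParams(mm=0.0))
        assert p[1 * 3 + 1] == 1.0

    def test_corner_reflection_stays_in_grid(self, rng):
        """No destination ever falls outside the grid, even from corners."""
        density = np.zeros((4, 4))
        p = female_move_distribution((0, 0), density, MovementParams(ms1=0.5, ms2=0.5))
        assert p.sum() == pytest.approx(1.0)  # all mass on valid cells
        for _ in range(100):
            r, c = move_female_sky((0, 0), density, MovementParams.from_level("high"), rng)
            assert 0 <= r < 4 and 0 <= c < 4

    def test_reflect_mirrors(self):
        np.testing.assert_array_equal(reflect(np.array([-2, -1, 0, 5, 6]), 5),
                                      [1, 0, 0, 4, 3])


class TestLek:
    def males(self, n, mated=0):
        out = []
        for _ in range(n):
            m = Moth("M", SS)
            m.times_mated = mated
            out.append(m)
        return out

    def test_five_males_no_lek(self, rng):
        f = female()
        mated, new_cell = seek_lek_and_mate(f, (2, 2), self.males(5), (5, 5), rng)
        assert not mated
        assert new_cell != (2, 2)
        assert f.state == "flying"

    def test_six_males_mate(self, rng):
        f = female()
        males = self.males(6)
        mated, cell = seek_lek_and_mate(f, (2, 2), males, (5, 5), rng)
        assert mated and cell == (2, 2)
        assert f.state == "ovipositing"
        assert 300 <= f.fertility <= 350
        assert sum(m.times_mated for m in males) == 1

    def test_capped_males_dont_count_or_mate(self, rng):
        """A male at the mating cap is never selected and cannot hold a lek."""
        for _ in range(200):
            capped = self.males(1, mated=MATING_CAP)[0]
            males = self.males(9) + [capped]
            f = female()
            mated, _ = seek_lek_and_mate(f, (1, 1), males, (5, 5), rng)
            assert mated
            assert capped.times_mated == MATING_CAP
        # 5 fresh males + 1 capped male is below the lek threshold
        males = self.males(5) + self.males(1, mated=MATING_CAP)
        mated, _ = seek_lek_and_mate(female(), (1, 1), males, (5, 5), rng)
        assert not mated

    def test_failed_search_moves_within_grid(self, rng):
        for _ in range(1000):
            r, c = uniform_neighbor((0, 0), (3, 3), rng)
            assert 0 <= r < 3 and 0 <= c < 3


class TestDescent:
    def test_equal_ages_uniform(self):
        p = descend_distribution(np.zeros((5, 5)))
        np.testing.assert_allclose(p, 1 / 25)

    def test_old_cell_dominates(self):
        ages = np.zeros(25)
        ages[7] = 1000
        p = descend_distribution(ages)
        assert p[7] > 0.97

    def test_descend_lands_under_sky_cell(self, rng):
        geom = GridGeometry()
        ages = np.zeros(geom.ground_shape)
        for _ in range(50):
            r, c = descend((1, 2), ages, geom, rng)
            assert 5 <= r < 10 and 10 <= c < 15

    def test_degenerate_single_cell(self, rng):
        geom = GridGeometry(ground_cell_area=2500, sky_cell_area=2500, total_area_ha=1)
        assert geom.nesting == 1
        ages = np.zeros(geom.ground_shape)
        assert descend((1, 1), ages, geom, rng) == (1, 1)


class TestOviposition:
    def test_day2_clipped_to_150(self, rng):
        """Half of a 320-egg complement exceeds the daily cap and is clipped."""
        f = female("ovipositing")
        f.fertility = 320
        f.mate_genotype = SS
        p = OvipositionParams()
        laid = []
        for day in range(5):
            coh = oviposit_day(f, (0, 0), p, rng, day_index=day, initial_fertility=320)
            laid.append(coh.number if coh else 0)
        assert laid[1] == 150
        assert sum(laid) <= 320
        assert f.state == "dead"

    def test_no_fertility_no_cohort(self, rng):
        f = female("ovipositing")
        f.fertility = 0
        f.mate_genotype = SS
        assert oviposit_day(f, (0, 0), OvipositionParams(), rng) is None
        assert f.state == "dead"

    def test_lifetime_total_bounded_by_draw(self, rng):
        """Total eggs laid never exceed the initial fertility draw (<= 350)."""
        n = 10_000
        p = OvipositionParams()
        F0 = rng.integers(p.fecundity_min, p.fecundity_max + 1, n)
        rem = F0.copy()
        total = np.zeros(n, dtype=np.int64)
        for day in range(p.max_days):
            amt = oviposition_amount(F0, rem, np.full(n, day), p)
            assert (amt >= 0).all()
            rem = rem - amt
            total += amt
        assert (total <= F0).all()
        assert (rem >= 0).all()

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            OvipositionParams(shares=(0.5, 0.5))
        with pytest.raises(ValueError):
            OvipositionParams(shares=(0.2, 0.2, 0.2, 0.2, 0.1))

    def test_unmated_female_cannot_lay(self, rng):
        with pytest.raises(ValueError):
            oviposit_day(female(), (0, 0), OvipositionParams(), rng)


def test_movement_levels_cover_table():
    assert set(MOVEMENT_LEVELS) == {"low", "average", "high"}
    assert MOVEMENT_LEVELS["low"] == (0.09, 0.01, 0.10, 0.10)
    assert LEK_SIZE == 6 and MATING_CAP == 5
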