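"""Cohort dynamics: egg survival, establishment under Bt, eclosion."""

import numpy as np
import pytest

from btrefuge.genetics import BtParams, Genotype, class_index
from btrefuge.landscape import FieldCell, GrowthParams
from btrefuge.lifecycle import (
    Cohort,
    CohortTable,
    Moth,
    MortalityParams,
    EGG,
    egg_step,
    establish_larvae,
    emerge_moths,
    hatch_and_establish,
    larva_step,
    update_eggs,
    update_moth,
)

SS = Genotype.from_string("SS|SS")
HET = Genotype.from_string("RS|RS")


def egg_table(number, mother=0, father=0, cell=0):
    return CohortTable(
        stage=[EGG], cell=[cell], mother=[mother], father=[father],
        genotype=[-1], number=[number], age=[0], dd=[0.0],
    )


class TestEggs:
    def test_daily_mortality_binomial(self, rng):
        """~3% of a 1,000-egg cohort dies per day, within binomial bounds."""
        survivors = []
        for _ in range(50):
            coh = update_eggs(
                Cohort("egg", SS, SS, 1000), rng, day_dd=1.0, hatch_threshold=60
            )
            survivors.append(coh.number)
        mean = np.mean(survivors)
        se = np.sqrt(1000 * 0.97 * 0.03 / 50)
        assert abs(mean - 970) < 4 * se

    def test_zero_mortality_conserves(self, rng):
        coh = Cohort("egg", SS, SS, 500, survival_rate=1.0)
        out = update_eggs(coh, rng, day_dd=1.0, hatch_threshold=60,
                          mort=MortalityParams(egg_daily=0.0))
        assert out.number == 500 and out.age == 1

    def test_empty_cohort_removed(self, rng):
        assert update_eggs(Cohort("egg", SS, SS, 0), rng) is None

    def test_promotion_at_threshold(self, rng):
        coh = Cohort("egg", SS, SS, 100, dd=55.0)
        out = update_eggs(coh, rng, day_dd=10.0, hatch_threshold=60,
                          mort=MortalityParams(egg_daily=0.0))
        assert out.stage == "larva" and not out.stage2

    def test_vectorised_step_conservation(self, rng):
        eggs = CohortTable.concat([egg_table(1000), egg_table(500, cell=3)])
        still, hatched, deaths = egg_step(eggs, 10.0, 60.0, MortalityParams(), rng)
        assert still.total() + hatched.total() + deaths == 1500


class TestEstablishment:
    ample = GrowthParams(stalk_capacity_max=100_000)

    def refuge_cell(self):
        return FieldCell("refuge", height=300.0, growth=self.ample)

    def bt_cell(self):
        return FieldCell("bt", height=300.0, growth=self.ample)

    def test_refuge_ten_percent_establish(self, rng):
        """90% establishment mortality outside the stalk on refuge cane."""
        coh = Cohort("larva", SS, SS, 10_000)
        out = establish_larvae(coh, self.refuge_cell(), BtParams(), rng)
        n = sum(c.number for c in out)
        se = np.sqrt(10_000 * 0.1 * 0.9)
        assert abs(n - 1000) < 4 * se
        assert all(c.stage2 for c in out)

    def test_bt_kills_susceptibles(self, rng):
        """SS x SS hatchlings on Bt survive at ~0.1 x 0.05^2 = 2.5e-4."""
        coh = Cohort("larva", SS, SS, 400_000)
        out = establish_larvae(coh, self.bt_cell(), BtParams(), rng)
        n = sum(c.number for c in out)
        expected = 400_000 * 0.1 * 0.0025
        se = np.sqrt(expected)
        assert abs(n - expected) < 4 * se

    def test_zero_capacity_blocks_everything(self, rng):
        cell = FieldCell("refuge", height=0.0)
        coh = Cohort("larva", HET, HET, 10_000)
        assert establish_larvae(coh, cell, BtParams(), rng) == []

    def test_capacity_rationing_caps_total(self, rng):
        """Arrivals in one cell never exceed its remaining stalk capacity."""
        table = CohortTable.concat(
            [egg_table(5000, mother=4, father=4), egg_table(5000)]
        )
        remaining = np.array([120.0])
        mort = MortalityParams(larva_outside=0.0)
        larvae, tally = hatch_and_establish(
            table, np.array([False]), remaining, BtParams(), mort, rng
        )
        assert larvae.total() <= 120
        assert remaining[0] >= 0
        assert larvae.total() + tally["overflow"] == 10_000

    def test_selection_acts_on_realised_genotypes(self, rng):
        """On Bt, survivors of a het x het cross are enriched for RR|RR."""
        table = egg_table(1_000_000, mother=4, father=4)
        mort = MortalityParams(larva_outside=0.0)
        larvae, _ = hatch_and_establish(
            table, np.array([True]), np.array([np.inf]), BtParams(), mort, rng
        )
        counts = np.zeros(9)
        np.add.at(counts, larvae.genotype, larvae.number)
        # analytic survivor composition: cross probabilities x class survival
        from btrefuge.genetics import CROSS_TABLE, survival_by_class

        mass = CROSS_TABLE[4, 4] * survival_by_class(BtParams())
        expected_share = mass[class_index(2, 2)] / mass.sum()  # ~0.756
        share = counts[class_index(2, 2)] / counts.sum()
        assert abs(share - expected_share) < 0.01


class TestLarvae:
    def test_whole_stage_mortality_ten_percent(self, rng):
        """Daily thinning compounds to the 10% in-stalk stage mortality."""
        table = CohortTable(
            stage=[1], cell=[0], mother=[0], father=[0], genotype=[0],
            number=[200_000], age=[0], dd=[0.0],
        )
        mort = MortalityParams()
        total_emerged = 0
        for _ in range(100):  # 10 dd/day against a 500 dd threshold -> 50 days
            table, emerged, _ = larva_step(table, 10.0, 500.0, mort, rng)
            total_emerged += emerged.total()
            if not len(table):
                break
        expected = 200_000 * 0.9
        assert abs(total_emerged - expected) < 4 * np.sqrt(200_000 * 0.09)


class TestEmergence:
    def test_fixed_parents_fixed_offspring(self, rng):
        coh = Cohort("larva", SS, SS, 200, stage2=True)
        moths = emerge_moths(coh, rng)
        assert len(moths) == 200
        assert all(m.genotype == SS for m in moths)
        genders = {m.gender for m in moths}
        assert genders == {"F", "M"}

    def test_double_het_cross_sixteenth_fully_resistant(self, rng):
        """RS|RS x RS|RS emergents are RR|RR at frequency 1/16."""
        coh = Cohort("larva", HET, HET, 10_000, stage2=True)
        moths = emerge_moths(coh, rng)
        frac = np.mean([m.genotype.r_counts == (2, 2) for m in moths])
        p = 1 / 16
        se = np.sqrt(p * (1 - p) / 10_000)
        assert abs(frac - p) < 4 * se

    def test_empty_cohort(self, rng):
        assert emerge_moths(Cohort("larva", SS, SS, 0), rng) == []


class TestMoths:
    def test_certain_death(self, rng):
        m = Moth("F", SS)
        assert update_moth(m, rng, MortalityParams(moth_daily=1.0)) is None

    def test_daily_survival_rate(self, rng):
        alive = sum(
            update_moth(Moth("M", SS), rng) is not None for _ in range(10_000)
        )
        se = np.sqrt(10_000 * 0.8 * 0.2)
        assert abs(alive - 8000) < 4 * se


def test_mortality_params_validated():
    with pytest.raises(ValueError):
        MortalityParams(egg_daily=1.5)
    with pytest.raises(ValueError):
        Cohort("egg", SS, SS, -1)
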