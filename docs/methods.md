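# Methods

This note documents the model implemented in `btrefuge`, the assumptions
behind it, the defaults, and what the test suite does and does not
demonstrate.

## Model structure

The simulation advances in daily steps on a two-layer grid. Ground cells
(100 m² each) carry cane state — variety (Bt or refuge), age, height, and
a height-proportional stalk capacity — plus egg and larval cohorts and
ovipositing females. Sky cells (2,500 m², each exactly atop a 5 × 5 block
of ground cells) carry flying adults. The boundary is a hard reflective
wall: any step that would leave the grid is mirrored back.

Within a day the phases are fixed: temperature and degree-days; cane
growth (and harvest on cycle days); the ground layer (egg mortality and
hatch, larval establishment, in-stalk development, eclosion); the sky
layer (adult mortality, movement, lek mating, descent); oviposition.
Within a phase all agents read the same start-of-phase snapshot (movement
kernels and lek eligibility are computed once per cell per day), which
approximates simultaneous updating without order artefacts. Across
phases the order above is a fixed convention; adult mortality precedes
movement.

## Genetics

Two loci, one per Bt mode of action, alleles S/R, Mendelian segregation,
no linkage, no mutation, no sex linkage, and no fitness cost of
resistance. Selection acts per MOA independently: per-locus survival on
Bt cane is 1 for an individual expressing resistance at that locus
(recessive default: RR only) and 1 − efficacy otherwise; overall kill is
one minus the product of per-locus survivals. With the default two MOA at
95% each, a fully susceptible or heterozygous individual survives Bt
establishment with probability 0.05² = 0.0025.

Bt mortality is applied **once, at stalk entry** (the neonate's first
feeding on toxic tissue), not daily — the "high dose" acts on first
exposure. Offspring genotypes are realised at hatch by a multinomial draw
over the parental cross distribution, so selection operates on realised
genotypes; eggs themselves carry only the parental pair.

## Life-stage bookkeeping

Eggs and larvae are cohorts (counts), not individuals; adults are
individual rows in a struct-of-arrays store. All mortalities are binomial
thinnings from a single per-run generator, so counts stay integral and
demographic stochasticity is preserved, and a per-day ledger of births,
deaths by cause and stage promotions balances exactly (audited in the test
suite).

Two bookkeeping choices deserve note:

* The 10% in-stalk larval mortality is a **whole-stage** quantity. It is
  spread over the stage in degree-day time — daily survival
  (1 − 0.1)^(dd/threshold) — so the stage-completion survival is exactly
  0.9 however temperature paces the stage.
* When same-day arrivals exceed a cell's remaining stalk capacity, the
  survivors are drawn **uniformly at random from all arrivals**
  (multivariate hypergeometric). An earlier proportional-rounding scheme
  was rejected because floor rounding annihilates rare genotype classes
  and measurably biased neutral allele frequencies downward; the
  hypergeometric draw is exactly genotype-neutral, as the neutral-drift
  test verifies.

## Behaviour

Movement probabilities come in three named levels (per-day probabilities):

| parameter | low | average (default) | high |
|---|---|---|---|
| female 1-cell jump, ms1 | 0.09 | 0.18 | 0.40 |
| female 2-cell jump, ms2 | 0.01 | 0.02 | 0.10 |
| female ground move, mf | 0.10 | 0.20 | 0.30 |
| male 1-cell jump, mm | 0.10 | 0.20 | 0.30 |

Destination choice within a ring weights each candidate by (1 + x)^β with
x the moth count (females) or mean cane height (males) and β = 1 by
default; the softened-linear form keeps empty cells reachable while
expressing the documented biases, whose strength is otherwise unmeasured.
Ring-2 jumps are direct (no intermediate interaction). Reflection can
fold several candidates onto one in-grid cell; their weights add.

Mating requires a lek: at least 6 males with fewer than 5 matings in the
female's cell. Otherwise she moves to a uniform neighbouring cell and
tries the next day. Eligibility is a start-of-phase snapshot, so a male
picked by several females on one day counts all of those matings. Males
at the cap remain in the model and keep contributing to the density bias.
Females mate once; fecundity is uniform on [300, 350].

The five-day laying schedule places (15, 50, 15, 10, 10)% of the initial
complement on days 1–5, each day clipped to [30, 150] and then to the
remaining complement. This is the simplest schedule consistent with all
the stated constraints; note they are jointly binding — for complements
above 300 the 50% day-2 clutch exceeds the 150-egg daily cap and is
clipped, so the realised mean day-2 share over the fecundity range is
48.0%, not 50% exactly. The acceptance band (±2 percentage points)
accommodates this.

## Environment and development

Temperature is the only climatic driver. A series can be read from a
`day,temp_c` file or generated synthetically: a 365-day sinusoid (mean
21 °C, amplitude 5 °C, warmest mid-January) plus Gaussian noise
(SD 1.5 °C), emulating coastal KwaZulu-Natal climatology; series shorter
than the horizon are tiled cyclically. Development is degree-day paced:
eggs hatch at 60 DD above 10 °C (≈ 4–7 days in summer), larvae+pupae
eclose at 500 DD above 10 °C (≈ 30–55 days seasonally), cane grows
0.1 cm per DD above 16 °C to a 300 cm maximum. These rates are package
defaults chosen to give a plausible multivoltine phenology; they are
fully configurable and should be recalibrated against rearing data for
quantitative use.

Cane is planted synchronously and harvested every 24 months (day 730 and
multiples); harvest resets age and height and destroys resident immatures
(a survival knob exists, default 0). At initialisation the stand is 180
days old with the height it would have accrued over the preceding 180
series days — a bare field at day 0 would starve the founder generation's
offspring of stalk capacity.

## Initialisation and experiments

Runs start with 20 batches of 1,000 adults on an even lattice of sky
cells, each batch split evenly by sex and assigned genotype classes by
largest-remainder quota — 0.5% fully resistant founders by default, i.e.
exactly 100 resistant moths of 20,000 (a binomial assignment is available
as an option). Bt and resistance are present from day 0; the first 1,460
days are a warm-up excluded from resistance metrics. The default horizon
is 3,650 days with 15 replicates per parameter combination, seeded
consecutively; a (config, seed) pair determines every output exactly.
The two case-study presets enumerate the layout × h × movement grids
(1/4/16 blocks × {10, 20, 30}% and the six shape layouts at 20%).

Layout generators are deterministic and report the refuge fraction they
actually achieve; block sides and frame widths round to whole cells, so
the achieved fraction is quantised (coarsely so for the frame layouts,
whose only knob is an integer width). The figure-derived shapes follow
the published geometry qualitatively; exact pixel geometry was not
available, so border frames are drawn as shared one-width lattice lines
along quadrant/sub-square boundaries, and the border+block hybrids place
equal blocks at the 12 edge stations and 4 quadrant centres (plus 4
corners in the revised variant).

## What the tests show — and do not

The suite verifies the mechanism, not field realism: exact Mendelian
ratios, the analytic kill probabilities, exact conservation of every
individual, determinism, boundary containment, neutral-drift stability of
allele frequencies when selection is off, and a scaled-down directional
experiment (10 ha, 3 years, 10 replicates, elevated 5% initial
resistance) confirming that more refuge never yields more
resistance-developed replicates. These scaled problem sizes were chosen
so the whole suite runs on a single CPU in minutes; they are smaller than
the 25 ha × 10 yr × 15-replicate experiments the model is designed for,
and at 5% initial resistance both tested refuge levels usually develop
resistance — the check is for the monotone direction, not effect size.
The synthetic temperature generator reproduces seasonal pacing but not
real inter-annual variability, and the demographic rates are literature-
style defaults; absolute population sizes and η values from desk-scale
runs should not be read as field predictions.

## Known limitations

Single farm, synchronous planting, reflective boundary (edge effects are
real and visible in resistance maps); no parasitism, predation, diapause,
drought stress, larval between-plant movement, female remating, or
fitness cost of resistance; at most two loci/MOA; no GIS import. The lek
system is reduced to the 6-male threshold rule; full pheromone-plume
dynamics are out of scope.
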