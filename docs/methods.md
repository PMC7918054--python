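# Methods

## Model structure

The automaton is a two-species contact process with density-dependent,
game-structured mortality. Cells are cotton plants; a cell's state is
(occupant ∈ {empty, SF, HA}, resistant ∈ {yes, no}), with SF =
*Spodoptera frugiperda* (species 1) and HA = *Helicoverpa armigera*
(species 2). Updates are synchronous with periodic boundaries and a
radius-1 Moore neighbourhood; one step is one generation. All rates are
per generation.

### Occupied-cell hazards (in order)

1. **Natural mortality / dispersal** NM: the cohort leaves the cell. The
   model folds emigration into NM; there is no long-range dispersal kernel.
2. **Insecticide** (spray generations only): a susceptible cohort dies with
   probability IM. Under the default `tracked` resistance model
   susceptibility is a per-individual phenotype drawn at initialisation
   (P(resistant) = RF for each species named resistant by the scenario) and
   inherited by colonists; under the simpler `immune` switch every
   individual of a resistant species ignores the spray.
3. **Competition**: survival *s* comes from payoff matrix **H** when the
   occupied neighbour fraction is ≥ T, else **L**; the interspecific column
   is used with probability equal to the competitor's neighbourhood share
   (n_other/8), the intraspecific column otherwise; the cohort dies with
   θ = 1 − s. The threshold comparison is ≥ (at T = 0.5 a half-occupied
   neighbourhood is already "high density").

### Colonisation of empty cells

Oviposition odds follow each species' share of the neighbourhood's expected
adult reproductive output

    w_i = m_i · Ro_i · s̄_i ,   f_i = AE · w_i / (w_1 + w_2),

where m_i is the number of *contributing* cohorts of species i among the 8
neighbours, Ro_i its per-female reproductive capacity, and s̄_i the expected
stage survival of those cohorts at the focal cell's density state, mixing
the interspecific entry in with weight (n_sf/8)(n_ha/8) — interspecific
encounters are rare unless both species are locally dense. Species 1 is
tested first (P(SF) = f₁, P(HA) = (1 − f₁)f₂), which gives it a genuine
priority advantage whenever both species could oviposit; the package
documents this asymmetry with a directional test. Weighting by s̄ means a
species' realised fitness is its *adult* output, not its egg count: at high
density the two species are nearly matched (400·0.31 ≈ 725·0.16) while at
low density HA's advantage is large (725·0.90 ≫ 400·0.63). This is what
produces HA's early lead from a sparse start and SF's takeover once the
refuge fills — and, with spraying, the scenario contrasts below.

During a spray generation the contributing cohorts are the expected
insecticide survivors, m_i = r_i + (n_i − r_i)(1 − IM): a cohort killed as
larvae leaves no adults to oviposit. This is the mechanism that lets a
resistant species capture the lattice (its recruitment is untouched while
the susceptible species' collapses) and it also accelerates resistance
spread, because a colonist inherits resistance with probability r_i/m_i —
the resistant fraction among the *surviving* parents, ≈ 0.87 after one
spray at RF = 0.0625 and IM = 0.99.

### Spraying and scenarios

The trigger is evaluated on the state entering each generation: spray iff
max(N_sf, N_ha) ≥ CL · (total cells). The spray is non-selective (all
susceptible individuals of both species are exposed) and there is no
refractory period. Scenarios only set whether the insecticide is enabled
and which species carry resistant individuals at initialisation.

## Parameters

| symbol | meaning | default | unit / range |
|---|---|---|---|
| AE | adult emergence | 0.86 | probability |
| T | density-state threshold | 0.50 | fraction of 8 neighbours |
| CL | control level triggering a spray | 0.20 | fraction of all cells |
| Ro_Sf, Ro_Ha | reproductive capacity | 400.00, 725.06 | neonates/female |
| NM | natural mortality / dispersal | 0.25 | probability |
| IM | insecticide mortality | 0.99 | probability |
| RF | initial resistant frequency | 0.0625 | probability |
| IF | founders per species | 500 | individuals |
| α, β entries | stage survival, low/high density | see README | probability |

The low-density matrix pairs with the high-density one under the indexing
s[i][j] (row = focal species, column = interaction context); the
high-density matrix also ships in a named alternate variant
(`presets/matrix_h_alternate.yaml`, diagonal 0.48/0.22) that appears in the
literature describing this system. Sensitivity ranges are the published
±25 % bands (Ro_Ha's upper bound, 965.33, is wider than +25 %; the bounds
are carried verbatim). T is excluded from the sensitivity analysis.

## Randomness and reproducibility

One `numpy` generator per run, seeded explicitly. Each generation consumes
a (rows × cols × 4) uniform draw table; cells use their four slots
positionally (occupied: NM, insecticide, encounter, competition; empty:
oviposition 1, oviposition 2, inheritance). The vectorised step and a naive
per-cell reference implementation consume the table identically and are
bit-identical on every tested lattice — the reference is the test oracle
for the production path. Identical (config, seed, command) gives
byte-identical CSV output.

## Survival GLMs and payoff assembly

Stage survival from competition trials is modelled per
(species × isolated/combined) stratum as binomial with a logit-linear
density effect, fitted by maximum likelihood (statsmodels). Complete
separation and single-density strata raise errors rather than returning
unstable estimates; a block bootstrap provides design-based uncertainty.
Payoff matrices are predictions at the 5 / 20 larvae-per-plant reference
densities, clipped to [0, 1].

The synthetic field-data generator emulates the randomized-block design:
2 species × {isolated, combined} × densities {5, 10, 15, 20} × 4 blocks,
one plant per combination infested with `density` larvae, a
normal(0, 0.25) block effect on the logit scale (a modest, typical
between-block heterogeneity for caged field trials), binomial survivors.
Its default truth curves are the logit-linear curves implied by the default
payoff matrices, so generate → fit → assemble approximately round-trips.
What it does not emulate: overdispersion beyond the block effect,
plant-level covariates, larval-instar structure, and block-by-density
interactions — parameter-recovery results on these data say nothing about
such misspecification in real trials.

## Sensitivity analysis

Design: each factor uniform over its band, crossed in a 2-level full
factorial, or the orthogonal Hadamard fraction (16 runs for the 14 default
factors; main effects mutually orthogonal, resolution III) as the default
preset for speed, with ≥ 2 replicate seeds per design point. The default
analysis runs the no-spray scenario on a 100 × 100 lattice for 40
generations — sizes chosen so a full design executes in seconds — and the
output is the two species' dominance trajectories (abundance or combined
series are selectable). A single PCA (centred; optional unit-variance
scaling) reduces the output; components are retained to 95 % cumulative
inertia; each factor's index on a component is its main-effect ANOVA share
of the component scores, and the GSI is the inertia-weighted mean across
retained components.

Known limitation: the founder count IF has near-zero GSI in this
implementation at every lattice size tested, because the lattice reaches
its quasi-equilibrium occupancy within a few generations and forgets its
initial abundance (dominance is IF-invariant by construction, and the
abundance transient is short relative to the analysed horizon). Reported
orderings place the high-density SF survival β₁₁, the reproductive
capacities and adult emergence at the top, and the low-density entries
α₁₂/α₂₁ at the bottom.

## Numerical and design choices

* The crossover statistic is the *durable* dominance shift: the first
  generation whose dominance sign opposes the initial sign and after which
  the initial sign never recurs; exact ties are skipped. A first-crossing
  definition is noise-dominated on finite lattices (the curves hover near
  0.5 early), whereas the durable shift tracks the ecological transition.
  Across seeds its distribution in the dual-resistance scenario is bimodal
  (early vs late shifts), so ensemble medians carry substantial spread.
* Degenerate denominators (no neighbours, no contributors) give f_i = 0 and
  inheritance probability 0.
* Probabilities are compared as `draw < p`, so p = 0 never fires and p = 1
  fires almost surely.
* The reduced presets (200 × 200 scenario runs; 100 × 100 sensitivity) keep
  ensembles interactive; the full-scale 1000 × 1000 preset runs at roughly
  15–20 s per 80-generation scenario.
* Scenario runs evaluate the spray trigger before the update, so a
  generation's spray status reflects the population the grower observes.

## Known limitations

* One cohort per plant: no within-cell larval counts; competition acts only
  through the payoff matrices.
* Resistance is a single phenotype; there is no allele-level
  (high-dose/refuge) genetics and no fitness cost of resistance.
* The oviposition normalisation and the encounter weighting inside s̄ are
  modelling choices among several plausible density-dependent forms; the
  scenario-level contrasts (which species dominates where, suppression
  under a resistant competitor) are robust to the encounter form, but the
  timing of the dual-resistance dominance shift is compressed relative to
  the behaviour the model family can exhibit at other parameter settings.
* A species can go extinct on small lattices where the corresponding field
  system would show rare-patch persistence.
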