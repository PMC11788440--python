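# Methods

## Exposure and burden model

The package implements an ingestion-only quantitative risk assessment for
chemicals of emerging concern (CECs) in drinking water. Each chemical *i*
is described by a source-water concentration *CS*ᵢ (ng/L), endpoint effect
factors *EF*ᵢʲ (change in lifetime disease probability per kg of lifetime
intake, cases/kg, for cancer and non-cancer endpoints separately), and
per-unit removal fractions *R*ᵢᵏ along an ordered treatment train. The
chain is

1. residual concentration `CE_i = CS_i · Π_k (1 − R_i^k)` — removals act
   multiplicatively and independently per unit;
2. population ingested mass `IF_i = SP · IR_cum · CE_i · 1e-12` kg, with
   `IR_cum = ir_daily · 365 · T` the cumulative per-capita intake;
3. endpoint burden `HE_i^j = EF_i^j · DF^j · IF_i` DALYs over the horizon.

Inhalation and dermal pathways are out of scope: for waterborne CECs the
ingestion route dominates, and effect factors are taken as ingestion-route
midpoint values. Dose–response is linear (no threshold), which is the
standard conservative convention at ng/L exposure levels.

Reported burdens are per person per year, `HE / (SP · T)`. The population
*SP* cancels analytically through the chain; it is carried explicitly so
that population-scale intermediate quantities (kg ingested, population
DALYs) remain available.

### Defaults and units

| parameter | default | unit | meaning |
|---|---|---|---|
| `sp` | 500 000 | persons | population served by the plant |
| `ir_daily` | 1.4 | L/day | per-capita drinking-water intake |
| `years` | 25 | y | plant service life = exposure horizon |
| `df_cancer` | 11.5 | DALYs/case | cancer damage factor |
| `df_noncancer` | 2.7 | DALYs/case | non-cancer damage factor |
| `threshold` | 1.00e-6 | DALYs person⁻¹ y⁻¹ | WHO tolerable burden |

Concentrations are always ng/L in files and interfaces; the single unit
conversion (1e-12 kg per ng/L·L) lives in `ingested_mass`.

### Mixture aggregation

Additive response addition — the sum of per-chemical burdens — is the
default and the conservative choice when interaction data are absent. Two
alternatives quantify the structural uncertainty of that assumption:

* **dominant** — the worst single contributor (maximum), a lower bound;
* **multiplicative** — independent action on per-person lifetime case
  probabilities `p_i = b_i · T / DF` (with `b_i` the annual per-person
  burden), combined as `1 − Π(1 − p_i)` and converted back with `DF / T`.

For case probabilities below ~1e-4 the multiplicative total is within 0.1%
of the additive total (second-order term of the product expansion), so the
choice only matters for high-risk mixtures. The ordering
dominant ≤ multiplicative ≤ additive holds for any non-negative inputs with
`p_i < 1` and is enforced by property tests. A chemical missing one
endpoint's effect factor is excluded from that endpoint only, never from
the other.

## Data preparation

* **Censoring.** Non-detects (all concentration cells blank) are set to
  half the limit of detection, or half the limit of quantification if no
  LOD is given; LOD takes precedence when both are present. The rule is
  idempotent and applied at load time; censored records become point
  distributions (the literature rarely reports spread for non-detects).
* **Removal imputation.** A missing (unit, chemical) removal entry is
  filled with the element-wise mean of the (low, mode, high) parameters
  over same-category chemicals with data in that unit. Averaging
  parameters rather than pooling samples keeps the imputation deterministic
  and order-free; it cannot leave [0, 1] when the inputs are in [0, 1]. No
  same-category data in a unit is an error, not a silent default.
* **Validation.** Out-of-range removals and malformed rows raise load
  errors naming the row; data are never silently clipped.

## Uncertainty propagation

Uncertain inputs carry min/mode/max **triangular** distributions — the
standard choice when only the extremes and a central value of literature
data are defensible. Sampling is by inverse CDF (piecewise square-root
formula) driven by named uniform sub-streams: each draw stream is keyed by
(chemical) for concentrations and (train, unit, chemical) for removals,
derived from one global seed via a `SeedSequence` of the CRC-32 of the
stream name. Adding a unit or chemical therefore never perturbs other
draws, and runs are bit-reproducible across platforms.

Per iteration, one concentration draw per chemical is **shared across
trains** — both systems treat the same source water — while removal draws
are independent per train and unit (mutual independence of treatment
steps). This pairing makes the train difference per iteration
well-defined; the benefit percentage counts strictly negative differences
(alternative minus reference). Fully independent runs are available via
`shared_cs=False`.

Defaults: 10 000 iterations; summaries are the median with 5th/95th
percentiles (variability) and the mean with the 2.5th–97.5th percentile
interval of the simulated distribution (uncertainty). Quantiles use linear
interpolation between order statistics (type 7). Threshold compliance is
the percentage of iterations with total burden ≤ the threshold
(inclusive). Adequacy of the iteration count is checked by repeating the
run under a different seed and reporting the worst relative deviation over
{median, p5, p95, mean} per endpoint (default tolerance 5%; at n = 10 000
the study-scale deviation is well under 1%).

## Sensitivity analysis

* **Rank correlation.** Spearman's ρ (tie-aware average ranks, via
  scipy) between each recorded input draw and the endpoint burden totals.
  Constant inputs yield NaN rather than a fabricated value. A parameter
  that does not enter an endpoint (e.g. the concentration of a chemical
  with no cancer effect factor) has |ρ| below the 3/√n null band.
* **One-factor-at-a-time.** Scalar inputs perturbed by ±20%; the
  sensitivity coefficient is the relative output change over the relative
  input change, reported for both directions plus their mean (the headline
  value, since one-sided secants of a nonlinear model differ: a quadratic
  gives 2.2 and 1.8 at ±20%).

## Life-cycle impact engine

A generic linear midpoint characterization: `score_c = Σ_f amount_f ·
factor_{f,c}` over a user-supplied factor matrix; ten default category
names cover the impacts commonly reported for urban water systems. No
proprietary factor databases are bundled or reimplemented — the engine is
data-driven and ships only synthetic fixtures, so absolute scores from the
fixtures are demonstrative only. The functional unit is 1 m³ of product
water over the plant's 25-year horizon; construction and decommissioning
are excluded, and transport flows are excluded from cross-system
comparisons by default but available to the mode-swap scenario.

Scenario levers: membrane replacement scales inversely with the
membrane-lifespan multiplier; brine energy recovery multiplies electricity
by `1 − hp_pump_share · recovery_fraction` (the high-pressure-pump share is
~0.5 for reverse-osmosis systems; the turbine recovery efficiency is a
required user input); transport amounts can be moved between modes.
Electricity-mix substitution splits the aggregate kWh flow into
source-resolved flows by country shares (total kWh preserved) and
characterizes them with per-source factor vectors. Comparisons are
reported as percent change against a baseline, negative meaning reduction;
a zero baseline score is flagged NaN rather than divided through.

## Synthetic data generator

The generator emulates the statistical shape of a literature-compiled CEC
study so that every pipeline stage is testable without external data:

* 93 chemicals — 41 pesticides, 19 industrial chemicals, 17
  pharmaceuticals, 7 antibiotics, 5 DBPs, 4 personal care products;
* concentration modes log-uniform over 10⁰–10³ ng/L; effect factors
  log-uniform over 10⁻³–10^1.1 cases/kg, with DBPs drawn from the top half
  of the range (high-toxicity byproducts) and always carrying a cancer
  factor; other categories have a cancer factor with probability 0.8;
* triangular spread: ±50% of the mode for concentrations, ±0.05 absolute
  for removal fractions;
* two trains — a 6-unit membrane train (riverbank filtration, reverse
  osmosis, ion exchange, remineralization, oxygenation, degasification)
  and a 7-unit conventional train (riverbank filtration, dry filtration,
  pellet softening, carry-over filtering, ion exchange, granular activated
  carbon, UV) — with per-unit-class removal ranges typical of each process
  class (reverse osmosis 0.85–0.99, activated carbon 0.3–0.8, polishing
  steps near zero);
* 10% of removal entries deleted (exercising imputation) and 10% of
  concentrations censored to half an LOD.

What it does **not** emulate: correlations between concentration and
toxicity, between units, or across chemicals; seasonal/spatial structure;
heavy-tailed (e.g. lognormal) concentration distributions; real removal
chemistry. Passing tests on synthetic data therefore demonstrate the
correctness of the computational machinery and the qualitative
system-comparison logic, not the true burden of any real water
system.

The paired-train **benchmark** plants strict stochastic dominance: the
conventional train's per-unit removals stay below 0.25 (residual fraction
≥ 0.75⁷ ≈ 0.133) while the membrane train carries a 0.90–0.99 unit
(residual fraction ≤ 0.10), so with shared concentration draws every
iteration favours the membrane train and the paired benefit must be
exactly 100%. Expected additive totals are computed in closed form
(`E[CS] · Π(1 − E[R])` by independence, triangular means `(a+c+b)/3`) and
recovered by the Monte Carlo mean within 3 standard errors.

## Numerical choices and edge cases

* Triangular inverse CDF handles mode-at-endpoint degeneracies explicitly;
  point specs short-circuit to constants.
* Multiplicative aggregation uses `log1p`/`expm1` for numerical stability
  at small probabilities.
* Empty mixture slices (no chemicals with an endpoint factor) total zero.
* The Spearman of a constant vector, the OAT coefficient of a zero base
  output and the percent change of a zero base score are all NaN-flagged,
  never silently zero.
* Seeds are folded modulo 2³⁰ before stream derivation.

## Known limitations

Single-pathway (ingestion) exposure; linear no-threshold dose–response; no
inter-unit process coupling (removal distributions are independent, though
real upstream changes alter downstream performance); mixture interactions
beyond the three aggregation conventions are not modelled; LCA uncertainty
is not propagated (scenario analysis only); the generator's distributional
choices are pragmatic stand-ins, not fitted to any survey.
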