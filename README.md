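# cecburden

Probabilistic disease-burden and life-cycle impact modelling of chemicals of
emerging concern (CECs) in drinking-water treatment trains.

Drinking-water sources carry complex mixtures of pesticides, industrial
chemicals, pharmaceuticals, antibiotics, disinfection byproducts (DBPs) and
personal care products at ng/L–µg/L levels. Water utilities weighing a
conventional extended treatment train against a riverbank-filtration +
reverse-osmosis train need to know (i) whether either system keeps the
mixture's health burden below the WHO tolerable limit of
1.00 × 10⁻⁶ DALYs person⁻¹ year⁻¹, (ii) how confident that judgement is
given uncertain concentrations and removal efficiencies, and (iii) what the
environmental price of the more aggressive treatment is. `cecburden` is a
library plus command-line tool for exactly that analysis.

## Model

For chemical *i* with source-water concentration *CS*ᵢ (ng/L) passing an
ordered train of *K* treatment units with removal fractions *R*ᵢᵏ:

```
CE_i   = CS_i · Π_k (1 − R_i^k)            residual concentration (ng/L)
IF_i   = SP · IR_cum · CE_i · 10⁻¹²        ingested mass (kg), population total
HE_i^j = EF_i^j · DF^j · IF_i              disease burden (DALYs), endpoint j
```

where *SP* is the served population (default 500 000), *IR*_cum the
cumulative per-capita intake (1.4 L/day over a 25-year service life =
12 775 L), *EF* the endpoint effect factor (cases/kg) and *DF* the damage
factor (2.7 and 11.5 DALYs/case for non-cancer and cancer). Burdens are
normalised to DALYs person⁻¹ year⁻¹ as *HE*/(SP·T) and summed over the
mixture (additive response addition by default; dominant and multiplicative
independent-action modes for robustness checks).

Every uncertain input — concentration and per-unit removal — is a
min/mode/max triangular distribution propagated by Monte Carlo (10 000
iterations by default). Outputs are cumulative probability distribution
curves, medians with 5th/95th percentile variability, means with 95%
percentile intervals, the fraction of iterations at or below the WHO
threshold, and — for a pair of trains fed by the same source water — the
fraction of iterations in which switching systems is a net health benefit.
Spearman rank correlation over the recorded input draws and ±20%
one-factor-at-a-time coefficients identify the driving parameters, and a
data-driven life-cycle engine characterizes inventories against
user-supplied midpoint factors with electricity-mix substitution and
mitigation scenarios (membrane-life extension, brine energy recovery,
transport mode swaps). No proprietary characterization factors are bundled.

## Worked example

Generate a synthetic study-scale dataset (93 chemicals in six categories,
two trains, deliberate data gaps exercising the imputation rules), simulate,
and report:

```sh
cecburden generate --preset study --seed 1 --out data/
cecburden simulate --cecs data/cec_table.csv --removals data/removal_table.csv \
    --train data/train_rbf_et.json --train2 data/train_rbf_ro.json \
    --context data/context.json --iterations 10000 --seed 1 --out run/
cecburden report run/
```

With seed 1 the simulation prints (in `run/summary.json` / `run/report.md`):

| series | cancer median | non-cancer median | compliance |
|---|---|---|---|
| source water | 6.807 × 10⁻⁵ | 2.518 × 10⁻⁵ | 0% / 0% |
| rbf_et (7 units) | 7.013 × 10⁻⁶ | 2.150 × 10⁻⁶ | 0% / 0% |
| rbf_ro (6 units) | 2.171 × 10⁻⁶ | 9.687 × 10⁻⁷ | 0% / 60.6% |

all in DALYs person⁻¹ year⁻¹, and a paired benefit of 100% (cancer) and
100% (non-cancer): in every iteration the membrane train delivers the lower
burden, because the synthetic reverse-osmosis unit removes 85–99% of every
chemical. Untreated source water never meets the tolerable burden; treatment
is indispensable, and only the membrane train approaches non-cancer
compliance under these synthetic conditions.

The deterministic chain is available directly:

```python
>>> from cecburden import ExposureContext, cumulative_intake, ingested_mass, \
...     health_effect, annual_per_person
>>> ctx = ExposureContext()                      # SP 500k, 1.4 L/day, 25 y
>>> m = ingested_mass(ctx.sp, cumulative_intake(ctx), 4.6)   # 4.6 ng/L
>>> annual_per_person(health_effect(11.9, ctx.df_cancer, m), ctx)
3.216796099999999e-07
```

i.e. a high-toxicity DBP (effect factor 11.9 cases/kg) at only 4.6 ng/L
already sits within a factor of ~3 of the tolerable burden.

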