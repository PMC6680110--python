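# nutricost

**Program-experience costing of nutrition-specific intervention packages at
national and subnational scale.**

`nutricost` answers the planner's question *"what would it cost, per year, to
deliver a package of direct nutrition interventions to everyone who needs
it?"* using the program-experience method: for each intervention, an observed
per-beneficiary unit cost from an operating programme is multiplied by the
projected size of its target population,

```
cost_i = UC_i × TP_i × coverage_i
```

where `UC_i` is the unit cost normalized to US$ per beneficiary per year,
`TP_i` is the eligible-beneficiary count derived from census-style
demographic projections plus eligibility rules (age window, anthropometric
prevalence, endemic-area restriction, programme exclusions), and coverage is
1.0 ("full coverage") for everything except severe-acute-malnutrition (SAM)
treatment, where an 80% operational ceiling applies in the
community-management model.

The package is aimed at nutrition-policy analysts and health economists who
need reproducible budget-impact estimates. It ships two fully specified
scenarios for India 2014:

* **SUN** — the ten-intervention Scaling Up Nutrition global costing package
  with its global unit costs;
* **India Plus** — fifteen interventions from India's national policy
  framework with local (Indian/South Asian) programme unit costs.

Both run against a packaged national fixture whose target populations are
back-derived from the published cost lines (`TP = cost / UC`), so the full
pipeline — scenario config → unit-cost normalization → target resolution →
costing → shares — reproduces the published totals end to end. A
35-state/union-territory table of category-level cost anchors supports
subnational analysis, and a seeded synthetic-data generator produces
census-style region tables for testing and experimentation.

## Worked example

```python
import nutricost as nc

report = nc.run_fixture_scenario("india_plus")
print(f"total: {report.total:.2f} US$ million/yr")
for cat, share in report.shares("category").items():
    print(f"  {cat:<24s} {report.aggregate('category')[cat]:8.2f} US$M  {share:5.2f}%")
line = report.line("cash_transfers")
print(f"cash transfer target: {line.target_population/1e6:.2f} million women")
```

prints

```
total: 5930.92 US$ million/yr
  counselling                287.04 US$M   4.84%
  supplementation           2295.40 US$M  38.70%
  micronutrient_deworming    201.01 US$M   3.39%
  health                     247.74 US$M   4.18%
  cash_transfer             2899.73 US$M  48.89%
cash transfer target: 28.09 million women
```

i.e. delivering the fifteen India Plus interventions at full coverage costs
about US$5.9bn per year, dominated by the maternity cash transfer (49%) and
supplementary food (39%); the SUN package (`run_fixture_scenario("sun")`)
totals US$4.2bn. The cash-transfer line alone is 28.09 million
newly-delivered women per year (government employees excluded) at $103.22
each.

One-way sensitivity swaps recompute a single line: applying the local
$29/child-year ration norm to the SUN food-supplement target population of
32.2 million children gives ≈US$0.93bn, while the global $51.10 rate on the
India Plus target of 57.9 million gives ≈US$2.96bn — the cross-estimates
that bracket the food-supplementation cost.

## Command line

```bash
nutricost cost --scenario india_plus --fixture --out reports/
nutricost compare --a sun --b india_plus --fixture --out reports/
nutricost sensitivity --scenario india_plus --intervention complementary_food \
    --unit-cost 51.10 --target 57.9e6 --fixture --out reports/
nutricost synth --seed 1 --n 5 --out regions.csv
nutricost fixture --out fixture/
```

Reports are written as CSV (fixed column order, explicit `US$ million/yr`
units, final Total row) and JSON (nested scenario → category → intervention,
losslessly re-readable).

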