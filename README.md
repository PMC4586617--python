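# goitrisk

Probabilistic cumulative and aggregate risk assessment for dietary
goitrogens — perchlorate, nitrate and thiocyanate in drinking water and
food — for risk assessors and regulatory scientists who need
population-level hazard-index statistics rather than single worst-case
point estimates.

## The model

All three agents inhibit iodide uptake into the thyroid through the
sodium–iodide symporter, so they share a mode of action and their
intakes add on a common potency scale.  For each simulated individual,
agent *g* and route *r* (water, food):

```
ADRI_{g,r} = C_{g,r} × EF_r                      [µg/kg-day]
ADRI_PEC   = Σ_{g,r} ADRI_{g,r} / PEC_g          [µg/kg-day PEC]
HI         = ADRI_PEC / RfD
```

where `C` is the concentration in the medium (µg/L water, µg/kg food),
`EF` the exposure factor (medium intake per kg body mass per day, one
shared water draw and one shared food draw per individual), and `PEC_g`
the perchlorate-equivalence divisor of agent *g*: 1 : 150 : 8.8
(perchlorate : nitrate : thiocyanate) on the serum-concentration basis,
or 1 : 240 : 0.5 with serum half-life correction, which weights
thiocyanate 17.6× more heavily.  Every `C` and `EF` is lognormal —
median and geometric standard deviation (GSD) — truncated at ±3 GSDs in
log space.  The population risk metric is the percentage of individuals
with HI > 1 under three reference doses (Approach 3: 13.5/22.9;
Approach 4: 29.5/38.9; Approach 4b: 14.5/23.9 µg/kg-day PEC without /
with half-life correction).

The package provides:

* `distributions` — the truncated lognormal (sampling, quantiles,
  closed forms, fitting from percentile sets);
* `scenario` — agents, PEC bases, RfD approaches, age groups, YAML
  scenario configs, and a synthetic scenario generator;
* `engine` — the Monte Carlo core: percentile tables, HI exceedance,
  per-goitrogen attribution, route shares, sample-size stability rule;
* `variance` — contribution-to-variance shares (normalised squared
  Spearman rank correlation over the eight input factors);
* `calibration` — recovery of unprinted component medians and EF
  spreads from published composite percentile/CV tables, with held-out
  validation against the published exceedance and attribution tables;
* `cli` — the `goitrisk` command (`synth`, `simulate`, `calibrate`,
  `verify`, `report`).

## Worked example

```python
import goitrisk as gr

scenario = gr.synthetic_scenario(seed=42)
samples = gr.simulate(scenario, ">21 years", basis="serum", n=50_000, seed=7)

print(gr.percentile_table(samples, [5, 50, 95]))
for approach, rfd in [("A3", 13.5), ("A4", 29.5), ("A4b", 14.5)]:
    print(approach, gr.exceedance_fraction(samples, rfd))
print(gr.attribute_exceedance(samples, 13.5))
print(gr.contribution_to_variance(samples).dominant_factor())
```

prints (rounded):

```
PEC ADRI percentiles (ug/kg-day): {5: 7.55, 50: 14.83, 95: 30.05}
A3: HI>1 for 58.8% (RfD 13.5 ug/kg-day)
A4: HI>1 for 5.5% (RfD 29.5 ug/kg-day)
A4b: HI>1 for 52.0% (RfD 14.5 ug/kg-day)
attribution at A3: {'perchlorate': 0.0, 'nitrate': 58.75, 'thiocyanate': 0.0}
dominant variance factor: nitrate_food_conc (74%)
```

Read: in this synthetic adult population the median PEC-weighted intake
(14.8 µg/kg-day) already exceeds the Approach-3 reference dose, so 59%
of the population carries HI > 1; under the exposure-response-based
Approach 4 only 5.5% do.  Nearly every exceedance is attributable to
nitrate in food, which also drives 74% of the inter-subject variance —
so mitigation effort aimed at waterborne perchlorate would miss the
dominant risk driver.  The same pipeline runs from the shell:

```sh
goitrisk synth --seed 42 --out scenario.yaml
goitrisk simulate --scenario scenario.yaml --basis serum --n 50000 \
    --seed 7 --out-dir results/
goitrisk report --age-group "2-3 years" --seed 1 --out-dir report/
```

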