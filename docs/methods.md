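# Methods

## Model

The package estimates inter-subject variability in combined goitrogen
intake and converts it into population hazard statistics.  Perchlorate,
nitrate and thiocyanate inhibit thyroidal iodide uptake through the same
sodium–iodide symporter mechanism, so their intakes are summed on a
perchlorate-equivalent (PEC) potency scale — a toxicity-equivalence
weighting in which each agent's average daily rate of intake (ADRI,
µg/kg-day) is divided by a potency divisor before summation:

* serum-concentration basis: divisors 1 (perchlorate), 150 (nitrate),
  8.8 (thiocyanate);
* serum-half-life-corrected ingested-mass basis: 1, 240, 0.5.

For each simulated individual, one water exposure factor (EF, L/kg-day)
and one food EF (kg/kg-day) are drawn and shared across agents — one
person has one intake rate — while the six concentration values
(3 agents × 2 routes) are drawn independently.  Intake and body mass
are folded into the single EF because they are positively correlated.
Component intake is `C × EF`, with nitrate multiplied by
`(1 + endo_nitrate_coeff)` for endogenous nitrate production before PEC
conversion (the coefficient is deterministic and population-wide;
default 0, since any nonzero value is absorbed by the calibrated
nitrate medians).  The composite PEC ADRI divided by a reference dose
(RfD) common to the mode of action gives the Hazard Index; the
population metric is the percentage with HI strictly above 1.  Three
RfD choices are carried: Approach 3 (13.5 / 22.9 µg/kg-day PEC without
/ with half-life correction), Approach 4 (29.5 / 38.9) and Approach 4b
(14.5 / 23.9).

Concentration draws are held perfectly correlated across days within an
individual.  For food this overstates between-person dispersion (people
sample many food sources over an exposure window, which would pull
individuals toward the population mean), so the exceedance percentages
are deliberately health-protective upper estimates; the data needed to
model the true temporal correlation are not available.

## Distributions

Every `C` and `EF` is lognormal, parameterised by median and geometric
standard deviation (GSD), truncated symmetrically in log space at
±`trunc` GSDs (default 3) and renormalised.  Sampling is inverse-CDF on
the restricted normal, so bounds hold exactly without rejection loops.
Closed forms used throughout: quantile `median·gsd^z(p)` with `z(p)`
the renormalised restricted-normal quantile; mean
`median·e^{s²/2}·(Φ(t−s)−Φ(−t−s))/(Φ(t)−Φ(−t))` with `s = ln gsd`.
Concentration GSDs default to 1.5 (the measured spread of the food
goitrogen data the assessment rests on); exposure-factor GSDs default
to 1.3 (water) and 1.25 (food) in the synthetic generator and are
fitted quantities in calibration.  A median of exactly 0 denotes the
degenerate all-zero distribution, used for thiocyanate in water, whose
concentration is negligible.

Random streams are derived per (age group, component) from the root
seed via CRC32 labels, so any component's draws are reproducible
independently of evaluation order, and switching PEC basis changes only
the divisors, never the draws.

## Engine choices

* Empirical quantiles use the inclusive linear-interpolation rule
  (numpy `linear`); at n = 50,000 the difference between interpolation
  rules is far below reporting precision.
* HI > 1 is strict; ties have probability zero for continuous inputs.
* Attribution partitions exceeding individuals by the *largest summed
  (water+food) PEC contribution*, so per-agent percentages sum exactly
  to the total exceedance.  This is the only reading under which the
  published per-goitrogen table columns sum exactly to the published
  totals (e.g. adults, Approach 3: 0.24 + 28.90 + 1.26 = 30.40); the
  alternative single-agent thresholding (percentage whose HI would
  exceed 1 from one agent alone) is available via `rule="single"` for
  sensitivity exploration only.
* The sample-size stability rule doubles n from a starting value until
  the 95th-percentile estimate changes by less than 1% between stages,
  returning the first stable stage's n (cap 10⁶, with the trace
  attached to the non-convergence error).
* Contribution to variance (CV) is the normalised squared Spearman rank
  correlation between each of the eight input factors (six
  concentrations, two EFs) and the composite ADRI — the estimator used
  by the spreadsheet risk tools this kind of assessment is usually run
  in.  Shares sum to 100 exactly before rounding; structurally
  degenerate factors get share 0.  A first-order conditional-mean
  variance decomposition (binned main effects) is provided as an
  independent cross-check, not the default.

## Synthetic scenario generator

`synthetic_scenario(seed)` emulates the study conditions: five
non-degenerate concentration components with GSD 1.5 truncated at 3
GSDs, medians drawn log-uniformly within ranges centred on realistic
U.S. levels (≈1 µg/L perchlorate and a few mg/L nitrate in water; food
levels sized so water carries only a few percent of each agent's intake
and nitrate dominates the serum-basis total), a fixed six-category food
basket collapsed to one effective food concentration per agent, two
shared EF distributions per age group, and the six-group age roster
(1–3 months through adults, plus pregnant women).  What it does *not*
emulate: spatial/temporal concentration structure, correlations between
food categories, agent-specific concentration spreads, or any
subpopulation clustering — so green tests on synthetic data demonstrate
the estimators' internal correctness and invariances, not field
accuracy of any particular national dataset.

## Calibration

The published assessment prints composite outputs (ADRI percentile rows
per age group and basis, CV shares, route-share constants) but not the
component medians or EF spreads behind them.  `calibration.calibrate`
inverts that mapping under the fixed structure (concentration GSD 1.5,
truncation 3 GSDs).

Identifiability is handled explicitly: percentile rows identify only
EF×C *products*; the water/food split of each agent is pinned as a hard
constraint on mean contributions by the published route shares (4%
perchlorate, 6% nitrate, 0% thiocyanate via water), and the
EF-versus-concentration split of the spread is informed by the CV
shares (soft terms).  Without route shares the fit refuses to report
component splits.  EF medians are unidentifiable in principle (only
products matter) and are set to representative per-age values, with the
concentration medians absorbing the scale.

Free parameters: the perchlorate-food and thiocyanate-food medians
relative to nitrate-food (serum-PEC units) and the two EF GSDs
(log-sd bounded in [0.02, 0.92] via a logistic reparameterisation).
The overall scale is not searched: it is pinned each evaluation so the
composite serum median equals the printed 50th percentile exactly, and
the half-life-basis median carries weight 25, because the medians are
the location anchors of the published parameterisation and every hazard
quotient is a ratio to that location.  The loss adds squared log-errors
on printed percentiles from the 30th upward (weight 1) and squared
errors on CV share fractions (weight 0.1 each), evaluated under common
random numbers (one fixed 20,000-draw matrix across all evaluations,
factor ranks precomputed) so the objective is smooth and a Nelder–Mead
simplex with 8 multistarts is reliable; the accepted objective
trajectory is monotone by construction.  Both bases are fitted jointly
from one shared draw set — the bases differ only in divisors.

Printed percentiles below the 30th are excluded from the loss and
reported in residuals instead.  The reason is structural, not
cosmetic: the printed rows' sub-median spread implies a composite GSD
near 2.0, while their p90–p95 implies ≈1.56 and the CV shares cap the
EF contribution to the spread — no sum of products of truncated
lognormals with concentration GSD 1.5 can satisfy both ends, and a
flat full-row least squares resolves the conflict by dragging the
fitted median ≈14% below the printed value, which destroys every
downstream exceedance comparison.  Anchoring the medians and fitting
the upper structure preserves everything the hazard metrics depend on;
the lower-tail residuals (≈+40–80%) remain visible in every result.

Verification is held out: the published exceedance and attribution
tables never enter the objective.  `verify` simulates the calibrated
scenario (n = 50,000) and reports signed errors against every printed
entry.

## Known limitations

* Three published quantities are *not* reproduced within their printed
  precision, for the structural reason above, and the corresponding
  acceptance tests are left failing rather than loosened:
  the adult/minimum Approach-3 exceedance (needs local GSD ≈1.76
  between p50 and p70 while p90+ needs ≈1.56 — the model family has
  one effective width), and the Approach-4 tail exceedances (the
  printed p95→p99 flattening implies a tail compression with no
  in-family counterpart; the serum-basis value lands near 3% against a
  printed 1.1%, and the half-life maximum near 8.6% against 11%).
* The printed CV share for nitrate in water (13–17%) is mutually
  inconsistent with the 6% route share (a factor carrying 6% of the
  mean cannot carry ~15× the variance implied by an identical-GSD
  factor carrying 94%); the fit permanently reports ≈−13 points of CV
  residual there.
* Identical published rows for 2–3 and 6–11 years (and 18–21 / >21) are
  kept as separate groups; their calibrations differ only through their
  CV rows.
* Problem sizes: 50,000 draws per age group and basis for all reported
  statistics (the size at which the published assessment's own 95th
  percentile stabilised to <1%), 20,000 common-random-number draws
  inside the calibration objective, 400,000 draws for the
  self-consistency round trip in the test suite.
* Bromide, chlorate and other goitrogens, serum pharmacokinetics, and
  the derivation of the RfD/PEC constants from the underlying
  dose-response reanalysis are out of scope; the constants are consumed
  as given.
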