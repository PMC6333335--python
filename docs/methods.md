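# Methods

`chdopt` implements a decision-analytic model for targeting statin therapy
in the primary prevention of coronary heart disease (CHD), where two
prognostic tests — a traditional risk score (TRS) built from clinical
factors and a genetic risk score (GRS) — can be deployed to population
segments before the treat/no-treat decision. This note documents the
model, its conventions, the synthetic data that stands in for the original
cohort inputs, and the numerical choices.

## The decision model

A patient's state of health over a 10-year horizon is a static binary
variable: they either will or will not suffer a CHD event within 10 years
absent treatment. The belief about that state is fully summarized by the
event probability (the "risk"); testing refines the belief, and statin
therapy reduces the probability that a would-be event occurs by the
relative risk reduction (base case 27 %).

Every path through the decision tree ends in one of four states, valued in
discounted 2015 euros and discounted quality-adjusted life-years (QALYs):

| state | meaning | cost (EUR) | QALY |
|---|---|---|---|
| I | no event, untreated (true negative) | 0 | 7.703 |
| II | no event, treated (false positive) | −1,928 | 7.686 |
| III | event, untreated (false negative) | −14,687 | 6.947 |
| IV | event, treated (true positive) | −12,102 | 7.139 |

(The numbers are the package's base-case output, `endstate_values` with
default `EconomicParameters`.) The objective is net monetary benefit,
`NMB = QALY × λ − cost`, with willingness to pay λ = 50,000 EUR/QALY in
the base case.

Valuation conventions:

- **Discounting.** 3 %/yr on costs and health outcomes. Annual flows
  (QoL-years, statin 53 EUR/yr + monitoring 173 EUR/yr, secondary
  prevention 451 EUR/yr) are end-of-year payments; a partial year is
  pro-rated and paid at the interval's end time. One-off event flows are
  discounted at the expected event time, 5.75 years.
- **State III** mixes a fatal branch (probability 0.22: QoL truncated to
  zero after the event, fatal event cost 2,417 EUR) and a non-fatal branch
  (one-year QALY loss of 0.147 and event cost 19,860 EUR at the event
  time, then secondary prevention until the horizon).
- **State IV** treats "event averted" as following the state-II path with
  probability 0.27; otherwise the event path is followed with primary
  prevention paid, and the 0.002/yr statin disutility accrued, until the
  event time. This folding of the risk reduction into the treated event
  state is the only reading under which the four state values are jointly
  consistent with the input parameters.
- The CHD-free quality of life uses the age-weighted average 0.903 of the
  age-band estimates (0.935/0.920/0.900/0.835), not its two-digit
  rounding; the rounded value visibly misses the state-I QALY.
- Tests carry costs (TRS 173 EUR, GRS 200 EUR) but no QALY impact.
- Costs are reported with a negative sign in end-state tables (the
  health-economics reporting convention) and as positive expected spend in
  strategy evaluations.

The closed-form terminal decision is: treat exactly when risk ≥
p\* = (NMB_I − NMB_II) / ((NMB_I − NMB_II) + (NMB_IV − NMB_III)) ≈ 18.6 %
at base case.

## Bayesian risk updating

Each test is a finite-alphabet observation: the continuous score is
discretized into bins (deciles of the pooled score distribution by
default) and characterized by the conditional probabilities of each bin
given the state. Observing bin *b* maps prior *p* to
`p·L1[b] / (p·L1[b] + (1−p)·L0[b])`. The two scores are modelled as
conditionally independent given the state — justified originally by the
negligible observed correlation between traditional risk factors and the
polygenic score (max |r| = 0.09) — so sequential two-test updates are
order-invariant and the posterior is a martingale under the predictive
result distribution (both properties are tested).

Likelihood tables are estimated from a cohort by binning at pooled
quantile edges with add-one smoothing per conditional, which keeps
posteriors finite on finite cohorts. The bin count (default 10) is a free
resolution/estimation-noise trade-off; nothing in the source setting pins
it down.

## Strategy optimization

Ten strategies are compared: no testing without (i) or with (ii) an
optimized treatment threshold; one optimized test (iii TRS, iv GRS); two
optimized tests in either order (v TRS→GRS, vi GRS→TRS); and four
non-optimized references (vii TRS for all, viii GRS for all, ix TRS for
all with GRS forced for updated risk 10–20 % inclusive, x both for all).
Strategies i and ii are embedded options of iii–vi; references vii–x still
make the terminal treatment decision optimally.

Each strategy is solved by backward induction: the terminal treat/no-treat
value is a max of two linear functions of the belief; a test stage is the
expectation of the continuation value over the predictive result
distribution, minus the test cost. Posteriors are evaluated exactly inside
the recursion (the finite alphabets make this cheap); the integer
0–100 % prior grid is used only for reporting segments and population
weighting, so segment endpoints may differ by up to one grid point from a
formulation that rounds posteriors onto the grid. Ties are broken in
favor of fewer tests, then no treatment, making output deterministic.
Population results are weights-on-the-grid averages; testing and
treatment shares are propagated through the realized branch
probabilities.

The solver is verified against exhaustive enumeration of all deterministic
test-then-treat policies on two-bin toy instances, and against dominance
properties (richer strategies are pointwise at least as valuable; a free
test never hurts; an uninformative test loses exactly its cost). Value
functions of the optimized strategies are convex piecewise-linear in the
prior; reference strategy ix is the one exception, since forcing the
second test inside a fixed risk window is a non-convex policy constraint.

## Sensitivity analyses

**PSA.** Uncertain parameters are drawn independently: event disutility
−Beta(52, 304), fatality probability Beta(48, 173), risk reduction
Beta(45, 121), GRS cost Uniform(100, 300), non-fatal event cost
Gamma(171, 116), fatal event cost Gamma(171, 14). Gamma is shape–scale
(mean = k·θ); this is the parameterization whose means coincide with the
base-case values and whose 95 % intervals are ±15 % (event costs), ±25 %
(disutility, fatality, risk reduction), and ±50 % (GRS cost) — both
checked empirically. Per (WTP, trial), a dedicated RNG stream is derived
from the master seed via `SeedSequence(seed, spawn_key=(wtp_index,
trial))`, so any single trial is re-runnable in isolation; runs are
bit-reproducible. In each trial the end states are re-derived and
strategies i–vi re-optimized before all ten are compared; optimality
shares are exact ratios of integer counts.

**One-way.** Each parameter is moved across its assessment range with the
strategy re-optimized at every value (an envelope property tested
explicitly: re-optimized NMB never falls below the frozen base-case
policy's NMB). **Two-way.** On a WTP × GRS-cost grid the emitted table
flags both weak optimality of the two-test strategy among all ten and
whether the genetic test is actually used; the informative region is
their conjunction, because an unaffordable GRS makes strategy v collapse
onto the TRS-only strategy and tie trivially.

## Synthetic data

The original likelihoods and population risk distribution derive from
national cohort and register data that cannot be redistributed, so the
package generates stand-ins with the documented structure:

- **Cohort**: 17,457 subjects with event rate 919/17,457 ≈ 5.3 % (the
  scale of the source cohorts), scores drawn from state-conditional
  bivariate Gaussians (binormal ROC model) with mean shift
  `√2·Φ⁻¹(AUC)`, within-state correlation 0 (bounded at |ρ| ≤ 0.09), and
  fatality Bernoulli(0.22) among events, independent of scores. The AUC
  defaults (TRS 0.80, GRS 0.65) are fixture conventions for a strong
  clinical score and a weaker genetic one; no acceptance-grade number
  depends on them.
- **Risk distribution**: Beta(1.5, 27) (mean ≈ 5.3 %, right-skewed, ~90 %
  of mass below 10 % risk) discretized by CDF differences over 101
  equal-width cells, standing in for the risk profile of a 45+ general
  population. This choice makes the *flat* Beta(1, 1) exactly uniform on
  the grid and keeps discretization error at machine precision relative
  to direct CDF differencing.

What the synthetic data does **not** emulate: the empirical shapes of real
score distributions (real TRS/GRS are not Gaussian within state), the
joint age/sex/covariate structure behind the risk distribution, and
miscalibration between stated priors and true event frequencies (the
generator is calibrated by construction). Population-level magnitudes —
strategy NMB differences, tested/treated shares, cost savings — therefore
reproduce the *qualitative* structure of the original results (two-test
optimized strategy first; optimized strategies dominate test-everyone
references; genetic testing worthwhile below a cost ceiling that rises
with WTP) but not their exact values. The end-state valuations, which
depend only on published parameters, are reproduced quantitatively
(costs within 1 %, QALYs and NMBs well within 0.5 %); the residual
0.1–0.4 % discrepancies are consistent with an unstated mid-horizon
discounting convention for the event-time flows.

## Problem sizes and runtime

The strategy solver is vectorized over the prior grid; a full ten-strategy
solve takes ~5 ms. The analysis drivers default to a 200-trial PSA on an
11-point WTP grid (≈25 s single-core); the full 1,000 × 51 design is
reachable through the `psa` block or CLI flags. Test-suite simulations use
cohorts of 3,000–100,000 subjects chosen so each statistical check has
power without slowing iteration.

## Known limitations

- The model is static: no re-testing, no deterioration over time, no
  competing mortality; statins are the only intervention.
- Scores arrive precomputed; building a TRS from clinical covariates or a
  polygenic score from genotypes is out of scope.
- EVPI-style value-of-information summaries and correlated parameter
  sampling in the PSA are not implemented.
- With a cohort of ~17k subjects and decile bins, likelihood-estimation
  noise moves population NMB differences between closely ranked
  strategies by a few euros; seeds are fixed everywhere to keep runs
  reproducible.
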