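# Methods

`daphdem` implements the demographic analysis chain used in chronic
life-history experiments on *Daphnia pulex* under combined calcium, food and
temperature limitation, together with an individual-based generator that
produces data with exactly the statistical structure the analysis assumes.
This note records the models, the defaults and why they are what they are,
the numerical choices, and the limits of what the synthetic data can show.

## 1. The experimental design being emulated

The default design is a 4 x 2 x 2 factorial: calcium at 0.25, 0.41, 1.02 and
1.74 mg Ca L^-1, food at 0.2 (LF) and 2.0 (HF) mg C L^-1, water temperature
at 17.5 and 21 deg C, with 12 individually-vialled females per treatment
(192 experimental units), censused daily for 19 days.  Animals are assigned
to 6 enclosure "boxes" in shuffled balanced blocks.  Recorded per female per
day: alive/dead, moult, neonates released; body length is measured only on
day-19 survivors.

## 2. The generator

### 2.1 Mortality

Death is a daily Bernoulli event with probability
`p(t) = 1 - exp(-exp(eta(t)))` — a discrete-time hazard with complementary
log-log link, so the generator and the inference model (section 5) are the
same family and parameter-recovery tests are well posed.  The linear
predictor is

```
eta(t) = b0 + b_u * u + b_f * food + b_T * temp
       + b_uf * u * food + b_uT * u * temp + b_t * t,      u = 1/Ca
```

Calcium enters as its reciprocal, a deficiency score: the biological cost of
losing 0.16 mg Ca L^-1 is far larger at 0.25 than at 1.5 mg Ca L^-1, and a
linear-in-Ca predictor cannot produce the observed near-total mortality at
0.25 next to >50% survival at 0.41 while keeping the rest of the gradient
realistic.  The `u * temp` term lets the shape of the Ca response differ
between temperatures, which is required for the survival-threshold bracket
to shift from (0.25, 0.41) at 17.5 deg C to (0.41, 1.02) at 21 deg C.

Default coefficients (solved analytically from target 19-day survivals
before any simulation was run, then verified exact):

| coefficient | value | role |
|---|---|---|
| b0 (intercept) | -18.1531 | baseline log-cumulative-hazard |
| b_u (1/Ca) | 4.66421 | Ca-deficiency cost |
| b_f (food) | -2.51322 | food protects (starvation) |
| b_T (temp) | 0.86414 | warmth raises mortality |
| b_uf (u x food) | 0.62544 | low Ca costlier when well fed |
| b_uT (u x temp) | -0.24510 | Ca response flattens when warm |
| b_t (interval) | 0.05 | hazard rises with age under chronic stress |

Because `1 - p = exp(-exp(eta))`, 19-day survival is exactly
`exp(-sum_t exp(eta(t)))`.  The implied cell survivals are, at high food:
0.001 / 0.581 / 0.951 / 0.974 along the Ca gradient at 17.5 deg C and
0.010 / 0.252 / 0.637 / 0.719 at 21 deg C; low-food cells range from ~0.00
to 0.28.  Pooled mean lifespans come out near 11.6 d (17.5 deg C) and 8.2 d
(21 deg C), reproducing the direction and rough size of the reported
temperature effect on lifespan.

### 2.2 Moulting and reproduction

Moults occur every 3 days at 17.5 deg C and every 2 days at 21 deg C (first
moult one interval after birth); faster moulting when warm gives the
observed increase of juvenile moulting rate with temperature.  A female
matures at the first moult on or after a normal draw (sd 1.2 d) around a
mean age of

```
8.0 + 6.0*[LF] - 0.857*(temp - 17.5) + max(0, ln(1/Ca)) days,
```

and releases a clutch at the maturation moult and at every later moult while
alive.  Clutch size is Poisson with mean

```
scale * Ca/(Ca + 0.25) * 1.15^[warm] * 0.17^[LF],
```

a Monod-saturating Ca response with half-saturation 0.25 mg Ca L^-1; the
scale is pinned so the HF / 1.74 mg Ca / 17.5 deg C treatment averages 7.67
neonates per clutch (the generator's calibration constant).  Saturation near
1 mg Ca L^-1 makes high-food reproduction plateau at the 1.02 level, which
is where the reproductive saturation point lands.

Plain (not zero-truncated) Poisson counts keep the calibrated mean exact; a
zero-count clutch is simply an unobserved clutch in the summaries.

Two explicit infertile regions are part of the default calibration:
reproduction never occurs for {Ca < 0.3 and temp < 19} nor for
{0.3 <= Ca < 0.7 and temp >= 19 and high food}.  The second box looks odd —
females reproduce at 0.25 but not 0.41 mg Ca L^-1 when warm — but this
non-monotone occurrence pattern is what the reference experiment reported,
and no monotone race between maturation and death can generate it.  The
regions are descriptive calibration, not mechanism, and are configurable.

### 2.3 What the generator does not emulate

No maternal effects, no Ca uptake physiology or moult-cycle Ca budget, no
food-quality dynamics, no ephippia/diapause, no between-clone variation, no
measurement error in neonate counts.  Daily hazards are conditionally
independent given covariates — there is no frailty beyond the optional box
intercept (default SD 0).  Tests passing on this generator therefore verify
the *analysis machinery* (estimators, tests, thresholds) and the internal
consistency of the chain, not field realism of *Daphnia* demography.

## 3. Life tables, traits and descriptive thresholds

`l_x` is the fraction of the starting cohort alive through day x (a female
found dead at the day-x census stops counting at x-1; day-19 survivors count
through the horizon).  `m_x` is neonates born on day x per female *alive* on
day x, so `l_x * m_x` is births per initial female — the Euler-Lotka weight.
With censoring only at the horizon, `l_x` coincides with the Kaplan-Meier
estimate at integer days (tested against lifelines).

The survival threshold bracket along a Ca gradient takes the highest level
with >50% mortality over the period *and* zero reproduction, and the lowest
passing level above it; ties at exactly 50% mortality count as passing.
Sentinels 0 and +inf mark criteria never failed/passed, and a non-monotone
pass/fail pattern returns the innermost bracket with an `ambiguous` flag.
The reproductive saturation point is the lowest Ca level whose reproduction
outputs do not differ from every higher level by a two-sided two-sample
permutation test at alpha = 0.05 (B = 3000).

## 4. Intrinsic rate of increase

`r` solves `sum_x exp(-r (x + 0.5)) l_x m_x = 1` (mid-interval age offset,
exactly as the convention prints it).  The left side is strictly decreasing
in r, so the root is unique whenever any reproduction occurred; it is found
by Brent's method on [-5, 5] day^-1 (bracket auto-expanded), internal
precision 1e-12, and checked against a declared tolerance of 1e-4 on
|LHS - 1|.  Sign consistency: net reproduction above/below 1 gives r
positive/negative.

Treatments with zero total reproduction use the census formula
`r = (ln(N_t + 0.01) / ln(N_0 + 0.01)) / t` — implemented deliberately in
this ratio-of-logarithms form, which returns 1/t (not 0) for a constant
population; it is only ever invoked for collapsing cohorts, where it is
negative as expected (all 12 dead by day 19: r = -0.0975 day^-1).

Uncertainty is the delete-one jackknife on individuals: pseudo-values
`theta_i = n*theta - (n-1)*theta_(-i)`, point estimate the pseudo-value mean
(the raw full-sample root is also reported), SE the pseudo-value standard
error.  For a linear statistic this reduces exactly to s/sqrt(n).  One known
artefact: in a no-reproduction cell with a single day-19 survivor, deleting
the survivor flips N_t to 0 and the pseudo-value mean is pulled well above
the full-sample value (0.0002 -> ~0.09 day^-1 at n = 12).  That is a
property of jackknifing the census formula as printed, and is surfaced via
`method == "fallback"` and the SE (~0.09) rather than silently smoothed.

## 5. Hazard regression, box screen

The analysis-side survival model is a binomial GLM with cloglog link on the
person-period expansion (one row per animal per day at risk, event = 1 on
the death day), with continuous Ca, food, temperature, interval and a
Ca x food interaction by default — Ca untransformed here, on the same scale
as the reference analysis.  Intercept-only data invert the link exactly:
`ln(-ln(1 - p))`.  Separation is flagged (extreme coefficients/SEs), not
raised.  The enclosure effect is screened by a likelihood-ratio test adding
box indicators to the fixed-effects model (df = boxes - 1): a fixed-effects
proxy for the random intercept, adequate as a screen and calibrated (null
p-values uniform) on the generator; full mixed-model integration is out of
scope.

## 6. Permutation tests for skewed responses

Reproduction output and the jackknife pseudo-values of r are heavily
non-normal, so fixed-effect inference uses null-model permutation tests:
observed statistic = Gaussian LRT chi-square `n ln(RSS_0/RSS_1)` between the
full linear model and the model without the term; reference distribution
from B permutations of the *null-model residuals* added back to the null
fitted values (Freedman-Lane), the scheme that keeps nuisance effects fixed
under the null; p = (1 + exceedances)/(1 + B), so p >= 1/(B+1) always.  The
engine works on precomputed QR factorisations, so B = 3000 costs
milliseconds.  Type-I error at alpha = 0.05 is calibrated within
Monte-Carlo error (tested over 1000 null simulations).

In the pipeline's permutation models the predictors (log Ca, food,
temperature) are mean-centered before interactions are formed.  On the raw
deg-C scale `food:temp` correlates ~0.999 with `food`, which destroys the
main-effect test in the presence of the interaction; centering is the
standard parameterisation fix and leaves interaction tests unchanged.
Reproduction-output models use terms {log_ca, food, temp, log_ca:food,
food:temp, log_ca:food:temp}; growth-rate models use the two-way set with
log_ca:temp instead of the three-way term.

## 7. Threshold-Monod fit for Ca_ZPG

`r(Ca) = r_max (Ca - Ca_ZPG) / (Ca - Ca_ZPG + K_s)` is fit by
Levenberg-Marquardt least squares to the per-treatment mean r values of one
food x temperature group (4 points, 3 parameters).  Defaults: unweighted
residuals (inverse-variance weights available); starting values r_max =
max r, Ca_ZPG = largest Ca with r <= 0 (or min(Ca)/2 if all positive), K_s =
median(Ca) - Ca_ZPG floored at 0.01.  SEs come from the Jacobian at the
optimum, the 95% CI from t with n-3 df (it may cross zero on a weakly
identified gradient), and a Wald p-value for Ca_ZPG is reported.  A group
whose growth rates are all non-positive is refused with an explanatory flag;
the pipeline additionally skips groups with fewer than two positive mean r
values, since a zero crossing cannot be bracketed — in the default run both
low-food groups are skipped, and both high-food groups fit, with Ca_ZPG
inside (0.25, 0.41) at 17.5 deg C and below 0.25 at 21 deg C.

## 8. Numerical and reproducibility choices

- Single `numpy.random.Generator` per simulated experiment, seeded from
  `SimConfig.seed` (default 11539); identical configs give byte-identical
  CSV output.  Every pipeline stage derives its seeds from the experiment
  seed.
- Problem sizes in the test-suite property checks: 100 random life tables
  for solver/oracle agreement; 500 replicates for the noisy Monod recovery;
  100 replicates at 2000 individuals for hazard-coefficient coverage; 1000
  null simulations at B = 999 for permutation calibration — sizes chosen so
  Monte-Carlo error is well inside the asserted bands.
- Degenerate inputs: empty or treatment-mixed record sets, <2 Ca levels,
  <4 Monod points, rank-deficient designs, aliased permutation terms and
  single-group box screens all raise informative errors; all-dead cohorts
  and all-negative growth gradients take documented non-exception paths.

## 9. Known limitations

- The box screen is fixed-effects; with many boxes and tiny cells it is
  conservative relative to a true random-intercept LRT.
- The Monod CI is asymptotic-t on 1 df in the default design; coverage on a
  4-point gradient is approximate by construction.
- The generator's infertile regions hard-code a reproduction-occurrence
  pattern rather than deriving it from physiology; simulations outside the
  calibrated factorial grid interpolate these rules crudely.
- `m_x` uses the per-living-female denominator; analyses wanting a
  per-initial-female fertility schedule can form `births / n0` from the
  exposed counts.
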