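# daphdem

Life-table demography of *Daphnia pulex* under combined calcium, food and
temperature limitation: from daily individual survival/reproduction records
to the intrinsic rate of natural increase, zero-growth calcium thresholds,
and hazard/permutation inference for factorial designs.

Soft-water lakes are losing calcium, and calcified zooplankton such as
*Daphnia* sit right at the failure point: below some ambient Ca
concentration they stop reproducing, and below a lower one they cannot
survive a moult cycle.  Whether warming tightens or relaxes those
thresholds is a population-level question, and the natural currency is the
intrinsic rate of increase

```
sum_x  exp(-r (x + 0.5)) * l_x * m_x  =  1        (Euler-Lotka)
```

with `l_x` the fraction of the cohort alive at age x days and `m_x` the
neonates produced on day x per living female.  Along a Ca gradient the
fitted growth rates follow a Monod curve with a zero-growth threshold,

```
r(Ca) = r_max * (Ca - Ca_ZPG) / (Ca - Ca_ZPG + K_s),
```

whose `Ca_ZPG` is the concentration at which the population just replaces
itself.  The package is aimed at ecologists and biostatisticians running (or
re-analysing) chronic *Daphnia* life-table experiments, and at anyone who
needs the individual pieces: a cohort life-table builder, a robust
Euler-Lotka solver with delete-one jackknife SEs, a threshold-Monod fitter,
discrete-time (person-period, cloglog) hazard regression, and Freedman-Lane
permutation tests for skewed responses.

Because raw individual-level data from such experiments are rarely
deposited, the package ships a calibrated individual-based generator
(`daphdem.simulate`) that reproduces the design and treatment-level patterns
of a published 4 Ca x 2 food x 2 temperature experiment (192 females, 19-day
horizon); every analysis stage is tested end to end on its output.

## Worked example

```python
from daphdem import (default_config, simulate_experiment, build_life_table,
                     jackknife_r, fit_monod_threshold)

records = simulate_experiment(default_config(seed=11539))   # 192 females
hf_cool = {}                                                # high food, 17.5 C
for r in records:
    ca, food, temp = r.treatment.key()
    if food == 2.0 and temp == 17.5:
        hf_cool.setdefault(ca, []).append(r)

for ca, recs in sorted(hf_cool.items()):
    est = jackknife_r(recs, horizon=19)
    print(f"Ca={ca:<5} r = {est.r_hat:+.4f} +/- {est.se:.4f}  ({est.method})")

cas = sorted(hf_cool)
fit = fit_monod_threshold(
    cas, [jackknife_r(hf_cool[ca], horizon=19).r_hat for ca in cas])
print(f"Ca_ZPG = {fit.ca_zpg:.3f} +/- {fit.se_ca_zpg:.3f} mg Ca/L, "
      f"95% CI ({fit.ci_ca_zpg[0]:.3f}, {fit.ci_ca_zpg[1]:.3f})")
```

prints

```
Ca=0.25  r = -0.0586 +/- 0.0000  (fallback)
Ca=0.41  r = +0.1812 +/- 0.0232  (euler_lotka)
Ca=1.02  r = +0.2461 +/- 0.0115  (euler_lotka)
Ca=1.74  r = +0.2679 +/- 0.0125  (euler_lotka)
Ca_ZPG = 0.264 +/- 0.002 mg Ca/L, 95% CI (0.237, 0.290)
```

Read: at high food and 17.5 deg C the cohort declines at 0.25 mg Ca L^-1
(no reproduction — r comes from the census fallback formula) and grows at
0.41 and above, so the zero-growth threshold sits between those levels; the
threshold-Monod fit places it at 0.264 mg Ca L^-1.  The same chain at 21
deg C puts Ca_ZPG below the lowest tested level — warming (within the
clone's preferred range) lowers the Ca requirement for population growth.

The whole analysis — life tables, traits, thresholds, growth rates, Monod
fits, the cloglog hazard model (including the negative Ca x food
interaction: low Ca costs more when food is plentiful), the box-effect LRT
screen and permutation tests — runs in one call or one command:

```
daphdem pipeline --out results/run1 --seed 11539
```

writing per-stage CSVs (`events`, `summary`, `life_tables`, `traits`,
`demography`, `thresholds`, `monod`, `hazard`, `permutation`) and a
`report.json` with the qualitative summary.  Individual stages are also
exposed (`daphdem simulate|lifetable|demography|monod|hazard|permtest`).

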