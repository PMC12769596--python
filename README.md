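# mbfd — individually randomized multiple baseline factorial designs

`mbfd` is a toolkit for designing, simulating and analyzing **multiple
baseline factorial designs (MBFD)**: small-sample longitudinal trials —
typical of rare-disease and behavioral research — that evaluate two
interventions (A and B) and their *sequential* combination against a
standard-of-care control. Every participant starts under control, is
individually randomized to an A-first or B-first sequence whose
intervention start is staggered across sequences, spends one or more
periods on the single intervention, and finishes on the combined
intervention AB. The outcome is measured once at the end of each period.

## Model

For participant *i* at period *j* the continuous outcome is modeled with a
participant random intercept:

```
Y_ij = u + β_T·j + (treatment terms) + α_i + ε_ij,
α_i ~ N(0, τ²),   ε_ij ~ N(0, σ²),   ICC = τ²/(τ²+σ²)
```

Three mean models target different estimands:

| model | treatment terms | combined (AB vs control) effect |
|---|---|---|
| 1 additive | β_A·X_A + β_B·X_B (X_A=X_B=1 in AB) | β_A + β_B |
| 2 interaction | + β_I·X_A·X_B | β_A + β_B + β_I |
| 3 multi-arm | β_A·Z_A + β_B·Z_B + β_C·Z_C (mutually exclusive) | β_C |

Estimation is by

* **LMM** — restricted maximum likelihood under compound symmetry
  (profiled over the variance ratio), Wald t-tests with **Satterthwaite**
  degrees of freedom; or
* **GEE** — identity-link Gaussian estimating equations with an
  exchangeable working correlation, with the Liang–Zeger robust sandwich
  variance and the **Mancl–DeRouen (MD)** small-sample bias-corrected
  sandwich (t reference with df = N − p).

A Monte Carlo engine (`mbfd.evaluate`) crosses sample size, ICC and effect
patterns to estimate bias, type I error and power with Bonferroni-adjusted
per-coefficient tests (0.05/2 for model 1, 0.05/3 for models 2–3).

## Worked example

```python
import mbfd

design = mbfd.build_standard_design()      # 6 sequences x 5 periods
print(design.to_text())
# C,A,AB,AB,AB
# C,C,A,AB,AB
# C,C,C,A,AB
# C,B,AB,AB,AB
# C,C,B,AB,AB
# C,C,C,B,AB

alloc = mbfd.randomize(design, 30, seed=1)          # 5 per sequence
data = mbfd.simulate_trial(
    design, alloc,
    mbfd.EffectParameters(beta_a=0.8, beta_b=0.8, beta_c=1.6),
    mbfd.VarianceComponents.from_icc(0.10),
    seed=42,
)
fit = mbfd.fit_reml(data, mbfd.ModelSpec(3))
print(fit.summary_frame().round(4))
```

```
              coef      se        df        t       p
intercept  -0.0903  0.2035  141.5418  -0.4438  0.6579
period      1.0220  0.0999  137.8025  10.2265  0.0000
beta_a      0.8849  0.2942  144.2094   3.0076  0.0031
beta_b      0.7109  0.2942  144.2094   2.4163  0.0169
beta_c      1.4974  0.3215  117.1445   4.6573  0.0000
```

`beta_a`/`beta_b` estimate each intervention's effect versus control in the
absence of the other; `beta_c` is the effect of the sequential combination
versus control (true values here: 0.8, 0.8, 1.6). The Satterthwaite df
reflect that treatment contrasts draw on both within- and
between-participant information.

Power for a planned scenario:

```python
from mbfd.evaluate import ScenarioConfig, run_scenario
res = run_scenario(ScenarioConfig(
    n_participants=30, icc=0.05, effects=(0.8, 0.8, 1.6),
    model_id=1, n_sim=2000, seed=11))
print(res.summary[["estimator", "coefficient", "rejection_rate"]])
#   estimator coefficient  rejection_rate
# 0       LMM      beta_a          0.7955
# 1       LMM      beta_b          0.8115
# 2       GEE      beta_a          0.8280
# 3       GEE      beta_b          0.8300
# 4    GEE-MD     beta_a           0.7555
# 5    GEE-MD     beta_b           0.7535
```

Uncorrected GEE looks most powerful because its small-sample type I error
is inflated; the MD correction restores the nominal level at the cost of a
few points of power — LMM sits in between.

The same functionality is exposed on the command line:

```bash
mbfd simulate --config trial.yml --out trial.csv --seed 1
mbfd fit --data trial.csv --model 3 --estimator GEE-MD
mbfd power --config scenarios.yml --out power.csv --seed 1
mbfd reproduce-tables --table 4 --n-sim 5000 --out table4.csv
```

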