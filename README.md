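# milkbot

Tools for quantifying the **shape and magnitude of dairy lactation
curves** from test-day milk records. The package is aimed at dairy
scientists, veterinarians and herd-management analysts who want to go
beyond cumulative yield: it fits individual lactations to a
four-parameter model, derives whole-lactation metrics in closed form,
and compares herd-parity groups statistically.

## The model

Daily milk yield on day-in-milk *t* (DIM, *t* = 1 at calving) is

```
Y(t) = a · (1 − exp((c − t)/b) / 2) · exp(−d·t)
```

a product of a saturating *growth* of productive capacity (the integral
of a right-sided Laplace growth-rate density), a first-order *death*
(senescence) process, and a magnitude scalar:

| parameter | name   | units  | meaning |
|-----------|--------|--------|---------|
| `a` | scale  | kg/day | theoretical maximum daily yield; pure magnitude |
| `b` | ramp   | days   | time constant of the early rise (one ramp past the offset, growth is ~82% complete) |
| `c` | offset | days   | lag between calving and the growth midpoint; near-unidentifiable from monthly data |
| `d` | decay  | 1/day  | senescence rate; `0.693/d` is persistency as a half-life |

Everything downstream is closed-form: peak day
`t_peak = c − b·ln(2bd/(1+bd))`, peak milk `Y(t_peak)`, persistency
`0.693/d`, cumulative yield between any two days, and the 305-day
cumulative yield M305.

Two fitting engines share one Levenberg–Marquardt core: pure least
squares (positivity enforced by log-reparameterization) and a MAP engine
with independent Gaussian priors that returns the population means when
given no data and converges to the least-squares fit as the priors
flatten. Herd-parity groups of fitted lactations are compared by
two-sided Z-tests, and each group gets a **divergence score** — the
number of same-parity peer groups whose mean differs at p < .05 (21
groups ⇒ expected score ~1 under the null). A synthetic cohort generator
reproduces the study structure (herds × parity groups × monthly
test-day schedules, truncated at 305 DIM, Gaussian test-day noise) with
a full truth ledger, so the whole pipeline is testable without any
external data.

## Worked example

```python
import numpy as np
from milkbot import (MilkBotParams, predict, derived_metrics,
                     Lactation, TestDay, fit_least_squares)

# population-mean first-parity curve
p = MilkBotParams(scale=38.66, ramp=31.43, offset=-0.5, decay=0.000974)
m = derived_metrics(p)
print(f"peak {m.y_peak:.1f} kg/day on DIM {m.t_peak:.1f}, "
      f"M305 {m.m305:.0f} kg, persistency {m.persistence:.0f} d")

# fit a highly irregular real-world 10-test lactation
dims = np.arange(15.0, 306.0, 30.0)
milk = [47.7, 83.1, 84.4, 32.2, 8.2, 55.4, 77.2, 64.5, 34.0, 24.1]
lact = Lactation("example", "N", "P2plus",
                 tuple(TestDay(d, y) for d, y in zip(dims, milk)))
fit = fit_least_squares(lact)
print(f"scale {fit.params.scale:.1f} kg/day, RMSE {fit.rmse:.1f} kg")
```

prints

```
peak 34.4 kg/day on DIM 88.2, M305 9621 kg, persistency 711 d
scale 74.9 kg/day, RMSE 23.0 kg
```

— the smooth fitted curve leaves a 23 kg root-mean-square residual on
this erratic lactation, illustrating RMSE's role as a consistency
measure (an ordinary lactation fits within ~4 kg).

The same pipeline is scriptable from the shell:

```
milkbot simulate --seed 1 --out sim/          # synthetic cohort + truth
milkbot fit sim/cohort.csv --out params.csv   # per-lactation parameters
milkbot compare params.csv --out-prefix out   # summaries + divergence
```

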