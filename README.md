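# rcsaem

SAEM estimation of the **Ramsay-curve three-parameter normal ogive (RC-3PNO)
model**: binary item responses are modelled by

P(U<sub>ij</sub> = 1 | θ<sub>i</sub>) = c<sub>j</sub> + (1 − c<sub>j</sub>) Φ(a<sub>j</sub> θ<sub>i</sub> + b<sub>j</sub>),

while the latent-trait density is *not* assumed normal but represented as a
**Ramsay curve** — the normalized exponential of a B-spline expansion on a
fixed grid of 121 points on [−6, 6]:

g(x<sub>q</sub> | η) = exp(B\*<sub>q</sub> η) / Σ<sub>r</sub> exp(B\*<sub>r</sub> η),  m = degree + knots − 1 coefficients.

Item parameters and the density are estimated **jointly** by a stochastic
approximation EM (SAEM) algorithm with probit data augmentation: each
iteration samples abilities on the grid, "knows-the-answer" indicators, and
truncated-normal probit variates; mixes the exponential-family sufficient
statistics with a Robbins–Monro gain (1 for the first 1000 iterations, then
1/(k − 1000)); and performs closed-form conjugate updates for the items plus
a Newton–Raphson MAP refit of the spline coefficients.

This matters in practice because fitting a 3PNO with a fixed standard-normal
latent density to data from a skewed population biases the item intercepts
heavily (|bias| > 0.2 in the benchmark below), while the Ramsay-curve fit
removes that bias.

Audience: psychometricians and biostatisticians running item-response
analyses or recovery simulations with non-normal latent traits.

## Worked example

```python
import numpy as np
from rcsaem import (build_grid, build_basis, make_true_world, gen_responses,
                    run_saem, SAEMConfig, density_moments)

grid = build_grid()                    # 121 points on [-6, 6]
basis = build_basis(grid, knots=6, degree=3)   # m = 8 spline coefficients

# truth: skewed latent density (skewness 1.72, kurtosis 9.16), 1000 people,
# 30 items with a ~ U(1, 2.5), b ~ N(0, 1), c ~ Beta(5, 17)
world = make_true_world("skewed", N=1000, J=30, basis=basis, seed=7)
U = gen_responses(world.theta, world.items, np.random.default_rng(8))

fit = run_saem(U, knots=6, degree=3, config=SAEMConfig(mode="rc", seed=1))
print("iterations:", fit.iterations)
print("mean |b error|:", np.mean(np.abs(fit.items.b - world.items.b)))
print("fitted density:", density_moments(fit.density))
```

Output from this exact script:

```
iterations: 2500
mean |b error|: 0.2490932017743242
fitted density: MomentSummary(mean=-0.0004676532148173012,
    sd=np.float64(1.0012555753480818),
    skewness=np.float64(1.3611135661366673),
    kurtosis=7.7389879034309965)
```

The fit runs its full 2500-iteration budget (the Robbins–Monro tolerance of
1e-4 rarely triggers earlier), recovers the intercepts to roughly ±0.25 on
this single draw, pins the latent scale to mean 0/sd 1, and reproduces the
strong positive skew and heavy tails of the generating density (fitted
skewness 1.36 and kurtosis 7.7 against generated values 1.72 and 9.16 —
the ability-posterior blurring attenuates the shape somewhat; see
`docs/methods.md`).

The same model is available from the shell:

```bash
rcsaem simulate --density skewed --n 1000 --j 30 --seed 7 --out resp.csv
rcsaem fit --responses resp.csv --knots 6 --degree 3 --mode rc --seed 1 \
           --out fit.json --density-out density.tsv
rcsaem select --responses resp.csv --knots 2..6 --degree 3,4   # AIC/BIC/HQIC
```

## Layout

- `rcsaem.grid_spline` — grid, B-spline basis, Ramsay densities, moments
- `rcsaem.ramsay_estimation` — spline-coefficient MAP (Newton–Raphson)
- `rcsaem.irt_core` — 3PNO probabilities and likelihood tables
- `rcsaem.saem_engine` — samplers, sufficient statistics, SAEM loop
- `rcsaem.synthesis` — true densities, ability/item/response generators
- `rcsaem.evaluation` — information criteria, bias/RMSE/ISE, study drivers
- `rcsaem.io`, `rcsaem.cli` — strict CSV/JSON/TSV formats and the CLI

See `docs/methods.md` for the model, algorithmic choices, and limitations.
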