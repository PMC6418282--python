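# gensmr

Population-density estimation for animals that cannot all be individually
identified, using **generalized spatial mark-resight (SMR)** models: a
live-trap *marking* process puts GPS collars on a subset of a population, a
clustered *camera-trap* array resights marked (identified) and unmarked
(identity-latent) animals, and collar *telemetry* sharpens the spatial
scale of detection.  The package is aimed at wildlife biologists designing
and analyzing large-area carnivore surveys — the defaults emulate a puma
survey spanning roughly 15,000 km² — but nothing in it is species-specific.

## The model

Activity centers `s_i` of `N` animals are uniform on a rectangular state
space `S`; abundance is handled by data augmentation (`z_i ~ Bern(ψ)`,
`N = Σ z_i`, density `D = 100·N/|S|` per 100 km²).  The population is
observed three ways, sharing one spatial scale `σ_d`:

- **marking** — binomial live-trap captures,
  `Y^M_ij ~ Binom(E^M_ij, 1 − exp(−λ₀^M e^{−d²_ij/2σ_d²}))`,
- **resighting** — Poisson camera counts,
  `Y^R_ij ~ Pois(E^R_ij · λ₀^R e^{−d²_ij/2σ_d²})`, identity known only for
  marked animals; unmarked detections are allocated to individuals by
  latent-identity MCMC (Chandler–Royle-style updates), optionally excluding
  allocations that mix observed sexes (`sex_i ~ Bern(p^sex)`),
- **telemetry** — thinned GPS fixes, bivariate normal about the center.

`E^M`/`E^R` are individual-by-trap exposure matrices (trap effort × known
alive/marked status), and an optional one-time relocation
`s^R_i ~ BVN(s^M_i, σ_t² I)` truncated to `S` accommodates activity-center
transiency between the marking and resighting periods.  Conventional SMR
(the marking process ignored) is the `generalized=False` variant; a null
spatial capture-recapture model (all identities known) is the degenerate
case used for survey-design evaluation.  See `docs/methods.md` for the
full account.

## Worked example

```python
import numpy as np
from gensmr import (Parameters, ModelSpec, MCMCConfig,
                    simulate_dataset, run_mcmc, summarize, marked_fractions)

truth_params = Parameters(lam0_m=0.007, lam0_r=0.019, sigma_d=6.51,
                          sigma_t=17.4, p_sex=0.33)
data, truth = simulate_dataset(params=truth_params, density_per_100km2=0.84,
                               seed=1)
print(f"simulated N={truth.n}, {truth.marked.sum()} marked, "
      f"{len(data.unmarked)} unmarked detections")

spec = ModelSpec(generalized=True, use_telemetry=True, use_transience=True,
                 use_sex_constraint=True, A=350)
chains = run_mcmc(data, spec, MCMCConfig(n_iter=30000, burn_in=5000, thin=5,
                                         seed=2))
print(summarize(chains).table.round(3))
```

This run printed `simulated N=178, 20 marked, 64 unmarked detections`
(truth drawn at density 0.84/100 km²; the realized population works out to
0.95/100 km² over the 18,672-km² buffered state space) and the summary

```
            mode     mean      sd  hpdi_low  hpdi_high  hpdi_width     cv
lam0_m     0.012    0.013   0.004     0.006      0.022       0.016  0.381
lam0_r     0.021    0.023   0.006     0.012      0.034       0.023  0.293
sigma_d    6.486    6.450   0.192     6.086      6.829       0.743  0.030
sigma_t   12.326   13.066   2.292     8.937     17.807       8.870  0.186
psi        0.514    0.548   0.131     0.326      0.827       0.502  0.255
p_sex      0.243    0.254   0.069     0.126      0.392       0.265  0.284
N        179.000  191.763  45.360   110.000    282.000     172.000  0.253
D          0.887    1.027   0.243     0.589      1.510       0.921  0.274
n_um      39.000   38.893   4.845    30.000     48.000      18.000  0.124
```

— the density mode 0.89/100 km² with 95% HPDI (0.59, 1.51) covers the
realized truth 0.95; `σ_d` is pinned tightly by telemetry (6.49 vs the
generating 6.51); the transiency scale's interval (8.9, 17.8) covers the
generating 17.4 but stays wide, as expected when relocating animals are
seldom photographed; and the female-fraction interval (0.13, 0.39) covers
the generating 0.33.  `marked_fractions(179, 20, 39)` then reports what
share of the estimated population carried spatial information.

A command-line interface mirrors the library:

```bash
gensmr simulate --seed 1 --out survey/
gensmr fit --data survey/ --transience --iters 30000 --seed 2 --out fit/
gensmr design-eval --reps 100 --seed 3 --out design/
```

## Survey-design evaluation

`run_design_study` (or `gensmr design-eval`) reproduces the pre-deployment
workflow for clustered camera designs: simulate a population of known
density on the buffered design, fit a null spatial capture-recapture model
per replicate, and aggregate relative bias, mean posterior CV, RMSE of the
posterior-mode density, and 95%-interval coverage.

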