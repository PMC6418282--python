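# Methods

`gensmr` estimates animal population density from three linked observation
processes over a shared latent activity-center process: live-trap *marking*,
camera-trap *resighting* with latent identities for unmarked detections, and
GPS *telemetry* on marked individuals.  This note documents the model, the
sampler, the synthetic-data generator, the numerical choices, and the known
limitations.

## Model

**State space and density.**  Activity centers live on a rectangular planar
state space `S` (km, equal-area projection), the detector bounding box
buffered by 25 km by default (about three detection-scale lengths, so
individuals outside `S` are effectively undetectable).  Generalized models
buffer the combined live-trap and camera extent; conventional models buffer
the cameras only.  Abundance is handled by data augmentation: a pool of `A`
potential individuals with inclusion indicators `z_i ~ Bernoulli(psi)`,
centers `s_i ~ Uniform(S)`, and sexes `sex_i ~ Bernoulli(p_sex)`
(1 = female).  Density is the derived quantity `D = 100 * N / |S|` per
100 km^2 with `N = sum(z)`.

**Marking.**  Captures at the `J_M` live-trap locations are binomial over
exposure trap-days: `Y^M_ij ~ Binomial(E^M_ij, 1 - exp(-lam0_m *
exp(-d_ij^2 / 2 sigma_d^2)))`, a hazard half-normal detection function with
distances from the marking-period center `s^M_i`.  A marking "occasion" is
one trap-day; `E^M` stores operational days per trap.

**Resighting.**  Camera counts are Poisson over exposure occasions:
`Y^R_ij ~ Poisson(E^R_ij * lam0_r * exp(-d_ij^2 / 2 sigma_d^2))` with
distances from the resighting-period center `s^R_i`.  Identities are known
for marked individuals (while marked); unmarked detections enter as
identity-free records to be allocated.  `lam0_r` and `sigma_d` may be
sex-specific; `sigma_d` is pooled across the marking, resighting, and
telemetry processes.

**Exposure and mark status.**  Per-individual, per-detector exposure
matrices account for unequal trap operation, known deaths, and mid-survey
markings.  A status matrix `m` (one row per marked individual, one column
per resighting occasion; 0 = not yet marked, 1 = marked, 2 = dead, with 2
absorbing) governs which occasions contribute known-identity counts and
which latent records an individual may own: code 0 admits unmarked records,
code 1 only known detections, code 2 nothing.

**Transiency.**  Optionally, one activity-center relocation between the
marking and resighting periods: `s^R_i ~ BVN(s^M_i, sigma_t^2 I)` truncated
to `S`.  The truncation mass is exact — the product of two 1-D normal CDF
differences, valid because the covariance is diagonal and the region
rectangular — which prevents the downward bias in `sigma_t` that an
untruncated kernel produces near the state-space edge.

**Telemetry.**  Thinned GPS locations (at most one per occasion, to limit
serial dependence) are independent bivariate normals around `s^R_i` with
per-axis sd `sigma_d`, untruncated (fixes can fall anywhere).

**Sex as a partial identity.**  Records carry an observed sex (female,
male, or unknown).  With the sex constraint on, a record can only be
allocated to an individual of matching sex, so a female and a male record
can never share an owner; unknown-sex records are unconstrained.  `p_sex`
is estimated from the included individuals.

**Priors.**  `lam0_m, lam0_r ~ U(0, 10)`, `sigma_d ~ U(0, 50)` km,
`sigma_t ~ U(0, 100)` km, `psi ~ Beta(1, 1)`, `p_sex ~ Beta(1, 1)`.  Flat
priors on the natural scale, with bounds wide relative to any plausible
carnivore survey; the random-walk updates operate on the log scale with the
matching Jacobian so the flat natural-scale prior is preserved.

## Sampler

Metropolis-within-Gibbs, one sweep per iteration:

1. **Detection parameters** — log-scale random walks.  Baseline rates use an
   exact shortcut: scaling `lam0` scales every rate, so the likelihood delta
   needs only per-row count totals and exposure-rate sums.
2. **`sigma_t`** — a plain log random walk, plus a joint move that rescales
   the resighting centers of all data-free individuals (no telemetry, no
   counts) together with `sigma_t` about their marking centers.  This is a
   deterministic-map proposal with Jacobian `c^(2 n_moved)`; for an
   untruncated kernel it would leave the prior invariant exactly, so its
   acceptance depends only on the truncation masses and the zero-detection
   terms.  Without it the transiency scale mixes very slowly, because most
   augmented individuals' relocations are pure prior draws that shackle the
   plain update.
3. **Activity centers** — per-individual bivariate normal random walks,
   proposed and accepted for all individuals at once (the likelihood
   factorizes over individuals given the parameters); proposals outside `S`
   are rejected.  Excluded individuals (`z = 0`) are redrawn from the prior,
   which keeps the inclusion update correct.
4. **Latent identity allocation** — for each unmarked record, propose a
   uniformly chosen eligible owner (included, permitted by `m` at the
   record's occasion, sex-compatible) and accept by the Poisson
   occasion-level likelihood ratio `(y_a / lam_a) * (lam_b / (y_b + 1))`
   computed at the record's (camera, occasion) cell.  The proposal is
   symmetric because the eligible set does not depend on the current owner.
5. **Sexes** — Gibbs.  Owners of sexed records are forced to the consistent
   value; otherwise the update combines the Bernoulli(`p_sex`) prior with
   the sex-specific likelihood when sex-specific detection is on.
6. **Inclusion** — `z` for individuals owning no data from its Bernoulli
   posterior (prior odds times the all-zero-history likelihood), then
   conjugate Beta updates for `psi` and `p_sex`.

Proposal scales adapt toward ~32% acceptance during burn-in only.  Distance
and rate matrices are cached and updated incrementally; with auditing on,
every retained draw re-derives them from scratch and checks the latent-state
invariants (allocation conservation, eligibility, sex exclusion).  The
sampler was validated against brute-force enumeration on a small instance
(four individuals, two cameras, one live trap; the activity-center integral
done by midpoint quadrature on a 15x15 grid): the sampled posterior over `N`
agrees with enumeration to within 0.004 total variation at the run lengths
used in the test suite.

**Chain lengths.**  The test suite and the acceptance script use short
chains (a few thousand sweeps, burn-in about a quarter of the run) at
reduced problem sizes chosen so the whole suite completes in minutes;
full-survey analyses should use runs one to two orders of magnitude longer,
especially for `sigma_t`.  Augmentation sizes follow the survey defaults
(250 conventional, 350 generalized with telemetry, 600 without), and the
sampler warns whenever a retained draw exceeds `0.95 A` — treat that as an
instruction to raise `A`, since a saturated augmentation truncates the
abundance posterior and distorts the fit (we observed both inflated and
deflated density modes on otherwise identical data when `A` was only ~2.5x
the expected abundance; ~3x or more the plausible posterior maximum is
safe).

## Synthetic data

The generator produces truth plus observations under exactly the model
above, with defaults emulating an expansive semi-arid puma survey: density
0.84/100 km^2; nine 3x3 camera clusters at 3.5-km spacing (28-km
longitudinal, alternating 36/45-km latitudinal cluster spacing, staggered),
17 weekly occasions; ~30 live-traps uniform over the camera extent with
uniform 2-42 trap-day effort (mean 22); `lam0_m = 0.007`/trap-day,
`lam0_r = 0.019`/occasion, `sigma_d = 6.51` km, `sigma_t = 17.4` km,
`p_sex = 0.33`; sex identifiable on 52% of unmarked detections; telemetry
thinned to one fix per occasion with 15% missingness.  Those settings yield
on the order of 10 marked animals and around 10^2 camera detections, the
magnitudes a real survey of this design produces.

Placing the live-traps inside the camera extent is deliberate: marked
animals then sit closer to cameras than the population at large, which is
the regime where conventional SMR (ignoring the marking process) is biased
and the generalized model is needed.

What the generator does *not* emulate: movement trajectories (telemetry is
i.i.d. around the center, no autocorrelation), habitat structure (uniform
centers, rectangular space), behavioral responses to traps, unknown
population turnover, or misclassified mark status (an optional corruption of
mark-status labels was considered and dropped — analyzed datasets resolve
those deterministically during preprocessing).  Recovery tests on these data
therefore demonstrate correctness of the estimator under its own
assumptions, not robustness to their violation.

## Design evaluation

`run_design_study` reproduces the pre-deployment workflow: simulate a
population at stated density on the design buffered by 3 sigma, generate
fully identified Poisson SCR counts, fit a null SCR model per replicate, and
aggregate relative bias (normal-approximation 95% CI), mean posterior CV
(posterior sd / posterior mode), RMSE of the posterior-mode density, and
coverage of the 95% HPDIs (Wilson 95% CI).  Abundance is drawn Poisson at
the stated density — the realized population is one draw of the uniform
point process the fitted model assumes — and performance is measured against
the nominal density.  Replicate failures are excluded with a warning below a
5% failure fraction and abort the study above it.

At the stated low-information settings (baseline rate 0.05/occasion, sigma
5 km, 17 occasions) a full hierarchical fit leaves substantial detection-
parameter uncertainty; an independent maximum-likelihood cross-check
(grid-integrated full likelihood, asymptotic variance from the numerical
Hessian) gives per-replicate density CVs of 0.28-0.35, matching this
package's posterior CVs.  Design summaries with materially smaller CVs are
achievable only when the detection parameters are essentially known: fixing
them at truth drops the CV to ~0.12 and the RMSE to ~0.15 on the same
replicates.  Both readings of "performance of a fitted null model" appear in
the design literature; this package reports the full-fit numbers.

## Numerical choices

- Distances are Euclidean km in double precision; rates accumulate in log
  space; `log(1 - p)` for the binomial marking terms is computed as `-h`
  from the hazard, which is exact and stable for tiny rates.
- Posterior point estimates are posterior modes: KDE argmax (Gaussian
  kernel, Scott bandwidth, 512-point grid over the sample range) for
  continuous parameters; the most frequent value with ties broken toward
  the smaller value for integer parameters (`N`, `n_UM`).  Modes from a
  KDE inherit a bandwidth sensitivity of order the grid resolution; the
  reported HPDIs do not depend on the KDE.
- 95% HPDIs are the shortest contiguous interval containing `ceil(0.95 n)`
  sorted draws.
- The combined detected-fraction percentage is reported additively across
  its two denominators (marked fraction of the population plus detected
  fraction of the unmarked), each rounded to two decimals before summing,
  matching the conventional report; note `100 (n_M + n_UM) / N` is a
  different quantity.
- Truncated-normal draws use per-axis inverse-CDF sampling — exact even
  when the mean sits in a corner of the rectangle, where rejection sampling
  would stall.

## Limitations

- Closed population apart from *known* deaths and mid-survey markings;
  unknown recruitment or emigration biases `D`.
- One relocation event at most; fully transient (per-occasion) centers are
  out of scope.
- `sigma_t` is weakly identified without telemetry; expect very wide
  intervals, and treat point estimates from camera-only fits with caution.
- The KDE mode can sit below the posterior mean for the right-skewed
  density posteriors typical of sparse surveys; with diffuse data the two
  point summaries can differ by ~10%.
- Conventional (marking-ignored) fits on sparse identity-latent data are
  only weakly identified: under flat priors the joint posterior of
  `(lam0_r, N)` can drift toward many-owners/low-rate configurations,
  because the number of admissible allocations grows with the number of
  included individuals.  With detection parameters fixed the latent-identity
  machinery is calibrated (checked against truth and by enumeration), so
  the drift is a prior-sensitivity of the conventional model itself, worst
  when few marked animals anchor the baseline rate and when unmarked
  detections are mostly spatial singletons — which model-faithful synthetic
  data produce, since the generator has no behavioral trail re-use to
  concentrate repeated detections at a camera.  Generalized fits with
  telemetry are well anchored in the same settings.  Conventional fits
  deserve informative detection-rate priors or abundant marked-resight
  data; treat flat-prior conventional estimates with caution.
- No model-selection machinery: variants are compared structurally.
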