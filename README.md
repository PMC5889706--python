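# smrpva

Density and viability analysis for small, isolated populations of
territorial carnivores, built around two estimators:

* **Spatial mark-resight (SMR) with telemetry.** A live-trapped subset of
  the population carries individually identifiable marks; baited camera
  stations resight the marked animals and count the unmarked ones.  A
  generalized SMR model combines the marking (trapping) process, the
  camera resightings, the unmarked counts and telemetry into one Bayesian
  estimate of density and abundance.
* **Population viability analysis (PVA).** An Euler-Lotka solver turns
  vital rates into a maximum intrinsic growth rate, which drives
  stochastic theta-logistic projections with an annual Poisson number of
  human-caused mortalities, yielding quasi-extinction probabilities.

The package also ships a habitat module (vegetation-cover rasters and the
discrete state space), a synthetic-data generator with the exact
statistical structure the model assumes, plain-text I/O, and a
reproducible end-to-end pipeline.

## The model

Each animal *i* has a latent activity center *s_i* on a discrete grid *S*
of 100-m cells, distributed by an inhomogeneous point process
`p_g ∝ area_g · exp(α₁ · veg_g)` where `veg_g` is the cell's vegetation
cover.  Detection decays with distance via a half-normal kernel with
sex-specific scale σ:

* captures: `ycap_ij ~ Binomial(Ktrap_j, p0cap_i · exp(−d_ij²/2σ²))`,
  `logit(p0cap_i) = β₀ + β₁·sex_i`
* resightings: `ycam_ijk ~ Bernoulli(p0cam_ijk · exp(−d_ij²/2σ²))`,
  `logit(p0cam_ijk) = δ₀ + δ₁·sex_i + δ₂·days_jk` with `days_jk` the days
  since the station was last baited
* unmarked counts: `nU_jk` is the sum of latent Bernoulli detections of
  the never-trapped animals (marginalized exactly as a Poisson-binomial)
* telemetry: fixes are bivariate normal around *s_i* with sd σ.

The unknown population size is handled by data augmentation
(`z_i ~ Bernoulli(ψ)`, `N = Σ z_i`), and the model is fit by
Metropolis-within-Gibbs MCMC (compiled with numba).  Density is the
number of included animals whose center falls in habitat (cover > 40 %),
divided by the habitat area.

The PVA recursion is
`N_{t+1} = max(0, N_t · exp(r(1 − (N_t/K)^θ) + ε_t) − H_t)` with
`ε_t ~ Normal(0, σ_env)` and `H_t ~ Poisson(λ)`; a trajectory is
quasi-extinct once it falls below 2 animals.

## Worked example

`examples/03_fit_density.py` simulates a survey of 10 animals along a
31-camera transect (39 nightly occasions, 12-night trap effort), fits the
SMR model with a reduced protocol (3 chains × 4,000 iterations), and
extrapolates density to two larger vegetated areas:

```
true N = 10; posterior median N = 10, 95% CRI [10, 11]
sigma_female: 283 m (truth 278), sigma_male: 1160 m (truth 1141)
largest R-hat: 1.026 (< 1.1 indicates convergence)
density: 1.24 +/- 0.05 per km^2 of habitat (CRI 1.22-1.35, habitat 8.2 km^2)
extrapolated to 36.9 km^2: 45 (CRI 45-50)
extrapolated to 25.6 km^2: 31 (CRI 31-34)
```

The posterior abundance covers the truth, both movement scales are
recovered, and the chains pass the split-chain R-hat check.  The other
example scripts are equally small: `01` builds a cover mask and state
space, `02` generates a survey, `04` prints the growth-rate table
(r = 0.144 / 0.205 / 0.265 at adult survival 0.7 / 0.8 / 0.9) and `05`
prints the 3 × 3 × 2 extinction-probability grid, e.g. at carrying
capacity 30 with ordinary logistic growth (θ = 1): 0 %, 33 % and 99 %
extinction risk at 1, 2 and 3 mean annual mortalities.

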