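# Methods

## Scope

`alpgraze` analyses fine-scale activity patterns of GPS-collared livestock
on heterogeneous (subalpine-type) pastures.  The chain is: classify 20-s
GPS fixes into grazing / resting / walking; count classified fixes per
activity on a 25 m lattice with gap-correction weights; derive seven
environmental/management covariates per cell; fit a weighted zero-inflated
negative-binomial hurdle regression per activity with spatially structured
random effects; and run the surrounding procedures (prior sensitivity,
spatial vs non-spatial comparison, subset regressions, activity budgets,
cross-area rank correlations).  A synthetic-data module generates
landscapes and behaviour-switching tracks so every stage is testable
without field data.

## The statistical model

Counts `y_i` of one activity in cell `i` follow a hurdle:

    Pr(y_i) = pi * 1[y_i = 0] + (1 - pi) * NB(mu_i, kappa | y > 0)

with a single zero proportion `pi` per model and NB over-dispersion
`kappa` (mean/size parameterisation, variance `mu + mu^2/kappa`; large
`kappa` approaches a Poisson).  The positive part has the log link

    log(mu_i) = beta' x_i + f(s_i) + f(z_i) + eps_i

where `x_i` are the centred/standardised covariates, `f(s)` a planar
second-order random walk over the lattice (13-point thin-plate-like
stencil, free boundary, rank deficiency 3), `f(z)` a first-order random
walk over 25 m elevation bands, and `eps_i` an unstructured error.  Each
random term has one precision (`tau_s`, `tau_z`, `tau_eps`).  Both
intrinsic structures are *scaled*: the structure matrix is multiplied so
the geometric mean of the constrained generalised-inverse marginal
variances is 1, making Gamma(a, b) precision priors comparable across
effects; (a, b) then fix the upper limit U of the marginal SD at tail
probability 0.001 (`U = qGamma(0.001, a, rate=b)^{-1/2}`).

Observation weights `w_i` enter the likelihood as frequency weights
(powers of the per-cell probability).

### Priors

* `tau_s`, `tau_z`: Gamma(1, 0.00025) by default (U = 0.5); the
  sensitivity sweep covers seven (a, b) pairs with U in {0.1, 0.5, 1, 5}
  and shapes up to 20.
* `tau_eps`: Gamma(0.5, 0.00149).
* `kappa`: Gamma(1, 0.01) on the natural scale — the over-dispersion prior
  is a package choice (only "diffuse" is prescribed by the method);
  its mean 100 keeps near-Poisson cases reachable.
* Fixed effects: Normal(0, 1000); the intercept is treated like the other
  fixed effects but excluded from reported covariate tables.
* `pi`: Beta(1, 1), conjugate to the zero/positive split, so the posterior
  mean is `(n0 + 1)/(n + 2)`.

### Inference

The hurdle factorises: `pi` is estimated from the zero indicator alone;
the positive part is a latent Gaussian model fitted by a nested Laplace
strategy.  For a hyperparameter configuration `theta = (log tau_s,
log tau_z, log tau_eps, log kappa)` the latent field (beta, f_s, f_z, eps
on positive cells) is replaced by its Gaussian approximation at the
conditional mode, found by damped Newton iterations with the exact
gradient and (clipped) curvature of the zero-truncated NB log-likelihood;
sparse LU factorisations (MMD ordering) make each iteration linear-ish in
the cell count.  Sum-to-zero and linear-trend constraints are imposed by
conditioning (kriging correction) at every step, never as soft penalties;
the intrinsic structures carry a relative jitter of 1e-6 so the prior
solves exist, and the conditioning determinants correct the Laplace
objective accordingly.

The marginal posterior of `theta` is explored on an adaptive axis grid:
Nelder-Mead locates the mode of the Laplace approximation, axis-wise
curvature gives per-dimension SDs, and the grid then walks outwards along
each axis in 1-SD steps until the log-density has dropped by 4 (at most 6
steps per direction) — precision posteriors are skewed, with flat
high-precision tails a symmetric grid would truncate.  Fixed-effect
marginals are
mixtures of the conditional Gaussians over those grid points, weighted by
the approximated posterior density; interval quantiles are solved from the
mixture CDF.  `int_strategy="eb"` uses the mode only (cheaper, slightly
narrower intervals) and is used for sweeps and subset fits.
Hyperparameter summaries are log-normal transforms of the Gaussian
approximation on the `theta` scale.  A full random-walk Metropolis sampler
of the same posterior exists only as a test oracle (`tests/_mcmc.py`);
on a 15-cell instance the two routes agree to within ~2 Monte-Carlo
standard errors in the posterior means and ~10 % in the SDs.

Reported "fitted mu_i" is the exponential of the mixture-mean linear
predictor without the cell-level `eps` (the smooth intensity surface).

### Numerical choices and degenerate inputs

* Latent Newton: convergence at 1e-6 relative step, cap 50 iterations,
  step halving on objective decrease; curvature floored at 1e-8 per unit
  weight so the system stays positive definite.
* `theta` search box |log| <= 16; failed inner solves during exploration
  are treated as -inf density, but the fit errors out if the mode itself
  cannot be evaluated.
* No positive counts -> error (the hurdle's positive part is undefined);
  a single elevation band disables the RW1 term.
* Precision scaling uses a dense constrained generalised inverse, adequate
  to a few thousand cells (the intended lattice sizes).

## Gridding and weights

Cells are half-open intervals `[x0+j*c, x0+(j+1)*c)` indexed row-major
from the south-west origin, so every fix maps to exactly one cell
(boundary fixes to the higher index); in-shed fixes are discarded before
counting.  With `g_t` the number of loggers delivering at time t, the raw
weight of cell i is `w_i = gbar / gbar_i` (overall mean over the activity
dataset divided by the cell's mean).  The raw definition does not make the
weighted counts sum to the retained total, so the weights are renormalised
by the constant that restores `sum_i y_i w_i = Y` exactly — a deliberate
deviation that makes the intensity normalisation conserve animal-time to
machine precision.  Raw weights remain available (`w_raw_*`).  Weights are
computed per activity dataset and recomputed per data subset.

Intensities are `R_i = N * n_i * P / A_i` with `n_i = (y_i/Y) * w_i`, herd
size N in livestock units, grazing period P in years (days/365), and cell
area `A_i` = 0.0625 ha, giving LU ha^-1 yr^-1; `sum_i R_i A_i = N * P`
holds exactly under the renormalised weights.

## Covariates

Slope is Horn's 3x3 finite difference in percent (edges by linear
extrapolation, i.e. one-sided differences).  Insolation is a documented
clear-sky direct-beam model: per hourly step with the sun above the
horizon, `S0 * T^(1/cos z) * max(0, cos(incidence))` summed over the
season, with S0 = 1.361 kW/m2 and transmittance T = 0.7; no cast shadows
or diffuse component.  It is a transparent stand-in for GIS potential-
radiation tools and enters the model only after standardisation, so its
absolute level is immaterial.  Vegetation types are reclassified to three
forage classes (nutrient-poor, nutrient-rich, sparse = forest/shrub/rock/
sedge); when nutrient-poor falls below a rarity threshold it is merged
into nutrient-rich (and the baseline moves accordingly).  Distances from
cell centres to the shed and the nearest water point are log-transformed
with a half-cell offset, `log(d + c/2)`.  Stocking rate per paddock is
`sum LU * (days/365) / area_ha`.  Continuous covariates are standardised
over active cells; forage dummies stay 0/1 against the nutrient-poor
baseline; elevation is not a linear fixed effect — it acts only through
the RW1 term.

## Behaviour classification

Walking separates from the other states at single-fix speed, but grazing
(slow, continuous movement) and resting (GPS noise around a point) only
separate at longer horizons.  The default metric set (26 columns,
configurable) therefore has speeds at lags {1,2,3,6,9,15} x 20 s, step
lengths, rolling speed mean/SD over 1/3/5-minute windows, turning-angle
cosine and magnitude, rolling mean turn cosine, straightness and net
displacement per window — all within one animal's contiguous sequence,
split at gaps > 60 s.  Training rows are balanced by random
under-sampling to the minority class; the random forest (200 trees,
seeded) is validated on *sequences held out wholesale*, because row-level
splits would leak temporally adjacent near-duplicates.  At prediction
time, incomplete edge rows inherit the nearest-in-time prediction and a
3-minute rolling majority vote removes single-fix flips (behaviour bouts
last minutes).  Accuracy is reported per class (recall) and as the macro
average.

## The synthetic-data generators

The landscape generator produces a smooth DEM (Gaussian-filtered noise
plus a gentle tilt, scaled into the subalpine 1,300–2,300 m range),
spatially autocorrelated forage classes by quantile-thresholding a smooth
field (realised shares within ±0.1 of targets), a 22-entry *synthetic*
vegetation-type catalogue with its 3-class lookup, shed/water points and a
Voronoi paddock partition; rotations occupy paddocks sequentially.  The
track simulator runs a three-state Markov chain per animal (20 s steps;
default dwell times of minutes to tens of minutes; stationary shares
roughly 42/53/5 % rest/graze/walk), with log-normal speeds around
0.005/0.15/1.0 m/s, von Mises heading persistence, destination cells
weighted by `exp(preference)` of cell covariates (so long-run occupancy is
log-linear in the covariates, the regression's estimand), confinement to
the open paddock, and isotropic Gaussian GPS noise (sigma 3 m, typical
collar accuracy).  Device failures are two-state Markov processes per
device, giving realistic contiguous gaps; `g_t` is recomputed as devices
delivering per timestamp.  Animals are independent (no herd cohesion) and
there is no forage-depletion feedback — passing tests on these data show
the *pipeline* is correct and calibrated, not that real herds behave this
way.

`simulate_cell_counts` bypasses the behavioural layer and draws counts
directly from the hurdle model with known parameters (constrained GMRF
field draws by dense Cholesky plus kriging correction), which is what
recovery and coverage experiments require.

## Validation studies (desk scale)

* **Point recovery**: one 55x55-cell area (3,025 cells), truth
  beta = (1, -0.4, 0.1, -0.2, -0.1, 0.3, 0.5, -0.8), kappa 3, pi 0.3,
  tau_eps 30 and weak latent fields (tau_s = tau_z = 100, marginal SD
  0.1 — the recovery estimand is the fixed effects, so the study keeps
  them the dominant signal); every fixed effect lands within 3 posterior
  SDs of truth.
* **Coverage**: 50 replicates of a 17x18-cell area under the same truth;
  95 % intervals cover the truth for 85–100 % of (replicate x effect)
  checks (measured ~95 %).
* **Confounding**: with a smooth trend-free nuisance surface (the
  non-linear component of the distance field) and a true log-distance
  coefficient of 0, the non-spatial fit is significantly biased while the
  spatial fit's interval covers 0 — the qualitative open-vs-closed-symbol
  contrast of spatial-vs-non-spatial estimation.
* **Classification**: five animals, 24 h, default regimes and dropouts;
  sequence-held-out macro accuracy is ~90 % (chance 33 %), with long-lag
  and windowed displacement metrics leading the importances.

Problem sizes were fixed as the package's study conditions; tolerances
(3 SD, the 85–100 % band, the >80 % accuracy bar) are part of those
conditions and are not tuned per run.

## Known limitations

* The Laplace marginals are Gaussian mixtures without skewness
  correction; strongly skewed fixed-effect posteriors (tiny positive
  counts) would be summarised slightly too symmetrically.
* With a *strong* spatial field (marginal SD ≳ 0.3) over few hundred
  cells and smooth covariates, fixed-effect posteriors are 20–40 % too
  narrow (spatial-confounding attenuation plus approximation error);
  replicate checks showed nominal calibration for weak fields and
  recovery of calibration as counts grow.  Interval statements about
  strongly confounded covariates at small n deserve extra caution.
* `tau_eps` and `kappa` both absorb over-dispersion and are weakly
  separately identified; their individual posteriors can be diffuse even
  when `beta` is well recovered.
* The insolation model omits terrain shading and diffuse radiation.
* Dense operations in precision scaling and field sampling cap practical
  lattices at a few thousand active cells.
* The CLI pipeline ingests synthetic areas end-to-end; external data
  enter through the same CSV/ASCII-grid/GeoJSON readers, but no projection
  handling is provided (projected metre coordinates are assumed).
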