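# alpgraze

Fine-scale spatial analysis of livestock activity on heterogeneous
pastures, for movement ecologists and grassland scientists working with
GPS-collared herds.  The package covers the full chain from raw 20-s GPS
fixes to per-covariate effect estimates:

1. **Behaviour classification** — multi-lag movement metrics and a
   balanced random forest separate grazing, resting and walking
   (sequence-held-out validation, per-class and macro accuracy).
2. **Gridding** — classified fixes are counted per activity on a 25 m
   lattice (one cell = 0.0625 ha); logger dropouts are corrected by cell
   weights `w_i = ḡ/ḡ_i`, renormalised so `Σ y_i w_i = Y`; counts are
   normalised to intensities `R_i = N·n_i·P/A_i` in LU ha⁻¹ yr⁻¹.
3. **Covariates** — elevation, Horn slope (%), clear-sky insolation,
   3-class forage quality, log distances to shed and water, and paddock
   stocking rate, centred and standardised.
4. **Spatial hurdle regression** — per activity,

       Pr(y_i) = π·1[y_i=0] + (1−π)·NB(μ_i, κ | y>0)
       log(μ_i) = βX + f(s_i) + f(z_i) + ε_i

   with a planar second-order random-walk field `f(s)` (intrinsic GMRF,
   13-point stencil), an RW1 elevation effect `f(z)`, an unstructured
   error `ε`, scaled precision structures with Gamma priors, and
   nested-Laplace Bayesian inference (Gaussian approximation at the
   latent mode, adaptive grid over the hyperparameters, mixture
   marginals with 95 % credibility intervals).
5. **Workflows** — prior-sensitivity sweeps, spatial vs non-spatial
   comparison, subset regressions (individuals / 4-h daytime bins / 14-d
   season bins with 10 % / 5 % minimum-share rules), activity budgets,
   and Spearman correlations of effects with area characteristics.

A first-class synthetic-data module (landscapes, paddock rotations,
behaviour-switching tracks with GPS noise and device dropouts, and direct
model-simulated cell counts) makes every stage testable without any field
data.  See `docs/methods.md` for the model, priors, numerics and
limitations.

## Worked example

Fit the hurdle model to counts simulated from the model itself on a small
lattice and compare the estimates with the truth:

```python
import numpy as np
from alpgraze.studies import study_design, TRUTH_HYPERS
from alpgraze.sim.counts import simulate_cell_counts
from alpgraze.fit import fit_positive_part

d = study_design(nrows=24, ncols=24, seed=11)   # synthetic area + covariates
sim = simulate_cell_counts(
    d["cov"].X, d["beta"], kappa=3.0, pi=0.3, tau_eps=30.0,
    spatial=d["spatial"], tau_s=10.0,
    elev_struct=d["elev_struct"], elev_bin_idx=d["elev_idx"], tau_z=30.0, seed=2)
summ = fit_positive_part(
    sim.y, np.ones(len(sim.y)), d["cov"].X, d["cov"].names, d["spec"],
    spatial=d["spatial"], elev_struct=d["elev_struct"], elev_bin_idx=d["elev_idx"])
print(f"pi_hat = {summ.pi_mean:.3f}  kappa_hat = {summ.hypers.loc['kappa','mean']:.2f}")
print(summ.effects.round(3)[["mean", "q025", "q975", "significant"]])
```

prints

```
pi_hat = 0.327  kappa_hat = 2.26
                 mean   q025   q975 significant
effect
slope          -0.310 -0.714  0.102        none
insolation      0.127 -0.342  0.609        none
log_dist_shed  -0.289 -0.472 -0.105    negative
log_dist_water -0.014 -0.246  0.216        none
stocking_rate   0.263  0.092  0.437    positive
nutrient-rich   0.391  0.072  0.715    positive
sparse         -0.667 -1.247 -0.085    negative
```

The true coefficients were (−0.4, 0.1, −0.2, −0.1, 0.3, 0.5, −0.8) with
π = 0.3 and κ = 3: every 95 % interval covers its target (at 576 cells
the weaker effects are, correctly, not yet flagged), and the significant
flags read as a field analysis would report them — less activity on
sparse forage, more on nutrient-rich vegetation and under higher stocking
pressure.

## The demo analysis

`analysis/` holds the numbered drivers of the full pipeline on one
synthetic study area (48×48 cells, 4 paddocks, 3 collared animals, device
dropouts): `01_simulate_area.py`, `02_classify_activity.py`,
`03_grid_and_covariates.py`, `04_fit_models.py`,
`05_sensitivity_and_subsets.py`, `06_area_correlations.py` (six areas).
Run them in order from the repository root; tables and rasters appear
under `results/`.  The same pipeline is scriptable via the CLI:

```sh
alpgraze --config examples/demo.ini run-all
```

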