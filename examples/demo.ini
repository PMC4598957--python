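# Demo pipeline configuration: one small synthetic study area.
[paths]
out_dir = results/demo

[grid]
cell_size = 25

[simulation]
enabled = true
nrows = 48
ncols = 48
relief = 400
class_shares = 0.35, 0.45, 0.20
n_water = 3
n_paddocks = 4
latitude = 46.8
herd_lu = 50
period_days = 7.5
n_animals = 3
track_hours = 72
gps_sigma = 3
fail_rate_per_h = 0.1
recover_rate_per_h = 2

[classifier]
train_fraction = 0.5
n_estimators = 200

[model]
int_strategy = grid
prior_a = 1
prior_b = 0.00025

[seeds]
seed = 1
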