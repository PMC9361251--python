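asymptote_mg_ha: 110.0
base_elev_m: 2150.0
canopy_fuel_per_cover: 16.0
canopy_noise_sigma: 0.3
cell_m: 20.0
consumption_intercept: 2.0
consumption_noise_sd: 16.0
consumption_slope: 0.08
elev_gradient:
- 0.3
- 0.0
elev_slope_mg_ha_per_m: 0.13
extent_m:
- 600.0
- 600.0
fuel_noise_sigma: 0.25
high_severity_dnbr: 440.0
initial_load_mg_ha: 15.0
litter_fraction_of_ld: 0.45
max_tree_height_m: 30.0
n_fires: 6
n_plots: 120
plot_area_ha: 0.03
pulse_density: 2.0
rate_per_yr: 0.25
record_window:
- 1984
- 2019
ref_elev_m: 2300.0
relief_m: 40.0
seed: 0
severity_mean: 150.0
severity_sd: 120.0
transects_per_plot: 2
woody_fraction: 0.55
woody_split:
- 0.08
- 0.2
- 0.22
- 0.5
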