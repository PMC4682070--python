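# Full-pipeline configuration for `morphomodes run-all --config examples/run_config.toml`
out_dir = "scratch/run_from_config"
seed = 7
simulate = true
n_samples = 2
n_cells = 50
k_templates = 3
image_size = 900
snr = 20.0
shape_noise = 0.05
irregularity = 0.3
contact_fraction = 0.2
n_colonies = 3
colony_size_cv = 0.10
n_points = 50
variance_threshold = 0.95
k_min = 2
k_max = 6
g1_hi = 1.25
g2_lo = 1.75
contact_gap = 1
linkage_distance = 80.0
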