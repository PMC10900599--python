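# Base case: low rate dispersion, 500 patients, 80 centers, 5 regions
n: 500
N: 80
G: 5
T_days: 365
activation_window: [0, 122]
alpha: 120.0
beta: 5800.0
n_reps: 10000
seed: 42
redraw_rates_per_replicate: true
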