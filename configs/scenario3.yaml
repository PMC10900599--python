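# Doubled number of centers, rates as scenario2
n: 500
N: 160
G: 5
T_days: 365
activation_window: [0, 122]
alpha: 1.2
beta: 58.0
n_reps: 10000
seed: 42
redraw_rates_per_replicate: true
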