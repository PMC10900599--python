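# Rates as scenario2, all MTI thresholds doubled
n: 500
N: 80
G: 5
T_days: 365
activation_window: [0, 122]
alpha: 1.2
beta: 58.0
n_reps: 10000
seed: 42
redraw_rates_per_replicate: true
designs:
  - U-PBD(4)
  - U-BUD(4)
  - U-EUD(4)
  - U-BSD(4)
  - R-PBD(4)
  - R-BUD(4)
  - R-EUD(4)
  - R-BSD(4)
  - C-PBD(4)
  - C-BUD(4)
  - C-EUD(4)
  - C-BSD(4)
  - DBR(4,4,4)
  - DBR(4,8,8)
  - DBR(4,8,16)
  - CRD
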