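{
  "comment": "Default fixture parameter set for testing: physiologically plausible hERG-like kinetics (slow activation/deactivation, fast inactivation/recovery). Replace with cell-specific values when fitting real recordings.",
  "params": {
    "p1": 0.000226,
    "p2": 0.0699,
    "p3": 3.45e-05,
    "p4": 0.05462,
    "p5": 0.0873,
    "p6": 0.00891,
    "p7": 0.00515,
    "p8": 0.03158,
    "p9": 0.1524
  },
  "conditions": {
    "K_out": 4.0,
    "K_in": 130.0,
    "T": 294.65
  },
  "noise_fraction": 0.01
}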