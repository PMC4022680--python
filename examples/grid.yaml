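# Full study design: 9 ratio rows x 10 transfer levels x both group sizes.
# Reduce reps for a quick look; 1000 reproduces the original sampling effort.
grid:
  n: [10, 20]
  transfer: [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
  lambda_pairs:
    - [0.001, 0.45]   # ratio 9
    - [0.002, 0.40]   # ratio 4
    - [0.003, 0.35]   # ratio 2.33
    - [0.004, 0.30]   # ratio 1.5
    - [0.005, 0.25]   # ratio 1
    - [0.006, 0.20]   # ratio 0.67
    - [0.007, 0.15]   # ratio 0.43
    - [0.008, 0.10]   # ratio 0.25
    - [0.009, 0.05]   # ratio 0.11
reps: 100
base_seed: 20140515
max_days: 900
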