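# Example generator configuration for `milkbot simulate --config ...`
# Any omitted key keeps its default (21 herds x 2 parity groups x 50
# lactations, monthly tests, population parameters per parity).

n_herds = 6
n_per_group = 50
parities = ["P1", "P2plus"]
first_test_dim = [5.0, 35.0]
test_interval = 30.0
interval_jitter = 3.0
max_dim = 305.0
min_tests = 7

# between-herd SD as a multiple of the within-group SD, per parameter
[herd_sd_multiplier]
scale = 0.5
ramp = 0.5
offset = 0.0
decay = 0.5

# population parameter distributions: mean = [scale, ramp, offset, decay]
[population.P1]
mean = [38.66, 31.43, -0.5, 0.000974]
sd = [5.87, 2.67, 0.0, 0.000605]
noise_sd = 3.7

[population.P2plus]
mean = [53.65, 26.13, -0.37, 0.002213]
sd = [9.3, 7.66, 0.39, 0.000858]
noise_sd = 4.65

# optional experiment hooks: shift one herd's P1 scale mean by +5 kg/day
[herd_shifts]
"H01:P1:scale" = 5.0
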