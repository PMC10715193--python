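# Synthetic demo: three categories with distinct exponents, one with a
# breakpoint, two phyla, and a shuffle null.  Run with:
#   cogscale run --config examples/demo.toml --out demo_out
seed = 7
n_perm = 2
binned = true
outdir = "demo_out"

[simulate]
n_organisms = 150
total_min = 100
total_max = 10000
filler_category = "S"

[simulate.laws.J]
exponent = 0.3
log10_norm = 1.0
noise_sd = 0.05

[simulate.laws.E]
exponent = 1.0
log10_norm = -1.5
noise_sd = 0.05

[simulate.laws.T]
kind = "breakpoint"
exponent_small = 1.6
log10_norm = -3.0
noise_sd = 0.08
slope_large = 0.8
break_x = 1584.9  # 10^3.2

[[simulate.phyla]]
name = "Alpha"
fraction = 0.5

[[simulate.phyla]]
name = "Beta"
fraction = 0.5
[simulate.phyla.exponent_offsets]
E = 0.2
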