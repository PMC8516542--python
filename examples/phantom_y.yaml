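# Noisy dark-vessel Y-tree phantom (preset with overrides).
preset: y
background: 200.0
noise_sigma: 15.0
illumination_gradient: [0.08, 0.04]
polarity: dark
rng_seed: 7
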