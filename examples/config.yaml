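# Example pipeline configuration (flat key-value; all keys optional).
vessel_polarity: dark
rng_seed: 0
denoise_noise_sigma: 15.0
vesselness_beta: 0.5
vesselness_c: 20.0
track_d: 5.0
track_delta_theta: 45.0
track_I0: 10.0
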