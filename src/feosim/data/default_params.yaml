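# Default model parameters.
coupling: 0.001        # K: FEO intercoupling strength
food_gain: 0.6433      # K_F: food input strength
n: 1000                # number of FEOs
period_mean: 24.0      # hours
period_sd: 1.0         # hours
indication_width: 0.2  # radians (~45 min at a 24 h period)
sigmoid_rate: 40.0     # k1
sigmoid_location: 5.0  # k2
fourier_coeffs: [0.2142, 0.3295, 0.3177, 0.2259, 0.1236, 0.0523, 0.0170, 0.0041]
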