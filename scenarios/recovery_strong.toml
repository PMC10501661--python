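# Sampling-fraction recovery under strong differential abundance:
# compare size-factor RMSE of every normalizer against the planted truth.
replicates = 10
d = 200
n = 100
prop_da = 0.1
signal = 4.0
latent = "binary"
seed = 1
methods = ["rsim", "oracle", "tss", "uq", "med", "tmm", "gmpr"]
analyses = ["size_factors"]
eta = 0.05
gamma = 0.8
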