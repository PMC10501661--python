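# Differential abundance analysis: realized FDP and sensitivity of the
# Welch t-test at alpha = 0.05 after each normalization.
replicates = 10
d = 200
n = 100
prop_da = 0.1
signal = 4.0
latent = "binary"
seed = 21
methods = ["rsim", "oracle", "tss", "gmpr"]
analyses = ["ttest", "size_factors"]
alpha = 0.05
eta = 0.05
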