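# Null two-group design with group 1 rarefied to 20% of its depth:
# any PERMANOVA rejection is a false positive driven by sequencing depth.
replicates = 25
d = 200
n = 60
prop_da = 0.0
latent = "binary"
rarefy_group1 = 0.2
seed = 11
methods = ["rsim", "tss"]
analyses = ["permanova"]
permutations = 99
alpha = 0.05
eta = 0.05
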