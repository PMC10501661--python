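"""Effect of normalization on per-taxon differential abundance testing.

Runs a Welch t-test per taxon (on log-transformed normalized values)
against the binary group label and scores the rejections against the
planted truth: realized false-discovery proportion (FDP) and
sensitivity.
"""

from rsim import (
    CovariateTable,
    SimulationConfig,
    baseline_normalize,
    fdp_and_sensitivity,
    filter_taxa,
    generate,
    per_taxon_tests,
    reference_normalize,
    rsim_normalize,
)

cm, truth = generate(SimulationConfig(d=200, n=100, prop_da=0.1, signal=4.0, seed=4))
cm = filter_taxa(cm)
covariates = CovariateTable(cm.sample_ids, truth.latent_values)

nm_rsim, _ = rsim_normalize(cm, eta=0.05, seed=4)
pipelines = {
    "rsim": nm_rsim,
    "tss": baseline_normalize(cm, "tss"),
    "oracle": reference_normalize(cm, truth.nonda_taxa & set(cm.taxon_ids)),
}

for name, nm in pipelines.items():
    result = per_taxon_tests(nm, covariates, test="t_test", alpha=0.05)
    fdp, sens = fdp_and_sensitivity(result.rejections, truth)
    fdp_bh, sens_bh = fdp_and_sensitivity(result.rejections_bh, truth)
    print(f"{name:>6}: raw-threshold FDP = {fdp:.3f}, sensitivity = {sens:.3f}; "
          f"BH-adjusted FDP = {fdp_bh:.3f}, sensitivity = {sens_bh:.3f}")
# "oracle" normalizes by the true non-DA taxa and marks the best a scaling
# method can do.  Reference-based normalization tracks it closely, while
# depth-based scaling shifts every taxon in the signal-carrying group and
# roughly doubles the false-discovery proportion at the same sensitivity.
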