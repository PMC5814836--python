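"""Simulate a 15N-RNA-SIP experiment and call the labelled OTUs.

Builds a 300-OTU community in which one OTU (0.5% of the community) is fully
15N-labelled — its RNA bands 0.015 g/ml denser than the rest — plus an
unlabelled control gradient, then runs the full caller: sparse-OTU
filtering, per-gradient negative-binomial modelling with a one-sided Wald
test (BH-corrected, FDR 0.1, log2FC > 0.25), abundance floor and hump-shape
confirmation.
"""

from diazosip.pipeline import RunConfig, generate_report, run_sip_pipeline
from diazosip.synthetic import GradientSimParams, simulate_gradient_experiment

params = GradientSimParams(
    n_otus=300,
    labelled_otu_ids=frozenset({"OTU_0001"}),
    fixed_abundances={"OTU_0001": 0.005},
    seed=11,
)
tables, truth, qpcr = simulate_gradient_experiment(params)
print(f"simulated gradients: {[t.gradient_id for t in tables]}")
print(f"ground truth labelled OTUs: {sorted(truth)}\n")

bundle = run_sip_pipeline(tables, RunConfig(seed=11))
text, report = generate_report(bundle)
print(text)

res = bundle["per_gradient"][tables[0].gradient_id]
row = res.loc["OTU_0001"]
print("the labelled OTU in the 15N gradient:")
print(f"  log2 fold change (heavy/light) = {row['log2_fold_change']:.2f}")
print(f"  BH-adjusted one-sided Wald p   = {row['padj']:.2e}")
print(f"  mean normalized count          = {row['base_mean']:.1f}")
print(f"  density-profile peak           = {row['peak_density']:.3f} g/ml (heavy window)")
print("\nA confirmed call needs all three: model enrichment, abundance >= 1.25,")
print("and a hump-shaped profile peaking where labelled template concentrates.")
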