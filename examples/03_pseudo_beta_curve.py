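"""Pseudo-beta-diversity: apparent turnover between replicates of ONE sample.

Dissimilarity between technical replicates of the same sample is purely
technical noise.  Tracing it across rarefaction depths shows how much
apparent beta-diversity is manufactured by shallow sequencing — and how the
abundance-weighted and presence-based metrics behave differently.
"""

import ampliconrep as ar

config = ar.SimulationConfig(seed=3)
table = ar.simulate_experiment(config, "replication")

depths = [100, 1000, 10_000, 40_000, 60_000]
for metric in ("bray_curtis", "jaccard"):
    curve = ar.pseudo_beta_curve(
        table, "OR1", metric, depths, n_draws=10, seed=3, platform="illumina"
    )
    print(f"\n{metric} pseudo-beta-diversity (replicates of OR1, deep platform):")
    for depth, mean, sd, n_pairs in curve.points:
        print(f"  depth {depth:>6}: {mean:.4f} +/- {sd:.4f}  ({n_pairs} pairs)")

# Reading the output: Bray-Curtis decays toward ~0.02 as depth grows —
# replicates converge once sampling noise shrinks.  Binary Jaccard plateaus
# well above zero: rare (and spurious, sequencing-error) OTUs keep flickering
# in and out of the presence sets no matter how deep you sequence, so
# presence-based metrics overstate dissimilarity between deep libraries.
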