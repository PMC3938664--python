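"""Do two sequencing platforms tell the same ecological story?

Simulates 60 soil samples from three bioregions, sequences each on a shallow
and a deep platform, and compares the platforms' beta-diversity structure via
Mantel correlation, perMANOVA, and the shared/unique OTU partition.
"""

import ampliconrep as ar
from ampliconrep._seeds import derive_seed
from ampliconrep.beta import distance_matrix
from ampliconrep.studies import combined_distance_matrix, platform_tables

config = ar.SimulationConfig(seed=5)
table = ar.simulate_experiment(config, "cross_platform")
depths = {"454": 1000, "illumina": 40000}
per_platform = platform_tables(table)

print("Mantel correlation of between-sample distances across platforms:")
for metric in ("jaccard", "bray_curtis", "beta_sim"):
    dms = {
        p: distance_matrix(sub, metric, depths[p], derive_seed(5, "dm", p, metric))
        for p, sub in per_platform.items()
    }
    res = ar.mantel(dms["454"], dms["illumina"], 999, seed=5)
    print(f"  {metric:<12} r = {res.statistic:.3f}  p = {res.p_value:.3f}")

dm = combined_distance_matrix(table, depths, "bray_curtis", seed=5)
for factor in ("group", "platform"):
    labels = [getattr(table.metadata[s], factor) for s in dm.sample_ids]
    res = ar.permanova(dm, labels, 999, seed=5)
    print(
        f"perMANOVA (bray_curtis) {factor:<9}: F = {res.statistic:.1f}  "
        f"r2 = {res.r_squared:.3f}  p = {res.p_value:.3f}"
    )

ov = ar.platform_overlap(table)
print(
    f"OTU overlap: {ov.shared} shared, {ov.unique_a} unique to {ov.platform_a}, "
    f"{ov.unique_b} unique to {ov.platform_b}"
)

# Reading the output: distance structure is nearly interchangeable across
# platforms (Mantel r ~ 0.9+); bioregion explains an order of magnitude more
# variance than platform; the deep platform recovers nearly every OTU the
# shallow one sees plus a large rare tail of its own.
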