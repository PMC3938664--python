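"""Simulate the pooled-PCR replication design and estimate alpha diversity.

Three soil communities are each sequenced as pools of 1/2/4/8/16 PCR
reactions on a shallow and a deep platform; every library is rarefied to a
platform-specific depth and the standard diversity metrics computed.
"""

import ampliconrep as ar
from ampliconrep.studies import alpha_by_platform

config = ar.SimulationConfig(seed=1)
table = ar.simulate_experiment(config, "replication")
print(f"simulated {table.n_samples} libraries x {table.n_otus} OTUs")

alpha = alpha_by_platform(table, {"454": 500, "illumina": 38000}, n_rarefactions=10, seed=1)
wide = alpha.pivot_table(index=["source_id", "platform", "pool_size"], columns="metric", values="value")
print(wide.round(3).to_string())

# Reading the output: observed richness ~30-60 at 500 reads and ~200-450 at
# 38,000 reads, varying by source community but NOT by pool size — pooling
# more PCR reactions does not change the diversity a library recovers.
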