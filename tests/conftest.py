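import numpy as np
import pytest

from ampliconrep.io import CountTable, SampleMeta


def make_table(counts, otu_ids=None, sample_ids=None, meta=None) -> CountTable:
    """Build a CountTable from a nested list; optional metadata tuples
    (source_id, pool_size, platform, group[, replicate_index])."""
    counts = np.asarray(counts)
    n_samples, n_otus = counts.shape
    otu_ids = otu_ids or [f"OTU{j + 1}" for j in range(n_otus)]
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(n_samples)]
    metadata = {}
    if meta:
        for sid, entry in zip(sample_ids, meta):
            src, pool, platform, group, *rest = entry
            metadata[sid] = SampleMeta(
                sample_id=sid,
                source_id=src,
                pool_size=pool,
                platform=platform,
                group=group,
                replicate_index=rest[0] if rest else 0,
            )
    return CountTable(otu_ids, sample_ids, counts, metadata)


@pytest.fixture
def toy_table():
    """3 samples x 4 OTUs with metadata: two replicates of one source plus a
    second source in the same group."""
    return make_table(
        [[5, 3, 0, 2], [4, 4, 1, 1], [0, 2, 6, 2]],
        meta=[
            ("srcA", 1, "454", "plot1"),
            ("srcA", 16, "454", "plot1", 1),
            ("srcB", 1, "454", "plot1"),
        ],
    )
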