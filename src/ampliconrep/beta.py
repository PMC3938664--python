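"""Pairwise community dissimilarity: Bray-Curtis, binary Jaccard, beta-sim.

Bray-Curtis is abundance-weighted; Jaccard and beta-sim are presence-based.
beta-sim (Lennon/Koleff turnover form ``min(b,c) / (min(b,c) + a)``) discounts
pure richness differences: a community nested inside a richer one scores 0.
All three are bounded in [0, 1], symmetric, and zero on identical inputs.

:func:`distance_matrix` rarefies every sample once (a single draw per sample,
so the matrix is internally consistent) and computes all pairwise values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import derive_rng
from .diversity import rarefy
from .io import CountTable

__all__ = [
    "bray_curtis",
    "jaccard_binary",
    "beta_sim",
    "distance_matrix",
    "mean_dissimilarity_to_plot",
    "DistanceMatrix",
    "BETA_METRICS",
]


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("count vectors must be 1-D and of equal length")
    if np.min(x) < 0 or np.min(y) < 0:
        raise ValueError("counts must be non-negative")
    return x, y


def bray_curtis(x, y) -> float:
    """``sum|x_i - y_i| / sum(x_i + y_i)``; errors if both vectors are empty."""
    x, y = _pair(x, y)
    denom = np.sum(x + y)
    if denom == 0:
        raise ValueError("bray_curtis undefined when both vectors are all-zero")
    return float(np.sum(np.abs(x - y)) / denom)


def jaccard_binary(x, y) -> float:
    """``1 - |A ∩ B| / |A ∪ B|`` on presence sets."""
    x, y = _pair(x, y)
    a = x > 0
    b = y > 0
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ValueError("jaccard undefined when both vectors are all-zero")
    inter = np.count_nonzero(a & b)
    return float(1.0 - inter / union)


def beta_sim(x, y) -> float:
    """Presence-based turnover ``min(b, c) / (min(b, c) + a)`` where ``a`` is
    the shared-taxon count and ``b``, ``c`` the counts unique to each sample."""
    x, y = _pair(x, y)
    pa = x > 0
    pb = y > 0
    if not pa.any() or not pb.any():
        raise ValueError("beta_sim requires at least one present taxon per sample")
    a = int(np.count_nonzero(pa & pb))
    b = int(np.count_nonzero(pa & ~pb))
    c = int(np.count_nonzero(~pa & pb))
    m = min(b, c)
    if m + a == 0:
        return 0.0
    return float(m / (m + a))


_METRIC_FUNCS = {
    "bray_curtis": bray_curtis,
    "jaccard": jaccard_binary,
    "beta_sim": beta_sim,
}
BETA_METRICS = tuple(_METRIC_FUNCS)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with metric/depth provenance."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str
    depth: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("values must be square and aligned with sample_ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("values must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly zero")
        if v.size and (v.min() < 0 or v.max() > 1 + 1e-12):
            raise ValueError("dissimilarities must lie in [0, 1]")
        self.values = v

    def condensed(self) -> np.ndarray:
        """Upper off-diagonal entries, row-major (scipy 'condensed' order)."""
        iu = np.triu_indices(len(self.sample_ids), k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def _pairwise(matrix: np.ndarray, metric: str) -> np.ndarray:
    """All pairwise dissimilarities, row-vs-rows vectorized; identical
    arithmetic to the scalar functions."""
    n = matrix.shape[0]
    out = np.zeros((n, n))
    x = matrix.astype(float)
    pres = x > 0
    for i in range(n):
        if metric == "bray_curtis":
            num = np.abs(x[i] - x).sum(axis=1)
            den = (x[i] + x).sum(axis=1)
            with np.errstate(invalid="ignore"):
                out[i] = np.where(den > 0, num / den, 0.0)
        elif metric == "jaccard":
            inter = np.count_nonzero(pres[i] & pres, axis=1)
            union = np.count_nonzero(pres[i] | pres, axis=1)
            out[i] = np.where(union > 0, 1.0 - inter / np.maximum(union, 1), 0.0)
        else:  # beta_sim
            a = np.count_nonzero(pres[i] & pres, axis=1)
            b = np.count_nonzero(pres[i] & ~pres, axis=1)
            c = np.count_nonzero(~pres[i] & pres, axis=1)
            m = np.minimum(b, c)
            denom = np.maximum(m + a, 1)
            out[i] = m / denom
    np.fill_diagonal(out, 0.0)
    return out


def distance_matrix(
    table: CountTable,
    metric: str,
    depth: int | None = None,
    seed: int = 0,
) -> DistanceMatrix:
    """Pairwise dissimilarities among all sufficiently deep samples.

    With ``depth`` set, each sample is rarefied once (a single seeded draw per
    sample) before distances are computed; shallower samples are dropped.
    With ``depth=None`` raw counts are used.
    """
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}; choose from {BETA_METRICS}")
    if depth is None:
        keep = list(table.sample_ids)
        matrix = table.counts.astype(float)
    else:
        depth = int(depth)
        keep = [s for s, t in zip(table.sample_ids, table.totals()) if t >= depth]
        if len(keep) < 2:
            raise ValueError(f"fewer than 2 samples have >= {depth} reads")
        matrix = np.stack(
            [
                rarefy(table.sample_counts(s), depth, derive_rng(seed, "dist", s))
                for s in keep
            ]
        ).astype(float)
    values = _pairwise(matrix, metric)
    return DistanceMatrix(keep, values, metric, depth, seed)


def mean_dissimilarity_to_plot(
    table: CountTable,
    focal_sample: str,
    metric: str,
    depth: int | None = None,
    seed: int = 0,
) -> float:
    """Mean dissimilarity from a focal sample to all other samples in its
    group, excluding technical replicates of the same source.

    This is the between-sample beta-diversity summary used to ask whether a
    library's pooling treatment changes how different it looks from the other
    samples at its site.
    """
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}")
    if focal_sample not in table.metadata:
        raise ValueError(f"no metadata for sample {focal_sample!r}")
    focal_meta = table.metadata[focal_sample]
    comparators = [
        s
        for s, m in table.metadata.items()
        if s != focal_sample and m.group == focal_meta.group and m.source_id != focal_meta.source_id
    ]
    if not comparators:
        raise ValueError(f"no comparator samples in group {focal_meta.group!r}")
    func = _METRIC_FUNCS[metric]
    if depth is None:
        x = table.sample_counts(focal_sample)
        vals = [func(x, table.sample_counts(s)) for s in comparators]
    else:
        x = rarefy(table.sample_counts(focal_sample), depth, derive_rng(seed, "dist", focal_sample))
        vals = [
            func(x, rarefy(table.sample_counts(s), depth, derive_rng(seed, "dist", s)))
            for s in comparators
        ]
    return float(np.mean(vals))
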