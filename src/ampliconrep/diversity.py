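"""Alpha-diversity estimators and rarefaction.

Implements the metric set standard in soil-fungal community ecology:
observed richness, Chao1, Fisher's alpha, Simpson diversity (complement form
``1 - sum p_i^2``) and Simpson evenness (inverse Simpson divided by observed
richness).  Rarefaction subsamples reads *without replacement*
(multivariate hypergeometric), so a rarefied vector can never contain more of
a taxon than the original library did.

Simpson conventions vary across software; the forms used here are the ones
consistent with complement-form values near 0.8 on high-diversity soils.
Both are plain functions, so alternatives are easy to swap in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._seeds import derive_rng
from .io import CountTable

__all__ = [
    "rarefy",
    "observed_richness",
    "chao1",
    "fishers_alpha",
    "simpson",
    "simpson_evenness",
    "alpha_table",
    "AlphaTable",
    "ALPHA_METRICS",
]


def _as_counts(counts) -> np.ndarray:
    x = np.asarray(counts)
    if x.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if x.size and np.min(x) < 0:
        raise ValueError("counts must be non-negative")
    return x


def rarefy(counts, depth: int, seed: int | np.random.Generator) -> np.ndarray:
    """Subsample a count vector to exactly ``depth`` reads without replacement.

    Deterministic given ``seed`` (an int or an existing Generator).  Raises if
    ``depth`` exceeds the library total; the caller decides whether to drop
    the sample instead.
    """
    x = _as_counts(counts).astype(np.int64)
    depth = int(depth)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    total = int(x.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds library size {total}")
    if depth == total:
        return x.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(x, depth).astype(np.int64)


def observed_richness(counts) -> int:
    """Number of taxa with at least one read."""
    return int(np.count_nonzero(_as_counts(counts)))


def chao1(counts) -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    ``S_obs + F1^2 / (2 F2)``; when no doubletons exist the bias-corrected
    fallback ``S_obs + F1 (F1 - 1) / 2`` is used, so the estimate is always
    finite and ``chao1 >= observed`` with equality iff F1 in {0, 1}.
    """
    x = _as_counts(counts)
    if not np.any(x > 0):
        raise ValueError("chao1 undefined for an all-zero vector")
    s_obs = observed_richness(x)
    f1 = int(np.count_nonzero(x == 1))
    f2 = int(np.count_nonzero(x == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def fishers_alpha(counts, tol: float = 1e-9) -> float:
    """Fisher's log-series alpha: the unique ``a > 0`` with
    ``S = a * ln(1 + N / a)``.

    ``a -> a ln(1 + N/a)`` increases monotonically from 0 to N, so a bracketed
    root exists and is unique whenever ``S < N`` (strict); ``N <= S`` raises.
    """
    x = _as_counts(counts)
    s = observed_richness(x)
    n = float(x.sum())
    if s < 1:
        raise ValueError("fishers_alpha requires at least one observed taxon")
    if n <= s:
        raise ValueError(f"fishers_alpha undefined for N={n} <= S={s}")

    def f(a: float) -> float:
        return a * np.log1p(n / a) - s

    lo, hi = 1e-12, 1e12
    return float(brentq(f, lo, hi, xtol=tol))


def simpson(counts) -> float:
    """Simpson diversity in complement form, ``1 - sum p_i^2`` (in [0, 1])."""
    x = _as_counts(counts).astype(float)
    n = x.sum()
    if n <= 0:
        raise ValueError("simpson undefined for an all-zero vector")
    p = x / n
    return float(1.0 - np.sum(p * p))


def simpson_evenness(counts) -> float:
    """Simpson evenness ``(1 / sum p_i^2) / S`` (inverse Simpson over
    observed richness); equals 1 for a perfectly even community."""
    x = _as_counts(counts).astype(float)
    n = x.sum()
    if n <= 0:
        raise ValueError("simpson_evenness undefined for an all-zero vector")
    p = x / n
    s = observed_richness(x)
    return float(1.0 / np.sum(p * p) / s)


_METRIC_FUNCS = {
    "observed": observed_richness,
    "chao1": chao1,
    "fishers_alpha": fishers_alpha,
    "simpson": simpson,
    "simpson_evenness": simpson_evenness,
}
ALPHA_METRICS = tuple(_METRIC_FUNCS)


@dataclass
class AlphaTable:
    """Rarefied alpha-diversity results plus the samples excluded for being
    shallower than the requested depth."""

    results: pd.DataFrame  # columns: sample_id, metric, value, depth
    excluded: list[str]
    depth: int
    n_rarefactions: int


def alpha_table(
    table: CountTable,
    depth: int,
    seed: int,
    n_rarefactions: int = 10,
    metrics: tuple[str, ...] = ALPHA_METRICS,
) -> AlphaTable:
    """Alpha diversity for every sufficiently deep sample at a common depth.

    Each metric is computed on ``n_rarefactions`` independent rarefaction
    draws and averaged, which removes most single-draw subsampling noise.
    Samples with fewer than ``depth`` reads are excluded and reported in
    ``AlphaTable.excluded``.
    """
    depth = int(depth)
    unknown = [m for m in metrics if m not in _METRIC_FUNCS]
    if unknown:
        raise ValueError(f"unknown metrics: {unknown}")
    totals = table.totals()
    keep = [s for s, t in zip(table.sample_ids, totals) if t >= depth]
    excluded = [s for s in table.sample_ids if s not in keep]
    if not keep:
        raise ValueError(f"no sample has >= {depth} reads")

    rows = []
    for sid in keep:
        x = table.sample_counts(sid)
        acc = {m: 0.0 for m in metrics}
        for rep in range(n_rarefactions):
            rng = derive_rng(seed, "alpha", sid, rep)
            sub = rarefy(x, depth, rng)
            for m in metrics:
                acc[m] += float(_METRIC_FUNCS[m](sub))
        for m in metrics:
            rows.append(
                {"sample_id": sid, "metric": m, "value": acc[m] / n_rarefactions, "depth": depth}
            )
    return AlphaTable(pd.DataFrame(rows), excluded, depth, n_rarefactions)
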