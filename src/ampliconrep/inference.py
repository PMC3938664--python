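"""Statistical inference: factorial ANOVA, Mantel, perMANOVA, OTU overlap.

The factorial ANOVA uses sequential (Type-I) sums of squares — the default
of R's ``aov``/``anova.lm``, which is what community-ecology workflows built
on R produce — via statsmodels OLS.  The permutation tests are implemented
directly on the distance matrices so that seeding and the ``(1+b)/(1+m)``
p-value estimator (p can never be exactly 0) are fully under our control;
independent implementations in scikit-bio are used as cross-checks in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .beta import DistanceMatrix
from .io import CountTable

__all__ = [
    "AnovaTable",
    "PermutationTestResult",
    "OverlapResult",
    "factorial_anova",
    "mantel",
    "permanova",
    "platform_overlap",
]


# -- factorial ANOVA -------------------------------------------------------


@dataclass
class AnovaTable:
    """Sequential-SS ANOVA decomposition."""

    terms: list[tuple[str, int, float, float, float]]  # (name, df, ss, F, p)
    residual_df: int
    residual_sum_sq: float

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.terms, columns=["term", "df", "sum_sq", "F", "p"])
        df.loc[len(df)] = ["Residual", self.residual_df, self.residual_sum_sq, np.nan, np.nan]
        return df

    def p_value(self, term: str) -> float:
        for name, _, _, _, p in self.terms:
            if name == term:
                return p
        raise KeyError(term)

    def f_stat(self, term: str) -> float:
        for name, _, _, f, _ in self.terms:
            if name == term:
                return f
        raise KeyError(term)


def factorial_anova(data: pd.DataFrame, formula: str) -> AnovaTable:
    """Fit ``formula`` by least squares and decompose with Type-I SS.

    ``data`` holds the response and predictors; term order in the output
    follows the formula as written.  A constant response is legal: all F are
    reported as 0 with p = 1 rather than 0/0.  A design rank-deficient beyond
    what the listed terms can absorb raises, naming the aliased term.
    """
    model = smf.ols(formula, data=data)
    n, rank = model.exog.shape[0], np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        # locate first column that adds no rank
        names = model.exog_names
        bad = None
        for j in range(1, model.exog.shape[1]):
            if np.linalg.matrix_rank(model.exog[:, : j + 1]) == np.linalg.matrix_rank(
                model.exog[:, :j]
            ):
                bad = names[j]
                break
        raise ValueError(f"design matrix is rank deficient (aliased term: {bad})")
    if n <= rank:
        raise ValueError(f"need more observations ({n}) than model df ({rank})")
    fit = model.fit()
    table = sm.stats.anova_lm(fit, typ=1)

    resid_row = table.loc["Residual"]
    residual_df = int(resid_row["df"])
    residual_ss = float(resid_row["sum_sq"])
    terms = []
    degenerate = residual_ss <= max(1e-12 * float(np.sum(np.square(model.endog))), 1e-300)
    for name, row in table.iterrows():
        if name == "Residual":
            continue
        df_t = int(row["df"])
        ss = float(row["sum_sq"])
        if degenerate:
            f_stat, p = 0.0, 1.0
        else:
            f_stat = (ss / df_t) / (residual_ss / residual_df)
            p = float(sps.f.sf(f_stat, df_t, residual_df))
        terms.append((str(name), df_t, ss, float(f_stat), p))
    return AnovaTable(terms, residual_df, residual_ss)


# -- permutation tests -----------------------------------------------------


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    r_squared: float | None = None
    df: tuple[int, int] | None = None


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Mantel matrix correlation with a one-sided (upper) permutation test.

    The statistic is the Pearson correlation of the upper off-diagonal
    entries; rows and columns of ``d2`` are permuted simultaneously and
    ``p = (1 + #{r_perm >= r_obs}) / (1 + m)``.
    """
    if d1.sample_ids != d2.sample_ids:
        raise ValueError("distance matrices must share sample_ids in the same order")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    n = len(d1.sample_ids)
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    observed = float(np.corrcoef(v1, d2.values[iu])[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        v2p = d2.values[np.ix_(perm, perm)][iu]
        if np.corrcoef(v1, v2p)[0, 1] >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermutationTestResult(observed, p, n_permutations, seed)


def _permanova_stats(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """One-way pseudo-F and r^2 from a squared-distance matrix and integer
    group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_between = ss_total - ss_within
    if ss_within == 0.0:
        return np.inf, ss_between / ss_total
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_between / ss_total


def permanova(
    d: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """One-way perMANOVA: permutational partition of squared dissimilarities.

    ``SS_total = sum_{i<j} d_ij^2 / n``; ``SS_within`` sums each group's
    internal pairs over its size; ``F = (SS_between/(a-1)) / (SS_within/(n-a))``
    with ``r^2 = SS_between / SS_total``.  p by label permutation,
    ``(1+b)/(1+m)``.
    """
    groups = np.asarray(groups)
    n = len(d.sample_ids)
    if groups.shape != (n,):
        raise ValueError("groups must align with the distance matrix")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    levels, codes = np.unique(groups, return_inverse=True)
    a = levels.size
    if a < 2:
        raise ValueError("need >= 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        small = levels[sizes < 2]
        raise ValueError(f"every group needs >= 2 members; too small: {list(small)}")
    d2 = d.values**2
    f_obs, r2 = _permanova_stats(d2, codes, a)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        f_perm, _ = _permanova_stats(d2, codes[rng.permutation(n)], a)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermutationTestResult(
        float(f_obs), p, n_permutations, seed, r_squared=float(r2), df=(a - 1, n - a)
    )


# -- platform overlap ------------------------------------------------------


@dataclass
class OverlapResult:
    """Shared / platform-unique OTU partition (a Venn diagram in numbers)."""

    platform_a: str
    platform_b: str
    shared: int
    unique_a: int
    unique_b: int

    @property
    def total(self) -> int:
        return self.shared + self.unique_a + self.unique_b

    def fractions(self) -> dict[str, float]:
        t = self.total
        return {
            "shared": self.shared / t,
            f"unique_{self.platform_a}": self.unique_a / t,
            f"unique_{self.platform_b}": self.unique_b / t,
        }


def platform_overlap(table: CountTable) -> OverlapResult:
    """Classify every observed OTU as shared between the two platforms or
    unique to one; requires metadata with exactly two platform levels."""
    if not table.metadata:
        raise ValueError("platform_overlap requires sample metadata")
    platforms = sorted({m.platform for m in table.metadata.values()})
    if len(platforms) != 2:
        raise ValueError(f"need exactly 2 platforms, found {platforms}")
    pa, pb = platforms
    rows_a = [i for i, s in enumerate(table.sample_ids) if table.metadata[s].platform == pa]
    rows_b = [i for i, s in enumerate(table.sample_ids) if table.metadata[s].platform == pb]
    in_a = table.counts[rows_a].any(axis=0)
    in_b = table.counts[rows_b].any(axis=0)
    return OverlapResult(
        platform_a=pa,
        platform_b=pb,
        shared=int(np.count_nonzero(in_a & in_b)),
        unique_a=int(np.count_nonzero(in_a & ~in_b)),
        unique_b=int(np.count_nonzero(~in_a & in_b)),
    )
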