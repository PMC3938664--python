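"""Technical-replicate reproducibility analyses.

Three procedures quantify how well repeated sequencing of the *same*
biological sample agrees with itself:

* :func:`pseudo_beta_curve` — "pseudo-beta-diversity": the dissimilarity
  between technical replicates of one sample, traced across rarefaction
  depths.  Apparent turnover between replicates is purely technical, so its
  depth profile shows how much of an observed beta-diversity signal could be
  sampling noise.
* :func:`detection_frequency` / :func:`fit_detection_model` — per-OTU
  detection consistency: how reliably an OTU reappears across replicates as a
  function of its mean read abundance, summarized by a binomial logistic
  regression on log10 abundance.
* :func:`abundance_concordance` — log-scale agreement of per-OTU read counts
  between two libraries of the same sample (OLS slope/intercept + Pearson r).

Under pure Poisson read sampling an OTU with mean count ``mu`` is detected
with probability ``1 - exp(-mu)``; :func:`detection_probability_closed_form`
exposes that reference curve (it is why OTUs averaging >10 reads are
detected essentially always).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from ._seeds import derive_rng
from .beta import BETA_METRICS, _METRIC_FUNCS as _BETA_FUNCS
from .diversity import rarefy
from .io import CountTable

__all__ = [
    "DepthCurve",
    "DetectionRecord",
    "LogisticFit",
    "ConcordanceResult",
    "pseudo_beta_curve",
    "detection_frequency",
    "fit_detection_model",
    "detection_probability_closed_form",
    "abundance_concordance",
]


# -- replicate selection ---------------------------------------------------


def _replicates(table: CountTable, source_id: str, platform: str | None) -> list[str]:
    reps = [s for s, m in table.metadata.items() if m.source_id == source_id]
    if not reps:
        raise ValueError(f"no samples with source_id {source_id!r}")
    platforms = {table.metadata[s].platform for s in reps}
    if platform is None:
        if len(platforms) > 1:
            raise ValueError(
                f"source {source_id!r} spans platforms {sorted(platforms)}; pass platform="
            )
    else:
        reps = [s for s in reps if table.metadata[s].platform == platform]
    if len(reps) < 2:
        raise ValueError(f"need >= 2 technical replicates of {source_id!r}, found {len(reps)}")
    return sorted(reps)


# -- pseudo-beta-diversity -------------------------------------------------


@dataclass
class DepthCurve:
    """Mean between-replicate dissimilarity per rarefaction depth."""

    source_id: str
    metric: str
    points: list[tuple[int, float, float, int]]  # (depth, mean, sd, n_pairs)

    def depths(self) -> list[int]:
        return [p[0] for p in self.points]

    def means(self) -> list[float]:
        return [p[1] for p in self.points]


def pseudo_beta_curve(
    table: CountTable,
    source_id: str,
    metric: str,
    depths: list[int],
    n_draws: int = 10,
    seed: int = 0,
    platform: str | None = None,
) -> DepthCurve:
    """Between-replicate dissimilarity of one source sample across depths.

    At each depth every replicate with enough reads is independently rarefied
    ``n_draws`` times; all between-replicate pairs are scored per draw and the
    mean/sd across pairs x draws reported.  Depths no replicate set can
    support (fewer than two deep-enough replicates) are dropped with a
    warning.
    """
    if metric not in BETA_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if any(int(d) < 1 for d in depths):
        raise ValueError("all depths must be >= 1")
    reps = _replicates(table, source_id, platform)
    func = _BETA_FUNCS[metric]
    totals = {s: int(table.sample_counts(s).sum()) for s in reps}

    points = []
    for depth in sorted(int(d) for d in depths):
        usable = [s for s in reps if totals[s] >= depth]
        if len(usable) < 2:
            warnings.warn(
                f"depth {depth} dropped: fewer than 2 replicates of {source_id!r} reach it",
                stacklevel=2,
            )
            continue
        vals = []
        for draw in range(n_draws):
            sub = {
                s: rarefy(table.sample_counts(s), depth, derive_rng(seed, "pseudo", s, depth, draw))
                for s in usable
            }
            for a, b in combinations(usable, 2):
                vals.append(func(sub[a], sub[b]))
        n_pairs = len(usable) * (len(usable) - 1) // 2
        vals = np.asarray(vals)
        points.append((depth, float(vals.mean()), float(vals.std(ddof=1) if vals.size > 1 else 0.0), n_pairs))
    return DepthCurve(source_id, metric, points)


# -- detection consistency -------------------------------------------------


@dataclass(frozen=True)
class DetectionRecord:
    """Per-OTU detection summary across replicates of one source sample."""

    otu_id: str
    mean_abundance: float  # mean read count across replicates, zeros included
    detection_proportion: float  # fraction of replicates with count > 0
    n_replicates: int


def detection_frequency(
    table: CountTable,
    source_id: str,
    platform: str | None = None,
) -> list[DetectionRecord]:
    """One record per OTU present in >= 1 replicate of ``source_id``."""
    reps = _replicates(table, source_id, platform)
    sub = np.stack([table.sample_counts(s) for s in reps])
    present_any = sub.any(axis=0)
    n = len(reps)
    records = []
    for j in np.flatnonzero(present_any):
        col = sub[:, j]
        records.append(
            DetectionRecord(
                otu_id=table.otu_ids[j],
                mean_abundance=float(col.mean()),
                detection_proportion=float(np.count_nonzero(col) / n),
                n_replicates=n,
            )
        )
    return records


@dataclass
class LogisticFit:
    """Binomial logistic regression of detection on log10 mean abundance."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    lr_chi2: float
    converged: bool
    n_records: int = 0


def _binom_loglik(beta: np.ndarray, x: np.ndarray, successes: np.ndarray, trials: np.ndarray) -> float:
    eta = beta[0] + beta[1] * x
    # log(p) and log(1-p) via logaddexp for numerical safety
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    return float(np.sum(successes * log_p + (trials - successes) * log_q))


_BETA_CAP = 35.0  # |logit| beyond this is numerically saturated


def fit_detection_model(
    records: list[DetectionRecord],
    zero_policy: str = "half-min",
) -> LogisticFit:
    """Maximum-likelihood binomial logit fit of detection proportion on
    log10(mean abundance).

    ``zero_policy`` sets how zero mean abundances are made loggable:
    ``"half-min"`` replaces them with half the minimum positive mean;
    ``"fixed-0.1"`` replaces them with 0.1.  (Both conventions circulate in
    the literature; the default is half-min.)

    Fitting is Newton/IRLS to gradient norm < 1e-8 (max 100 iterations).
    Under perfect separation (e.g. every OTU detected in every replicate) the
    MLE diverges; the fit is then returned with ``converged=False`` and
    parameters capped at a finite saturation bound.
    """
    if not records:
        raise ValueError("no detection records")
    mu = np.array([r.mean_abundance for r in records], dtype=float)
    trials = np.array([r.n_replicates for r in records], dtype=float)
    successes = np.array(
        [round(r.detection_proportion * r.n_replicates) for r in records], dtype=float
    )
    if zero_policy == "half-min":
        positive = mu[mu > 0]
        if positive.size == 0:
            raise ValueError("all mean abundances are zero")
        mu = np.where(mu > 0, mu, positive.min() / 2.0)
    elif zero_policy == "fixed-0.1":
        mu = np.where(mu > 0, mu, 0.1)
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    x = np.log10(mu)
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct abundance values")

    degenerate = bool(np.all(successes == trials) or np.all(successes == 0))
    if degenerate:
        warnings.warn(
            "degenerate response (every record fully detected or fully missed): "
            "no finite MLE; returning capped estimates with converged=False",
            stacklevel=2,
        )

    beta = np.zeros(2)
    design = np.column_stack([np.ones_like(x), x])
    converged = False
    for _ in range(100):
        eta = design @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        grad = design.T @ (successes - trials * p)
        if np.linalg.norm(grad) < 1e-8:
            converged = True
            break
        w = trials * p * (1.0 - p)
        info = design.T @ (design * w[:, None])
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # damped Newton: halve until the log-likelihood does not decrease
        ll0 = _binom_loglik(beta, x, successes, trials)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            if _binom_loglik(cand, x, successes, trials) >= ll0 - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        if np.max(np.abs(beta)) > _BETA_CAP * 10:
            break
    if converged and (degenerate or np.max(np.abs(beta)) > _BETA_CAP):
        # gradient vanishes numerically once the probabilities saturate, so a
        # "converged" solution at extreme coefficients is really separation
        converged = False
    if not converged:
        if not degenerate:
            warnings.warn(
                "logistic fit did not converge (possible separation); capping", stacklevel=2
            )
        beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)

    eta = design @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    w = trials * p * (1.0 - p)
    info = design.T @ (design * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.array([np.inf, np.inf])

    # LR statistic vs the intercept-only model (closed-form null MLE)
    p0 = successes.sum() / trials.sum()
    p0 = min(max(p0, 1e-12), 1 - 1e-12)
    beta0 = np.array([np.log(p0 / (1 - p0)), 0.0])
    ll_full = _binom_loglik(beta, x, successes, trials)
    ll_null = _binom_loglik(beta0, x, successes, trials)
    lr = max(2.0 * (ll_full - ll_null), 0.0)

    return LogisticFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        lr_chi2=float(lr),
        converged=converged,
        n_records=len(records),
    )


def detection_probability_closed_form(mu: float) -> float:
    """Poisson-sampling detection probability ``1 - exp(-mu)``."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return float(-np.expm1(-mu))


# -- abundance concordance -------------------------------------------------


@dataclass
class ConcordanceResult:
    """log10(x+1) read-abundance agreement between two replicate libraries."""

    slope: float
    intercept: float
    pearson_r: float
    n_otus: int


def abundance_concordance(
    table: CountTable,
    source_id: str,
    replicate_a: str,
    replicate_b: str,
) -> ConcordanceResult:
    """OLS of log10(count+1) in ``replicate_b`` on ``replicate_a`` over OTUs
    present in either library, plus the Pearson correlation.

    A slope near 1 with r near 1 means per-OTU read abundance in one library
    predicts the other — e.g. a single-PCR library predicting a 16-PCR pool.
    """
    for s in (replicate_a, replicate_b):
        if s not in table.sample_ids:
            raise ValueError(f"unknown sample {s!r}")
        if table.metadata and table.metadata.get(s, None) is not None:
            if table.metadata[s].source_id != source_id:
                raise ValueError(f"{s!r} does not belong to source {source_id!r}")
    xa = table.sample_counts(replicate_a).astype(float)
    xb = table.sample_counts(replicate_b).astype(float)
    support = (xa > 0) | (xb > 0)
    if np.count_nonzero(support) < 3:
        raise ValueError("need >= 3 OTUs present in either replicate")
    la = np.log10(xa[support] + 1.0)
    lb = np.log10(xb[support] + 1.0)
    if replicate_a == replicate_b or np.array_equal(xa, xb):
        return ConcordanceResult(1.0, 0.0, 1.0, int(np.count_nonzero(support)))
    res = stats.linregress(la, lb)
    return ConcordanceResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        n_otus=int(np.count_nonzero(support)),
    )
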