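"""End-to-end study pipelines on simulated data.

Two orchestrations mirror the two arms of a pooled-replicate, two-platform
amplicon study:

* :func:`run_replication_study` — simulate the replication design, then ask
  whether pooling more PCR reactions changes anything: alpha diversity per
  platform at fixed rarefaction depth, a factorial ANOVA (pooling level x
  source sample x platform, sequential SS), pseudo-beta-diversity depth
  curves, per-OTU detection records with the logistic fit, and log-abundance
  concordance between the 1-PCR and 16-PCR libraries.
* :func:`run_platform_study` — simulate the cross-platform design, then ask
  whether the two platforms tell the same ecological story: per-platform
  alpha and cross-platform alpha regressions, per-platform distance matrices
  with Mantel correlations, perMANOVA for platform and for bioregion on the
  combined matrix, and the shared/unique OTU partition.

Every run writes plain TSV outputs plus a ``manifest.json`` recording the
command, config hash, master seed and package version.  All randomness
derives from the single master seed, so outputs are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from ._seeds import derive_seed
from .beta import DistanceMatrix, _pairwise, distance_matrix
from .diversity import alpha_table, rarefy
from .inference import factorial_anova, mantel, permanova, platform_overlap
from .io import CountTable, write_count_table, write_metadata
from .reproducibility import (
    abundance_concordance,
    detection_frequency,
    fit_detection_model,
    pseudo_beta_curve,
)
from .simulate import SimulationConfig, simulate_experiment

__all__ = [
    "load_config",
    "run_replication_study",
    "run_platform_study",
    "write_manifest",
    "alpha_by_platform",
    "platform_tables",
    "combined_distance_matrix",
    "REPLICATION_ANOVA_FORMULA",
]

# Pooling level enters as a numeric covariate; the model is the full
# factorial crossing of pooling level, source sample and platform.  The
# source x platform interaction must be in the model: source richness
# differences scale with platform depth, and leaving that interaction in the
# residual makes every other F conservative.
REPLICATION_ANOVA_FORMULA = "value ~ pool_size * source_id * platform"

_REPLICATION_ANALYSIS_DEFAULTS = {
    "rarefaction_depth_by_platform": {"454": 500, "illumina": 38000},
    "pseudo_beta_depths_by_platform": {
        "454": [50, 100, 200, 400, 600, 800, 1000],
        "illumina": [100, 1000, 10000, 20000, 40000, 60000],
    },
    "pseudo_beta_metrics": ["bray_curtis", "jaccard"],
    "n_rarefactions": 10,
    "n_draws": 10,
    "zero_policy": "half-min",
}

_PLATFORM_ANALYSIS_DEFAULTS = {
    "rarefaction_depth_by_platform": {"454": 1000, "illumina": 40000},
    "metrics": ["jaccard", "bray_curtis", "beta_sim"],
    "alpha_regression_metrics": ["observed", "chao1", "fishers_alpha"],
    "n_rarefactions": 10,
    "n_permutations": 999,
}


def load_config(path: str | Path | None) -> tuple[SimulationConfig, dict]:
    """Load a JSON study config: ``{"simulation": {...}, "analysis": {...}}``.

    A flat object is treated as simulation fields.  Missing keys fall back to
    defaults; ``None`` yields an all-default configuration.
    """
    if path is None:
        return SimulationConfig(), {}
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    sim_doc = doc.get("simulation", doc if "analysis" not in doc else {})
    analysis = doc.get("analysis", {})
    sim = dict(sim_doc)
    for key in ("pool_sizes", "source_sigmas"):
        if key in sim:
            sim[key] = tuple(sim[key])
    return SimulationConfig(**sim), analysis


def _config_hash(config: SimulationConfig, analysis: dict) -> str:
    payload = json.dumps({"simulation": asdict(config), "analysis": analysis}, sort_keys=True)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


def write_manifest(
    out_dir: str | Path,
    command: str,
    config_hash: str,
    seed: int,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config_hash": config_hash,
        "seed": int(seed),
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path


def _log(stage: str, t0: float) -> None:
    print(f"[ampliconrep] {stage} ({time.perf_counter() - t0:.1f}s)", file=sys.stderr)


def _write_tsv(frame: pd.DataFrame, path: Path, float_fmt: str = "%.10g") -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=float_fmt)


def _stage(name: str):
    """Context manager tagging any stage failure with the stage name."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            _log(name, self.t0)

    return _Ctx()


def _alpha_frame(table: CountTable, depths: dict, n_rarefactions: int, seed: int) -> pd.DataFrame:
    """Per-platform rarefied alpha results joined with metadata."""
    frames = []
    for platform, depth in sorted(depths.items()):
        sub_ids = [s for s, m in table.metadata.items() if m.platform == platform]
        if not sub_ids:
            continue
        sub = table.subset_samples(sorted(sub_ids))
        res = alpha_table(sub, int(depth), derive_seed(seed, "alpha", platform), n_rarefactions)
        frames.append(res.results)
    alpha = pd.concat(frames, ignore_index=True)
    meta = table.meta_frame().drop(columns=["sample_id"])
    return alpha.join(meta, on="sample_id").sort_values(["metric", "sample_id"], ignore_index=True)


def alpha_by_platform(
    table: CountTable,
    depth_by_platform: dict,
    n_rarefactions: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Rarefied alpha diversity with each platform held to its own depth,
    joined with sample metadata (long format: sample_id, metric, value, plus
    metadata columns)."""
    return _alpha_frame(table, depth_by_platform, n_rarefactions, seed)


# -- replication study -----------------------------------------------------


def run_replication_study(
    config: SimulationConfig,
    out_dir: str | Path,
    analysis: dict | None = None,
) -> Path:
    """Simulate the replication design and run the full pooling analysis.

    Writes ``table.tsv``, ``metadata.tsv``, ``alpha.tsv``, ``anova.tsv``,
    ``curves.tsv``, ``detection.tsv``, ``detection_fit.tsv``,
    ``concordance.tsv`` and ``manifest.json`` into ``out_dir``.
    """
    params = {**_REPLICATION_ANALYSIS_DEFAULTS, **(analysis or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    with _stage("simulate replication design"):
        table = simulate_experiment(config, "replication")
        write_count_table(table, out / "table.tsv")
        write_metadata(table, out / "metadata.tsv")

    with _stage("alpha diversity"):
        alpha = _alpha_frame(
            table, params["rarefaction_depth_by_platform"], params["n_rarefactions"], seed
        )
        _write_tsv(alpha, out / "alpha.tsv")

    with _stage("factorial ANOVA"):
        rows = []
        for metric, sub in alpha.groupby("metric"):
            aov = factorial_anova(sub, REPLICATION_ANOVA_FORMULA)
            for name, df_t, ss, f, p in aov.terms:
                rows.append({"metric": metric, "term": name, "df": df_t, "sum_sq": ss, "F": f, "p": p})
            rows.append(
                {
                    "metric": metric,
                    "term": "Residual",
                    "df": aov.residual_df,
                    "sum_sq": aov.residual_sum_sq,
                    "F": np.nan,
                    "p": np.nan,
                }
            )
        _write_tsv(pd.DataFrame(rows), out / "anova.tsv")

    with _stage("pseudo-beta-diversity curves"):
        rows = []
        sources = sorted({m.source_id for m in table.metadata.values()})
        for src in sources:
            for platform, depths in sorted(params["pseudo_beta_depths_by_platform"].items()):
                for metric in params["pseudo_beta_metrics"]:
                    curve = pseudo_beta_curve(
                        table,
                        src,
                        metric,
                        depths,
                        n_draws=params["n_draws"],
                        seed=derive_seed(seed, "curve", src, platform, metric),
                        platform=platform,
                    )
                    for depth, mean, sd, n_pairs in curve.points:
                        rows.append(
                            {
                                "source_id": src,
                                "platform": platform,
                                "metric": metric,
                                "depth": depth,
                                "mean_dissimilarity": mean,
                                "sd": sd,
                                "n_pairs": n_pairs,
                            }
                        )
        _write_tsv(pd.DataFrame(rows), out / "curves.tsv")

    with _stage("detection frequency + logistic fit"):
        det_rows = []
        fit_rows = []
        for platform in sorted(config.platforms):
            pooled = []
            for src in sources:
                records = detection_frequency(table, src, platform=platform)
                pooled.extend(records)
                det_rows.extend(
                    {
                        "source_id": src,
                        "platform": platform,
                        "otu_id": r.otu_id,
                        "mean_abundance": r.mean_abundance,
                        "detection_proportion": r.detection_proportion,
                        "n_replicates": r.n_replicates,
                    }
                    for r in records
                )
            fit = fit_detection_model(pooled, zero_policy=params["zero_policy"])
            fit_rows.append(
                {
                    "platform": platform,
                    "intercept": fit.intercept,
                    "slope": fit.slope,
                    "se_intercept": fit.se_intercept,
                    "se_slope": fit.se_slope,
                    "lr_chi2": fit.lr_chi2,
                    "converged": fit.converged,
                    "n_records": fit.n_records,
                }
            )
        _write_tsv(pd.DataFrame(det_rows), out / "detection.tsv")
        _write_tsv(pd.DataFrame(fit_rows), out / "detection_fit.tsv")

    with _stage("1-vs-16 PCR concordance"):
        rows = []
        lo, hi = min(config.pool_sizes), max(config.pool_sizes)
        for src in sources:
            for platform in sorted(config.platforms):
                rep_a = f"{src}.{platform}.p{lo:02d}"
                rep_b = f"{src}.{platform}.p{hi:02d}"
                if rep_a not in table.sample_ids or rep_b not in table.sample_ids:
                    continue
                res = abundance_concordance(table, src, rep_a, rep_b)
                rows.append(
                    {
                        "source_id": src,
                        "platform": platform,
                        "replicate_a": rep_a,
                        "replicate_b": rep_b,
                        "slope": res.slope,
                        "intercept": res.intercept,
                        "pearson_r": res.pearson_r,
                        "n_otus": res.n_otus,
                    }
                )
        _write_tsv(pd.DataFrame(rows), out / "concordance.tsv")

    write_manifest(out, "run-replication-study", _config_hash(config, params), seed)
    return out


# -- cross-platform study --------------------------------------------------


def _platform_tables(table: CountTable) -> dict[str, CountTable]:
    """Split by platform, relabelling samples by source so the two platform
    tables align sample-for-sample."""
    out = {}
    for platform in sorted({m.platform for m in table.metadata.values()}):
        ids = sorted(s for s, m in table.metadata.items() if m.platform == platform)
        sub = table.subset_samples(ids)
        mapping = {s: sub.metadata[s].source_id for s in ids}
        meta = {}
        for s in ids:
            m = sub.metadata[s]
            meta[mapping[s]] = type(m)(
                sample_id=mapping[s],
                source_id=m.source_id,
                pool_size=m.pool_size,
                platform=m.platform,
                group=m.group,
                replicate_index=m.replicate_index,
            )
        out[platform] = CountTable(
            list(sub.otu_ids), [mapping[s] for s in ids], sub.counts, meta
        )
    return out


def _combined_distance(
    table: CountTable,
    depths: dict,
    metric: str,
    seed: int,
) -> DistanceMatrix:
    """One distance matrix over libraries from both platforms, each rarefied
    to its own platform's depth (the standard per-platform normalization
    before a joint ordination/perMANOVA).

    Because the two platforms are rarefied to different depths, rarefied
    counts are converted to relative abundances before computing distances;
    otherwise an abundance-weighted metric between a 1,000-read and a
    40,000-read vector just measures the depth difference.  Presence-based
    metrics are unaffected by the rescaling.
    """
    keep = []
    rows = []
    for sid in table.sample_ids:
        platform = table.metadata[sid].platform
        depth = int(depths[platform])
        x = table.sample_counts(sid)
        if x.sum() < depth:
            continue
        keep.append(sid)
        sub = rarefy(x, depth, derive_seed(seed, "combined", sid)).astype(float)
        rows.append(sub / sub.sum())
    values = _pairwise(np.stack(rows), metric)
    return DistanceMatrix(keep, values, metric, None, seed)


def run_platform_study(
    config: SimulationConfig,
    out_dir: str | Path,
    analysis: dict | None = None,
) -> Path:
    """Simulate the cross-platform design and compare the platforms' stories.

    Writes ``table.tsv``, ``metadata.tsv``, ``alpha.tsv``,
    ``alpha_regression.tsv``, ``dist_<platform>_<metric>.tsv``,
    ``mantel.tsv``, ``permanova.tsv``, ``overlap.tsv`` and ``manifest.json``.
    """
    params = {**_PLATFORM_ANALYSIS_DEFAULTS, **(analysis or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    depths = {k: int(v) for k, v in params["rarefaction_depth_by_platform"].items()}

    with _stage("simulate cross-platform design"):
        table = simulate_experiment(config, "cross_platform")
        write_count_table(table, out / "table.tsv")
        write_metadata(table, out / "metadata.tsv")

    with _stage("alpha diversity + cross-platform regression"):
        alpha = _alpha_frame(table, depths, params["n_rarefactions"], seed)
        _write_tsv(alpha, out / "alpha.tsv")
        platforms = sorted({m.platform for m in table.metadata.values()})
        pa, pb = platforms  # regression of first platform's value on second's
        rows = []
        for metric in params["alpha_regression_metrics"]:
            sub = alpha[alpha["metric"] == metric]
            wide = sub.pivot_table(index="source_id", columns="platform", values="value")
            wide = wide.dropna()
            res = sps.linregress(wide[pb], wide[pa])
            rows.append(
                {
                    "metric": metric,
                    "response": pa,
                    "predictor": pb,
                    "slope": res.slope,
                    "stderr": res.stderr,
                    "intercept": res.intercept,
                    "r_squared": res.rvalue**2,
                    "p": res.pvalue,
                    "n": len(wide),
                }
            )
        _write_tsv(pd.DataFrame(rows), out / "alpha_regression.tsv")

    with _stage("distance matrices + Mantel"):
        per_platform = _platform_tables(table)
        mantel_rows = []
        dms: dict[tuple[str, str], DistanceMatrix] = {}
        for metric in params["metrics"]:
            for platform, sub in per_platform.items():
                dm = distance_matrix(
                    sub, metric, depths[platform], derive_seed(seed, "dm", platform, metric)
                )
                dms[(platform, metric)] = dm
                dm.to_dataframe().to_csv(out / f"dist_{platform}_{metric}.tsv", sep="\t")
            d1 = dms[(platforms[0], metric)]
            d2 = dms[(platforms[1], metric)]
            common = [s for s in d1.sample_ids if s in set(d2.sample_ids)]
            d1c = _subset_dm(d1, common)
            d2c = _subset_dm(d2, common)
            res = mantel(d1c, d2c, params["n_permutations"], derive_seed(seed, "mantel", metric))
            # slope of one platform's dissimilarities on the other's
            slope = sps.linregress(d2c.condensed(), d1c.condensed())
            mantel_rows.append(
                {
                    "metric": metric,
                    "mantel_r": res.statistic,
                    "p": res.p_value,
                    "n_permutations": res.n_permutations,
                    "slope": slope.slope,
                    "slope_stderr": slope.stderr,
                    "n_samples": len(common),
                }
            )
        _write_tsv(pd.DataFrame(mantel_rows), out / "mantel.tsv")

    with _stage("perMANOVA (platform, bioregion)"):
        rows = []
        for metric in params["metrics"]:
            dm = _combined_distance(table, depths, metric, seed)
            meta = table.metadata
            for factor, labels in (
                ("platform", [meta[s].platform for s in dm.sample_ids]),
                ("group", [meta[s].group for s in dm.sample_ids]),
            ):
                res = permanova(
                    dm, labels, params["n_permutations"], derive_seed(seed, "permanova", metric, factor)
                )
                rows.append(
                    {
                        "metric": metric,
                        "factor": factor,
                        "pseudo_F": res.statistic,
                        "df_between": res.df[0],
                        "df_within": res.df[1],
                        "r_squared": res.r_squared,
                        "p": res.p_value,
                        "n_permutations": res.n_permutations,
                    }
                )
        _write_tsv(pd.DataFrame(rows), out / "permanova.tsv")

    with _stage("platform OTU overlap"):
        ov = platform_overlap(table)
        frame = pd.DataFrame(
            [
                {
                    "class": "shared",
                    "n_otus": ov.shared,
                    "fraction": ov.shared / ov.total,
                },
                {
                    "class": f"unique_{ov.platform_a}",
                    "n_otus": ov.unique_a,
                    "fraction": ov.unique_a / ov.total,
                },
                {
                    "class": f"unique_{ov.platform_b}",
                    "n_otus": ov.unique_b,
                    "fraction": ov.unique_b / ov.total,
                },
            ]
        )
        _write_tsv(frame, out / "overlap.tsv")

    write_manifest(out, "run-platform-study", _config_hash(config, params), seed)
    return out


def platform_tables(table: CountTable) -> dict[str, CountTable]:
    """Split a two-platform table into per-platform tables whose samples are
    relabelled by source, so they align sample-for-sample."""
    return _platform_tables(table)


def combined_distance_matrix(
    table: CountTable,
    depth_by_platform: dict,
    metric: str,
    seed: int = 0,
) -> DistanceMatrix:
    """Joint distance matrix over both platforms' libraries, each rarefied to
    its platform's depth and normalized to relative abundance."""
    return _combined_distance(table, depth_by_platform, metric, seed)


def _subset_dm(dm: DistanceMatrix, ids: list[str]) -> DistanceMatrix:
    idx = [dm.sample_ids.index(s) for s in ids]
    return DistanceMatrix(list(ids), dm.values[np.ix_(idx, idx)], dm.metric, dm.depth, dm.seed)
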