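"""Synthetic amplicon library-preparation simulator.

Generates OTU count tables that emulate a two-pronged sequencing study
design:

* a **replication** design: three soil communities, each amplified as a pool
  of 1/2/4/8/16 independent PCR reactions and sequenced on two platforms with
  very different read depths (a shallow pyrosequencing-like platform, a deep
  short-read platform);
* a **cross_platform** design: three bioregions x two sites x ten samples,
  every sample sequenced on both platforms, with bioregion-level
  metacommunity structure.

The generative chain per library is: true community profile -> multinomial
template sampling (``template_molecules`` DNA molecules enter each PCR) ->
a few exactly-branching PCR cycles (per-molecule binomial duplication at
taxon-specific efficiency) -> deterministic exponential growth for the
remaining cycles -> equal-volume pooling of replicate reactions ->
multinomial read sampling at the platform depth, with each read turning into
a spurious "error" OTU with probability ``error_rate``.

Per-taxon amplification efficiency is ``clip(mean + taxon offset + reaction
offset, 0.01, 1)``: taxon offsets are redrawn per platform (different
primers, persistent bias), while the reaction offset is a single scalar per
PCR reaction (reaction-wide conditions shift all taxa together, so it is
nearly composition-neutral).  Exact branching is restricted to the first few
cycles because that is where per-molecule stochasticity still matters; after
thousands of copies exist, growth is effectively deterministic, and full
30-cycle branching would overflow integer ranges for no added realism.

Spurious OTUs are labelled ``ERR_<parent>_<j>`` with ``j`` drawn from a
geometric "collision" distribution, so repeated errors on an abundant parent
can hit the *same* spurious OTU and recur across replicates — mimicking how
real low-abundance error OTUs reappear in re-sequenced libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import derive_rng, derive_seed
from .io import CountTable, SampleMeta

__all__ = [
    "CommunityProfile",
    "SimulationConfig",
    "make_community",
    "simulate_pcr",
    "pool_replicates",
    "sequence_sample",
    "simulate_experiment",
    "REPLICATION_SOURCES",
]

REPLICATION_SOURCES = ("CT2", "OR1", "OR4")
CROSS_PLATFORM_GROUPS = ("AK", "CA", "NC")


@dataclass
class CommunityProfile:
    """True relative abundances of a simulated community (sums to 1)."""

    otu_ids: list[str]
    abundance: np.ndarray

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundance, dtype=float)
        if ab.shape != (len(self.otu_ids),):
            raise ValueError("abundance must align with otu_ids")
        if ab.size == 0:
            raise ValueError("community must contain at least one taxon")
        if np.min(ab) < 0:
            raise ValueError("abundances must be non-negative")
        if abs(ab.sum() - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1, got {ab.sum()}")
        self.abundance = ab / ab.sum()


@dataclass
class SimulationConfig:
    """Full parameterization of the library-prep generative model.

    Defaults emulate a soil-fungus amplicon study: a lognormal community of
    1,500 taxa calibrated so observed richness lands near 30-60 OTUs at 500
    reads and 200-350 OTUs at 38,000 reads; 30 PCR cycles of which the first 5 branch
    stochastically; template pools far deeper than any read depth (real
    extracts contain orders of magnitude more template molecules than the
    sequencer samples reads); and a shallow vs deep platform pair.  All rates
    and sizes are explicit knobs — none is asserted to be a measured value.
    """

    n_taxa: int = 1500
    abundance_model: str = "lognormal"  # or "geometric"
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 4.0
    geometric_theta: float = 0.01
    # replication design: per-source lognormal sigmas so the three soils
    # differ systematically in diversity
    source_sigmas: tuple[float, ...] = (3.8, 4.0, 4.2)
    template_molecules: int = 1_000_000
    cycles: int = 30
    stochastic_cycles: int = 5
    efficiency_mean: float = 0.8
    efficiency_sd_taxon: float = 0.02
    efficiency_sd_reaction: float = 0.02
    pool_sizes: tuple[int, ...] = (1, 2, 4, 8, 16)
    depth_by_platform: dict = field(default_factory=lambda: {"454": 1200, "illumina": 65000})
    platform_detectable_fraction: dict = field(
        default_factory=lambda: {"454": 1.0, "illumina": 1.0}
    )
    error_rate: float = 0.005
    error_collision: float = 0.5  # geometric p for the spurious-OTU label index
    group_concentration: float = 200.0
    # fraction of the global taxon pool available to each bioregion's
    # metacommunity; distinct regions share only part of the species pool
    group_taxon_fraction: float = 0.6
    n_groups: int = 3
    n_sites_per_group: int = 2
    n_samples_per_site: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if self.abundance_model not in ("lognormal", "geometric"):
            raise ValueError(f"unknown abundance_model {self.abundance_model!r}")
        if not 0 < self.geometric_theta < 1:
            raise ValueError("geometric_theta must lie in (0, 1)")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be >= 0")
        if self.template_molecules < 1:
            raise ValueError("template_molecules must be >= 1")
        if not 0 <= self.stochastic_cycles <= self.cycles:
            raise ValueError("need 0 <= stochastic_cycles <= cycles")
        if not 0 < self.efficiency_mean <= 1:
            raise ValueError("efficiency_mean must lie in (0, 1]")
        if min(self.efficiency_sd_taxon, self.efficiency_sd_reaction) < 0:
            raise ValueError("efficiency sds must be >= 0")
        if any(k < 1 for k in self.pool_sizes):
            raise ValueError("pool sizes must be >= 1")
        for plat, d in self.depth_by_platform.items():
            if int(d) < 1:
                raise ValueError(f"depth for {plat!r} must be >= 1")
        for plat, f in self.platform_detectable_fraction.items():
            if not 0 < f <= 1:
                raise ValueError(f"detectable fraction for {plat!r} must lie in (0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        if not 0 < self.error_collision <= 1:
            raise ValueError("error_collision must lie in (0, 1]")
        if self.group_concentration <= 0:
            raise ValueError("group_concentration must be > 0")
        if not 0 < self.group_taxon_fraction <= 1:
            raise ValueError("group_taxon_fraction must lie in (0, 1]")

    @property
    def platforms(self) -> tuple[str, ...]:
        return tuple(self.depth_by_platform)


def _otu_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"OTU_{i + 1:0{width}d}" for i in range(n)]


def make_community(
    config: SimulationConfig,
    seed: int | None = None,
    sigma_ln: float | None = None,
) -> CommunityProfile:
    """Draw a true community profile from the configured abundance model.

    Abundances are sorted descending and normalized.  ``sigma_ln`` overrides
    the lognormal sd (used to give different sources different diversity).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_taxa
    if config.abundance_model == "lognormal":
        sigma = config.lognormal_sigma if sigma_ln is None else float(sigma_ln)
        if sigma < 0:
            raise ValueError("sigma_ln must be >= 0")
        weights = rng.lognormal(config.lognormal_mu, sigma, size=n)
    else:
        theta = config.geometric_theta
        weights = theta * (1 - theta) ** np.arange(n)
    weights = np.sort(weights)[::-1]
    return CommunityProfile(_otu_ids(n), weights / weights.sum())


def simulate_pcr(
    community: CommunityProfile,
    config: SimulationConfig,
    efficiencies: np.ndarray,
    seed: int,
) -> CommunityProfile:
    """One PCR reaction: template sampling, branching, deterministic growth.

    Template molecules are drawn multinomially from the community; for the
    first ``stochastic_cycles`` rounds each taxon's molecule count grows by a
    binomial draw at its efficiency; the remaining cycles multiply
    deterministically by ``(1 + e_i)^(cycles - stochastic_cycles)``.  The
    amplicon pool is returned renormalized as a profile.  A taxon that drew
    zero template molecules stays absent.
    """
    eff = np.asarray(efficiencies, dtype=float)
    if eff.shape != (len(community.otu_ids),):
        raise ValueError("efficiencies must align with community taxa")
    if np.min(eff) <= 0 or np.max(eff) > 1:
        raise ValueError("efficiencies must lie in (0, 1]")
    if config.template_molecules < 1:
        raise ValueError("template_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(config.template_molecules, community.abundance).astype(np.int64)
    for _ in range(config.stochastic_cycles):
        counts = counts + rng.binomial(counts, eff)
    grown = counts.astype(float) * (1.0 + eff) ** (config.cycles - config.stochastic_cycles)
    return CommunityProfile(list(community.otu_ids), grown / grown.sum())


def pool_replicates(
    profiles: list[CommunityProfile],
    weights: np.ndarray | None = None,
) -> CommunityProfile:
    """Pool PCR reactions: (weighted) average of profiles, renormalized."""
    if not profiles:
        raise ValueError("need at least one profile")
    ids = profiles[0].otu_ids
    for p in profiles[1:]:
        if p.otu_ids != ids:
            raise ValueError("profiles must share identical otu_ids")
    w = np.ones(len(profiles)) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (len(profiles),) or np.min(w) < 0 or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    stacked = np.stack([p.abundance for p in profiles])
    pooled = (w[:, None] * stacked).sum(axis=0)
    return CommunityProfile(list(ids), pooled / pooled.sum())


def sequence_sample(
    profile: CommunityProfile,
    platform: str,
    config: SimulationConfig,
    seed: int,
) -> pd.Series:
    """Sequence a pooled amplicon profile on one platform.

    Taxa outside the platform's detectable set are masked (profile
    renormalized); reads are drawn multinomially at the platform depth; each
    read independently becomes a spurious-OTU read with probability
    ``error_rate`` and is reassigned to ``ERR_<parent>_<j>`` with geometric
    ``j``.  The returned Series (indexed by OTU id, spurious labels appended)
    sums exactly to the platform depth.
    """
    if platform not in config.depth_by_platform:
        raise ValueError(f"unknown platform {platform!r}")
    depth = int(config.depth_by_platform[platform])
    n = len(profile.otu_ids)
    frac = float(config.platform_detectable_fraction.get(platform, 1.0))
    p = profile.abundance.copy()
    if frac < 1.0:
        # the detectable set is a property of the platform (primers), fixed
        # across every sample sequenced on it for a given master seed
        mask_rng = derive_rng(config.seed, "detectable", platform)
        n_detect = max(1, int(np.floor(frac * n)))
        detectable = np.zeros(n, dtype=bool)
        detectable[mask_rng.choice(n, size=n_detect, replace=False)] = True
        p = np.where(detectable, p, 0.0)
    if p.sum() == 0:
        raise ValueError("all taxa with abundance are masked on this platform")
    p = p / p.sum()

    rng = np.random.default_rng(seed)
    reads = rng.multinomial(depth, p).astype(np.int64)
    out = pd.Series(reads, index=list(profile.otu_ids), dtype=np.int64)
    if config.error_rate > 0:
        n_err = rng.binomial(reads, config.error_rate)
        out -= n_err
        err_counts: dict[str, int] = {}
        for j_parent in np.flatnonzero(n_err):
            labels = rng.geometric(config.error_collision, size=int(n_err[j_parent]))
            for j in labels:
                key = f"ERR_{profile.otu_ids[j_parent]}_{int(j)}"
                err_counts[key] = err_counts.get(key, 0) + 1
        if err_counts:
            out = pd.concat([out, pd.Series(err_counts, dtype=np.int64)])
    assert int(out.sum()) == depth
    return out


# -- experiment designs ----------------------------------------------------


def _reaction_efficiencies(
    config: SimulationConfig,
    taxon_offsets: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    delta = rng.normal(0.0, config.efficiency_sd_reaction)
    return np.clip(config.efficiency_mean + taxon_offsets + delta, 0.01, 1.0)


def _platform_taxon_offsets(config: SimulationConfig, platform: str) -> np.ndarray:
    rng = derive_rng(config.seed, "taxon-eff", platform)
    return rng.normal(0.0, config.efficiency_sd_taxon, size=config.n_taxa)


def _assemble(table: dict[str, pd.Series], meta: dict[str, SampleMeta], n_taxa: int) -> CountTable:
    real = _otu_ids(n_taxa)
    err = sorted({o for s in table.values() for o in s.index if o.startswith("ERR_")})
    cols = real + err
    frame = pd.DataFrame(index=list(table), columns=cols, dtype=float)
    for sid, series in table.items():
        frame.loc[sid] = series.reindex(cols, fill_value=0)
    frame = frame.fillna(0.0)
    # drop globally absent spurious columns only (real taxa keep their slot)
    keep = real + [c for c in err if frame[c].sum() > 0]
    return CountTable(keep, list(table), frame[keep].to_numpy(dtype=np.int64), meta)


def _simulate_library(
    community: CommunityProfile,
    config: SimulationConfig,
    platform: str,
    taxon_offsets: np.ndarray,
    pool_size: int,
    tag: str,
) -> pd.Series:
    profiles = []
    for r in range(pool_size):
        rng = derive_rng(config.seed, "pcr", tag, r)
        eff = _reaction_efficiencies(config, taxon_offsets, rng)
        profiles.append(
            simulate_pcr(community, config, eff, derive_seed(config.seed, "pcr-draw", tag, r))
        )
    pooled = pool_replicates(profiles)
    return sequence_sample(pooled, platform, config, derive_seed(config.seed, "seq", tag))


def simulate_experiment(config: SimulationConfig, design: str = "replication") -> CountTable:
    """Simulate a full sequencing experiment; deterministic given
    ``config.seed``.

    ``design="replication"``: every source x pool size x platform combination
    yields one library (3 x 5 x 2 = 30 samples under the defaults).
    ``design="cross_platform"``: groups x sites x samples, each sample
    sequenced on both platforms, with group-level metacommunity structure
    set by ``group_concentration``.
    """
    if design == "replication":
        return _replication_design(config)
    if design == "cross_platform":
        return _cross_platform_design(config)
    raise ValueError(f"unknown design {design!r}")


def _replication_design(config: SimulationConfig) -> CountTable:
    offsets = {p: _platform_taxon_offsets(config, p) for p in config.platforms}
    columns: dict[str, pd.Series] = {}
    meta: dict[str, SampleMeta] = {}
    for i, src in enumerate(REPLICATION_SOURCES):
        sigma = None
        if config.abundance_model == "lognormal" and config.source_sigmas:
            sigma = config.source_sigmas[i % len(config.source_sigmas)]
        community = make_community(
            config, seed=derive_seed(config.seed, "community", src), sigma_ln=sigma
        )
        for platform in config.platforms:
            for rep_idx, k in enumerate(config.pool_sizes):
                tag = f"{src}/{platform}/p{k}"
                sid = f"{src}.{platform}.p{k:02d}"
                columns[sid] = _simulate_library(
                    community, config, platform, offsets[platform], int(k), tag
                )
                meta[sid] = SampleMeta(
                    sample_id=sid,
                    source_id=src,
                    pool_size=int(k),
                    platform=platform,
                    group=src,
                    replicate_index=rep_idx,
                )
    return _assemble(columns, meta, config.n_taxa)


def _dirichlet_like(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw via gammas, tolerating very small concentrations (tiny
    components underflow to 0, i.e. the taxon is absent from that draw)."""
    g = rng.gamma(np.maximum(alpha, 1e-12))
    total = g.sum()
    if total == 0:
        raise ValueError("degenerate Dirichlet draw: all components zero")
    return g / total


def _cross_platform_design(config: SimulationConfig) -> CountTable:
    offsets = {p: _platform_taxon_offsets(config, p) for p in config.platforms}
    groups = [CROSS_PLATFORM_GROUPS[i % 3] + ("" if i < 3 else str(i)) for i in range(config.n_groups)]
    columns: dict[str, pd.Series] = {}
    meta: dict[str, SampleMeta] = {}
    conc = config.group_concentration
    for group in groups:
        base = make_community(config, seed=derive_seed(config.seed, "metacommunity", group))
        if config.group_taxon_fraction < 1.0:
            mask_rng = derive_rng(config.seed, "group-pool", group)
            n_keep = max(1, int(round(config.group_taxon_fraction * config.n_taxa)))
            keep = np.zeros(config.n_taxa, dtype=bool)
            keep[mask_rng.choice(config.n_taxa, size=n_keep, replace=False)] = True
            ab = np.where(keep, base.abundance, 0.0)
            base = CommunityProfile(list(base.otu_ids), ab / ab.sum())
        for s in range(config.n_sites_per_group):
            site = f"{group}{s + 1}"
            site_rng = derive_rng(config.seed, "site", site)
            site_profile = _dirichlet_like(site_rng, 5.0 * conc * base.abundance)
            for j in range(config.n_samples_per_site):
                source = f"{site}.s{j + 1:02d}"
                samp_rng = derive_rng(config.seed, "sample", source)
                sample_profile = CommunityProfile(
                    list(base.otu_ids), _dirichlet_like(samp_rng, conc * site_profile)
                )
                for platform in config.platforms:
                    tag = f"{source}/{platform}"
                    sid = f"{source}.{platform}"
                    columns[sid] = _simulate_library(
                        sample_profile, config, platform, offsets[platform], 1, tag
                    )
                    meta[sid] = SampleMeta(
                        sample_id=sid,
                        source_id=source,
                        pool_size=1,
                        platform=platform,
                        group=group,
                        replicate_index=0,
                    )
    return _assemble(columns, meta, config.n_taxa)
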