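import numpy as np
import pytest

from ampliconrep.simulate import (
    CommunityProfile,
    SimulationConfig,
    make_community,
    pool_replicates,
    sequence_sample,
    simulate_experiment,
    simulate_pcr,
)


@pytest.fixture
def small_config():
    return SimulationConfig(
        n_taxa=40,
        template_molecules=5000,
        depth_by_platform={"454": 300, "illumina": 3000},
        seed=11,
    )


class TestMakeCommunity:
    def test_single_taxon(self):
        cfg = SimulationConfig(n_taxa=1)
        assert make_community(cfg).abundance.tolist() == [1.0]

    def test_degenerate_lognormal_is_uniform(self):
        cfg = SimulationConfig(n_taxa=8)
        comm = make_community(cfg, sigma_ln=0.0)
        assert np.allclose(comm.abundance, 1 / 8)

    def test_normalized_sorted_and_deterministic(self):
        cfg = SimulationConfig(n_taxa=100, seed=3)
        a = make_community(cfg, seed=5)
        b = make_community(cfg, seed=5)
        assert np.array_equal(a.abundance, b.abundance)
        assert a.abundance.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(a.abundance) <= 0)

    def test_geometric_model(self):
        cfg = SimulationConfig(n_taxa=5, abundance_model="geometric", geometric_theta=0.5)
        comm = make_community(cfg)
        ratios = comm.abundance[1:] / comm.abundance[:-1]
        assert np.allclose(ratios, 0.5)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_taxa=0)
        with pytest.raises(ValueError):
            SimulationConfig(abundance_model="zipf")
        with pytest.raises(ValueError):
            SimulationConfig(stochastic_cycles=31, cycles=30)
        with pytest.raises(ValueError):
            SimulationConfig(error_rate=1.0)


class TestSimulatePcr:
    def test_deterministic_branch_closed_form(self, small_config):
        """With no stochastic cycles the product is exactly the template draw
        scaled by (1+e_i)^cycles."""
        cfg = SimulationConfig(
            n_taxa=40, template_molecules=5000, stochastic_cycles=0, seed=11
        )
        comm = make_community(cfg, seed=2)
        rng = np.random.default_rng(99)
        eff = rng.uniform(0.5, 1.0, size=40)
        out = simulate_pcr(comm, cfg, eff, seed=123)
        templates = np.random.default_rng(123).multinomial(5000, comm.abundance)
        expected = templates * (1 + eff) ** 30
        assert np.allclose(out.abundance, expected / expected.sum(), atol=1e-12)

    def test_absent_taxon_stays_absent(self, small_config):
        comm = CommunityProfile([f"t{i}" for i in range(3)], np.array([0.5, 0.5, 0.0]))
        out = simulate_pcr(comm, small_config, np.array([0.8, 0.8, 0.8]), seed=0)
        assert out.abundance[2] == 0.0

    def test_equal_efficiency_recovers_input_in_expectation(self):
        """With equal efficiencies and many templates, the mean product
        profile matches the input within 3 SE per taxon."""
        cfg = SimulationConfig(n_taxa=12, template_molecules=10_000, seed=0)
        comm = make_community(cfg, seed=7, sigma_ln=1.0)
        eff = np.full(12, 0.8)
        reps = 400
        draws = np.stack(
            [simulate_pcr(comm, cfg, eff, seed=s).abundance for s in range(reps)]
        )
        se = draws.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(draws.mean(axis=0) - comm.abundance) <= 3 * se + 1e-7)

    def test_rejects_bad_efficiencies(self, small_config):
        comm = make_community(small_config)
        with pytest.raises(ValueError):
            simulate_pcr(comm, small_config, np.full(40, 1.5), seed=0)


class TestPoolReplicates:
    def test_identical_profiles_fixed_point(self):
        p = CommunityProfile(["a", "b"], np.array([0.3, 0.7]))
        pooled = pool_replicates([p, p, p])
        assert np.allclose(pooled.abundance, p.abundance)

    def test_degenerate_weights_select_first(self):
        p1 = CommunityProfile(["a", "b"], np.array([0.3, 0.7]))
        p2 = CommunityProfile(["a", "b"], np.array([0.9, 0.1]))
        pooled = pool_replicates([p1, p2], weights=np.array([1.0, 0.0]))
        assert np.allclose(pooled.abundance, p1.abundance)

    def test_mismatched_taxa_rejected(self):
        p1 = CommunityProfile(["a", "b"], np.array([0.5, 0.5]))
        p2 = CommunityProfile(["a", "c"], np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            pool_replicates([p1, p2])

    def test_pooling_variance_scales_inversely_with_k(self):
        """The variance of pooled composition across reaction sets falls like
        1/k: log-variance vs log-k has slope -1 (iid averaging)."""
        cfg = SimulationConfig(n_taxa=20, template_molecules=300, seed=0)
        comm = make_community(cfg, seed=1, sigma_ln=1.0)
        eff = np.full(20, 0.8)
        ks = [1, 4, 16]
        seeds = 300
        variances = []
        for k in ks:
            tops = []
            for s in range(seeds):
                profiles = [
                    simulate_pcr(comm, cfg, eff, seed=s * 100 + r) for r in range(k)
                ]
                tops.append(pool_replicates(profiles).abundance[0])
            variances.append(np.var(tops, ddof=1))
        slope = np.polyfit(np.log(ks), np.log(variances), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)


class TestSequenceSample:
    def test_pure_multinomial_when_no_error(self, small_config):
        cfg = SimulationConfig(
            n_taxa=40, error_rate=0.0, depth_by_platform={"454": 300}, seed=11
        )
        comm = make_community(cfg, seed=1)
        reads = sequence_sample(comm, "454", cfg, seed=5)
        assert int(reads.sum()) == 300
        assert not any(str(i).startswith("ERR_") for i in reads.index)

    def test_spurious_read_mean_matches_binomial(self):
        cfg = SimulationConfig(
            n_taxa=30, error_rate=0.02, depth_by_platform={"deep": 20_000}, seed=11
        )
        comm = make_community(cfg, seed=1, sigma_ln=1.0)
        err_totals = []
        for s in range(40):
            reads = sequence_sample(comm, "deep", cfg, seed=s)
            err_totals.append(
                sum(v for k, v in reads.items() if str(k).startswith("ERR_"))
            )
            assert int(reads.sum()) == 20_000
        expected = 20_000 * 0.02
        se = np.sqrt(20_000 * 0.02 * 0.98 / 40)
        assert abs(np.mean(err_totals) - expected) <= 3 * se

    def test_deeper_sequencing_finds_more_spurious_otus(self):
        """Distinct spurious OTUs grow with depth (the mechanism keeping
        presence-based replicate dissimilarity off the floor)."""
        cfg = SimulationConfig(
            n_taxa=30,
            error_rate=0.005,
            depth_by_platform={"d3": 1000, "d4": 10_000, "d5": 100_000},
            seed=11,
        )
        comm = make_community(cfg, seed=1, sigma_ln=1.0)
        means = []
        for plat in ("d3", "d4", "d5"):
            distinct = [
                sum(str(k).startswith("ERR_") for k in sequence_sample(comm, plat, cfg, seed=s).index)
                for s in range(30)
            ]
            means.append(np.mean(distinct))
        assert means[0] < means[1] < means[2]

    def test_detectable_fraction_masks_consistently(self):
        cfg = SimulationConfig(
            n_taxa=50,
            error_rate=0.0,
            depth_by_platform={"p": 5000},
            platform_detectable_fraction={"p": 0.5},
            seed=4,
        )
        comm = make_community(cfg, seed=1, sigma_ln=0.5)
        seen = set()
        for s in range(5):
            reads = sequence_sample(comm, "p", cfg, seed=s)
            seen |= {k for k, v in reads.items() if v > 0}
        assert len(seen) <= 25  # never exceeds the platform's detectable set

    def test_unknown_platform_rejected(self, small_config):
        comm = make_community(small_config)
        with pytest.raises(ValueError):
            sequence_sample(comm, "nanopore", small_config, seed=0)


class TestSimulateExperiment:
    def test_replication_design_bookkeeping(self, small_config):
        table = simulate_experiment(small_config, "replication")
        assert table.n_samples == 3 * 5 * 2
        pools = sorted({m.pool_size for m in table.metadata.values()})
        assert pools == [1, 2, 4, 8, 16]
        assert {m.platform for m in table.metadata.values()} == {"454", "illumina"}
        # every library sums to its platform depth
        for sid, m in table.metadata.items():
            assert table.sample_counts(sid).sum() == small_config.depth_by_platform[m.platform]

    def test_cross_platform_design_bookkeeping(self):
        cfg = SimulationConfig(
            n_taxa=40,
            template_molecules=2000,
            depth_by_platform={"454": 200, "illumina": 2000},
            n_samples_per_site=2,
            seed=1,
        )
        table = simulate_experiment(cfg, "cross_platform")
        assert table.n_samples == 3 * 2 * 2 * 2  # groups x sites x samples x platforms
        groups = {m.group for m in table.metadata.values()}
        assert len(groups) == 3

    def test_identical_seeds_identical_tables(self, small_config):
        t1 = simulate_experiment(small_config, "replication")
        t2 = simulate_experiment(SimulationConfig(**vars(small_config)), "replication")
        assert t1 == t2

    def test_unknown_design_rejected(self, small_config):
        with pytest.raises(ValueError):
            simulate_experiment(small_config, "timecourse")
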