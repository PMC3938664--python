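import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ampliconrep.beta import DistanceMatrix
from ampliconrep.inference import (
    factorial_anova,
    mantel,
    permanova,
    platform_overlap,
)

from conftest import make_table


def random_dm(rng, n, ids=None):
    m = rng.uniform(0.05, 1.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(ids or [f"s{i}" for i in range(n)], np.clip(m, 0, 1), "jaccard")


class TestFactorialAnova:
    def test_one_way_f_equals_t_squared(self):
        """For two balanced groups the one-way F statistic is exactly the
        square of the pooled two-sample t statistic."""
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 10)
        data = pd.DataFrame(
            {"value": np.concatenate([a, b]), "grp": ["a"] * 10 + ["b"] * 10}
        )
        aov = factorial_anova(data, "value ~ grp")
        t, p = sps.ttest_ind(a, b)
        assert aov.f_stat("grp") == pytest.approx(t**2, abs=1e-10)
        assert aov.p_value("grp") == pytest.approx(p, abs=1e-12)

    def test_balanced_two_by_two_hand_decomposition(self):
        """Hand-computed sequential SS for a fixed balanced 2x2 dataset."""
        # cells: A1={10,12} A2={20,22} B1={14,16} B2={32,34}
        data = pd.DataFrame(
            {
                "value": [10.0, 12.0, 20.0, 22.0, 14.0, 16.0, 32.0, 34.0],
                "f1": ["A", "A", "A", "A", "B", "B", "B", "B"],
                "f2": ["x", "x", "y", "y", "x", "x", "y", "y"],
            }
        )
        aov = factorial_anova(data, "value ~ f1 * f2")
        # grand mean 20; f1 means 16 vs 24 -> SS 8*(4^2)/2=128
        # f2 means 13 vs 27 -> SS 8*(7^2)/2=392
        # interaction effects (cell - row - col + grand) = +/-2 -> SS 2*4*4=32
        by_term = {t[0]: t[2] for t in aov.terms}
        assert by_term["f1"] == pytest.approx(128.0, abs=1e-10)
        assert by_term["f2"] == pytest.approx(392.0, abs=1e-10)
        assert by_term["f1:f2"] == pytest.approx(32.0, abs=1e-10)
        assert aov.residual_sum_sq == pytest.approx(8.0, abs=1e-10)  # 4 cells * 2*(1)^2
        assert aov.residual_df == 4

    def test_constant_response_degenerates_gracefully(self):
        data = pd.DataFrame({"value": [3.0] * 8, "grp": list("aabbccdd")})
        aov = factorial_anova(data, "value ~ grp")
        assert all(t[3] == 0.0 and t[4] == 1.0 for t in aov.terms)

    def test_aliased_design_rejected_with_name(self):
        data = pd.DataFrame(
            {
                "value": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "f1": ["a", "a", "a", "b", "b", "b"],
                "f2": ["x", "x", "x", "y", "y", "y"],  # perfectly aliased with f1
            }
        )
        with pytest.raises(ValueError, match="rank deficient"):
            factorial_anova(data, "value ~ f1 + f2")

    def test_too_few_observations_rejected(self):
        data = pd.DataFrame({"value": [1.0, 2.0], "grp": ["a", "b"]})
        with pytest.raises(ValueError):
            factorial_anova(data, "value ~ grp")


class TestMantel:
    def test_self_correlation_is_one(self):
        d = random_dm(np.random.default_rng(0), 8)
        res = mantel(d, d, n_permutations=99, seed=1)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value >= 1 / 100

    def test_p_floor(self):
        rng = np.random.default_rng(2)
        d1 = random_dm(rng, 10)
        d2 = DistanceMatrix(d1.sample_ids, np.clip(d1.values * 0.9, 0, 1), "jaccard")
        res = mantel(d1, d2, n_permutations=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_mismatched_ids_rejected(self):
        rng = np.random.default_rng(3)
        d1 = random_dm(rng, 5, ids=list("abcde"))
        d2 = random_dm(rng, 5, ids=list("abcdX"))
        with pytest.raises(ValueError):
            mantel(d1, d2, 99, 0)

    def test_statistic_matches_skbio(self):
        """scikit-bio's independent Mantel implementation must produce the
        same correlation statistic."""
        import skbio

        rng = np.random.default_rng(4)
        d1, d2 = random_dm(rng, 9), random_dm(rng, 9)
        ours = mantel(d1, d2, 99, 0)
        r, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(d1.values, d1.sample_ids),
            skbio.DistanceMatrix(d2.values, d2.sample_ids),
            permutations=0,
        )
        assert ours.statistic == pytest.approx(r, abs=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        d1, d2 = random_dm(rng, 8), random_dm(rng, 8)
        a = mantel(d1, d2, 199, seed=7)
        b = mantel(d1, d2, 199, seed=7)
        assert (a.statistic, a.p_value) == (b.statistic, b.p_value)


def brute_force_pseudo_f(values, labels):
    """Literal double-loop partition of squared dissimilarities."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += values[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        acc = 0.0
        for i, j in itertools.combinations(idx, 2):
            acc += values[i, j] ** 2
        ss_within += acc / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    return (ss_between / (a - 1)) / (ss_within / (n - a)), ss_between / ss_total


class TestPermanova:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        labels = ["a", "a", "a", "b", "b", "b"]
        for _ in range(10):
            d = random_dm(rng, 6)
            res = permanova(d, labels, n_permutations=99, seed=0)
            f_ref, r2_ref = brute_force_pseudo_f(d.values, labels)
            assert res.statistic == pytest.approx(f_ref, abs=1e-10)
            assert res.r_squared == pytest.approx(r2_ref, abs=1e-10)

    def test_matches_skbio_pseudo_f(self):
        import skbio

        rng = np.random.default_rng(7)
        d = random_dm(rng, 9)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        ours = permanova(d, labels, 99, 0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values, d.sample_ids), labels, permutations=9
        )
        assert ours.statistic == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_perfect_separation_small_p(self):
        """Duplicated identical samples per group with between-group distance
        1: SS_within is 0, the pseudo-F is infinite and only the rare
        partition-preserving permutations tie it, so p sits near its floor
        (2 of C(8,4) label partitions preserve the split)."""
        n = 8
        v = np.ones((n, n))
        v[:4, :4] = 0.0
        v[4:, 4:] = 0.0
        np.fill_diagonal(v, 0.0)
        d = DistanceMatrix([f"s{i}" for i in range(n)], v, "jaccard")
        res = permanova(d, ["g1"] * 4 + ["g2"] * 4, n_permutations=199, seed=0)
        assert np.isinf(res.statistic)
        assert res.p_value <= 0.06  # ~1/35 expected tie rate plus the floor

    def test_singleton_group_rejected(self):
        d = random_dm(np.random.default_rng(8), 5)
        with pytest.raises(ValueError, match="too small"):
            permanova(d, ["a", "a", "a", "a", "b"], 99, 0)

    def test_deterministic_and_stable_under_more_permutations(self):
        rng = np.random.default_rng(9)
        d = random_dm(rng, 12)
        labels = ["a"] * 6 + ["b"] * 6
        p1 = permanova(d, labels, 199, seed=3).p_value
        p1_again = permanova(d, labels, 199, seed=3).p_value
        p2 = permanova(d, labels, 399, seed=3).p_value
        assert p1 == p1_again
        assert abs(p1 - p2) < 0.15  # Monte-Carlo wobble only


class TestPlatformOverlap:
    def test_three_otu_partition(self):
        table = make_table(
            [[1, 0, 2], [0, 3, 1]],
            meta=[("x", 1, "454", "g"), ("y", 1, "illumina", "g")],
        )
        ov = platform_overlap(table)
        assert (ov.shared, ov.unique_a, ov.unique_b) == (1, 1, 1)

    def test_all_shared(self):
        table = make_table(
            [[1, 1], [2, 2]], meta=[("x", 1, "454", "g"), ("y", 1, "illumina", "g")]
        )
        ov = platform_overlap(table)
        assert ov.unique_a == ov.unique_b == 0 and ov.shared == 2

    def test_partition_sums_to_total(self):
        rng = np.random.default_rng(10)
        counts = rng.integers(0, 3, size=(6, 40))
        meta = [("s", 1, "454" if i < 3 else "illumina", "g") for i in range(6)]
        table = make_table(counts, meta=meta)
        ov = platform_overlap(table)
        observed = int(np.count_nonzero(counts.any(axis=0)))
        assert ov.total == observed

    def test_requires_exactly_two_platforms(self):
        table = make_table([[1], [1]], meta=[("x", 1, "454", "g"), ("y", 1, "454", "g")])
        with pytest.raises(ValueError, match="2 platforms"):
            platform_overlap(table)
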