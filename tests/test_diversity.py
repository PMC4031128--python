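import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microsel.diversity import (
    DistanceMatrix,
    alpha_metrics,
    anosim,
    bray_curtis,
    group_ttest,
    prevalence_ci,
    rarefaction_curve,
    rarefy,
    read_distance_tsv,
    write_distance_tsv,
)
from microsel.exceptions import InputError
from microsel.io import CountTable

from .oracles import expected_rarefied_richness, pooled_ttest


def table_from(counts):
    counts = np.atleast_2d(np.asarray(counts))
    n, p = counts.shape
    return CountTable([f"S{i}" for i in range(n)],
                      [f"O{j}" for j in range(p)], counts)


class TestAlphaMetrics:
    def test_uniform_four_species_shannon_two(self):
        assert alpha_metrics(np.array([5, 5, 5, 5]), "shannon") == pytest.approx(2.0)

    def test_single_species(self):
        assert alpha_metrics(np.array([10, 0, 0]), "shannon") == 0.0
        assert alpha_metrics(np.array([10, 0, 0]), "observed_otus") == 1

    def test_shannon_75_25(self):
        expected = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert alpha_metrics(np.array([75, 25]), "shannon") == \
            pytest.approx(expected, abs=1e-12)
        assert round(alpha_metrics(np.array([75, 25]), "shannon"), 4) == 0.8113

    def test_all_zero_errors(self):
        with pytest.raises(InputError):
            alpha_metrics(np.zeros(3, dtype=int), "shannon")

    def test_natural_log_flag(self):
        assert alpha_metrics(np.array([1, 1]), "shannon", base=np.e) == \
            pytest.approx(np.log(2))

    @given(st.lists(st.integers(1, 100), min_size=2, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_shannon_maximal_at_uniform(self, counts):
        richness = len(counts)
        uniform = alpha_metrics(np.full(richness, 10), "shannon")
        assert alpha_metrics(np.array(counts), "shannon") <= uniform + 1e-9


class TestRarefy:
    def test_full_depth_identity(self):
        counts = np.array([6, 3, 1])
        assert np.array_equal(rarefy(counts, 10, seed=0), counts)

    def test_zero_depth(self):
        assert np.array_equal(rarefy(np.array([4, 2]), 0, seed=0),
                              np.zeros(2, dtype=np.int64))

    def test_depth_exceeds_total_errors(self):
        with pytest.raises(InputError, match="exceeds"):
            rarefy(np.array([1, 1]), 5, seed=0)

    def test_sum_is_exactly_depth(self):
        rng = np.random.default_rng(0)
        counts = np.array([50, 30, 10, 5, 5])
        for depth in (1, 17, 60, 99):
            assert rarefy(counts, depth, rng).sum() == depth

    def test_expected_richness_matches_hypergeometric_oracle(self):
        counts = np.array([6, 3, 1])
        depth = 5
        expected = expected_rarefied_richness(counts, depth)
        rng = np.random.default_rng(12)
        n_iter = 20000
        obs = np.array([
            np.count_nonzero(rarefy(counts, depth, rng))
            for _ in range(n_iter)
        ])
        se = obs.std(ddof=1) / np.sqrt(n_iter)
        assert abs(obs.mean() - expected) <= 4 * se


class TestRarefactionCurve:
    def test_single_iteration_full_depth_equals_metric(self):
        table = table_from([[10, 5, 5], [8, 8, 4]])
        curve = rarefaction_curve(table, depths=[20], iterations=1,
                                  metric="shannon", seed=0)
        for i in range(2):
            assert curve.means[i, 0] == pytest.approx(
                alpha_metrics(table.counts[i], "shannon"))

    def test_richness_nondecreasing_in_depth(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 40, size=(3, 30))
        counts[:, 0] += 5
        table = table_from(counts)
        min_total = table.counts.sum(axis=1).min()
        depths = [int(min_total * f) for f in (0.2, 0.5, 0.8, 1.0)]
        curve = rarefaction_curve(table, depths=depths, iterations=25,
                                  metric="observed_otus", seed=2)
        for i in range(3):
            assert np.all(np.diff(curve.means[i]) >= -0.5)  # MC tolerance

    def test_deterministic_under_seed(self):
        table = table_from([[10, 5, 5], [8, 8, 4]])
        c1 = rarefaction_curve(table, [10, 20], iterations=5, seed=3)
        c2 = rarefaction_curve(table, [10, 20], iterations=5, seed=3)
        assert np.array_equal(c1.means, c2.means)
        assert np.array_equal(c1.sds, c2.sds)

    def test_invalid_depth_names_sample(self):
        table = table_from([[10, 5], [2, 1]])
        with pytest.raises(InputError, match="S1"):
            rarefaction_curve(table, depths=[10], iterations=1, seed=0)


class TestGroupTtest:
    def test_identical_groups(self):
        t, p = group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_constant_equal_groups(self):
        t, p = group_ttest([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_separated_groups_significant(self):
        a = np.array([0.0, 0.001, -0.001, 0.0005])
        b = np.array([1.0, 1.001, 0.999, 1.0005])
        t, p = group_ttest(a, b)
        assert p < 0.01
        t_o, p_o = pooled_ttest(a, b)
        assert t == pytest.approx(t_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_antisymmetry(self):
        a = [1.0, 2.0, 4.0]
        b = [2.0, 3.0, 7.0]
        t1, p1 = group_ttest(a, b)
        t2, p2 = group_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_too_small_group_errors(self):
        with pytest.raises(InputError):
            group_ttest([1.0], [1.0, 2.0])


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        D = bray_curtis(table_from([[3, 2, 1], [3, 2, 1]]))
        assert D.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        D = bray_curtis(table_from([[5, 0], [0, 7]]))
        assert D.values[0, 1] == pytest.approx(1.0)

    def test_formula_example(self):
        D = bray_curtis(table_from([[2, 2], [2, 0]]))
        assert D.values[0, 1] == pytest.approx(1.0 / 3.0)

    @given(st.lists(st.lists(st.integers(0, 50), min_size=4, max_size=4),
                    min_size=3, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_bounds_symmetry(self, rows):
        rows = [r if sum(r) > 0 else [1] + r[1:] for r in rows]
        D = bray_curtis(table_from(rows))
        assert np.all(D.values >= -1e-12) and np.all(D.values <= 1 + 1e-12)
        assert np.allclose(D.values, D.values.T)
        assert np.all(np.diag(D.values) == 0)


class TestAnosim:
    def _separated(self):
        # two tight clusters far apart
        counts = np.array([[100, 0, 1], [99, 1, 1], [98, 2, 1],
                           [0, 100, 1], [1, 99, 1], [2, 98, 1]])
        return bray_curtis(table_from(counts)), ["A"] * 3 + ["B"] * 3

    def test_perfect_separation_r_one(self):
        D, labels = self._separated()
        r, _ = anosim(D, labels, permutations=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_perfect_separation_p_add_one_rule(self):
        D, labels = self._separated()
        r, p = anosim(D, labels, permutations=999, seed=0)
        # permuted R can only reach the observed 1.0 through rank ties
        assert p <= (1 + 200) / 1000
        assert p >= 1 / 1000

    def test_r_in_range_and_perm_mean_near_zero(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 50, size=(12, 8))
        D = bray_curtis(table_from(counts))
        rs = []
        for seed in range(40):
            labels = rng.permutation(["A"] * 6 + ["B"] * 6).tolist()
            r, _ = anosim(D, labels, permutations=9, seed=seed)
            rs.append(r)
            assert -1 - 1e-9 <= r <= 1 + 1e-9
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) <= 4 * se + 0.05

    def test_matches_skbio_reference(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(6)
        counts = rng.integers(1, 60, size=(10, 6))
        D = bray_curtis(table_from(counts))
        labels = ["A"] * 5 + ["B"] * 5
        r, _ = anosim(D, labels, permutations=9, seed=0)
        dm = skbio.DistanceMatrix(D.values, ids=D.sample_ids)
        res = skbio_anosim(dm, grouping=labels, permutations=9)
        assert r == pytest.approx(float(res["test statistic"]), abs=1e-12)

    def test_degenerate_grouping_errors(self):
        D, labels = self._separated()
        with pytest.raises(InputError):
            anosim(D, ["A"] * 5 + ["B"], permutations=9, seed=0)


class TestPrevalenceCI:
    @pytest.mark.parametrize(
        "x,n,percent,lo,hi",
        [
            (30, 51, 58.8, 45.3, 72.3),
            (11, 51, 21.6, 10.3, 32.9),
            (0, 51, 0.0, 0.0, 0.0),
        ],
    )
    def test_examples(self, x, n, percent, lo, hi):
        est = prevalence_ci(x, n)
        assert (est.percent, est.ci_low, est.ci_high) == (percent, lo, hi)

    def test_bounds_ordering(self):
        for x in range(0, 52):
            est = prevalence_ci(x, 51)
            assert 0 <= est.ci_low <= est.percent <= est.ci_high <= 100

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            prevalence_ci(-1, 10)
        with pytest.raises(InputError):
            prevalence_ci(11, 10)
        with pytest.raises(InputError):
            prevalence_ci(0, 0)


class TestDistanceIO:
    def test_round_trip(self, tmp_path):
        D = bray_curtis(table_from([[3, 1, 0], [1, 1, 1], [0, 0, 9]]))
        path = tmp_path / "dist.tsv"
        write_distance_tsv(D, str(path))
        again = read_distance_tsv(str(path))
        assert again.sample_ids == D.sample_ids
        assert np.allclose(again.values, D.values, atol=1e-9)

    def test_mismatched_ids_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("\tA\tB\nA\t0\t1\nC\t1\t0\n")
        with pytest.raises(InputError):
            read_distance_tsv(str(path))

    def test_asymmetric_rejected(self):
        with pytest.raises(InputError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
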