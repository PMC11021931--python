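import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import brute_force_u, exact_rank_permutation_p
from sticklediv.divergence import (
    DivergenceTrajectory,
    MultivariateDivergence,
    TrajectoryPoint,
    bootstrap_d,
    cles,
    compare_d_distributions,
    divergence_report,
    divergence_trajectory,
    euclidean_d,
    first_overlap_time,
    mean_vector,
    permutation_test_d,
    trait_divergence_table,
    trait_mean_correlations,
    wilcoxon_u,
)
from sticklediv.reference import KSERIES_TRAIT_TESTS
from sticklediv.synthetic_data import default_fossil_params, generate_fossil_series


class TestWilcoxonU:
    def test_complete_separation(self):
        u, _ = wilcoxon_u([3.0, 4.0], [1.0, 2.0])
        assert u == 0.0

    def test_interleaved_pairs(self):
        u, _ = wilcoxon_u([1.0, 3.0], [2.0, 4.0])
        assert u == 3.0  # pairs 2>1, 4>1, 4>3

    def test_identical_multisets(self):
        vals = [1.0, 2.0, 2.0, 5.0]
        u, p = wilcoxon_u(vals, vals)
        assert u == len(vals) ** 2 / 2
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError, match="non-missing"):
            wilcoxon_u([], [1.0])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=6),
        st.lists(st.integers(0, 8), min_size=1, max_size=6),
    )
    def test_u_matches_brute_force_pair_count(self, first, last):
        first = np.array(first, dtype=float)
        last = np.array(last, dtype=float)
        u, _ = wilcoxon_u(first, last)
        assert u == pytest.approx(brute_force_u(first, last), abs=1e-9)

    def test_p_close_to_exact_permutation_null_small_samples(self):
        """Normal-approximation p within 0.05 of the exact permutation p for
        pooled samples of at most 12 values (including ties)."""
        # tie-free fixtures: with heavy ties in tiny samples the normal
        # approximation and the exact null genuinely differ by more than 0.05
        rng = np.random.default_rng(2024)
        for _ in range(60):
            n1 = int(rng.integers(3, 7))
            n2 = int(rng.integers(3, 13 - n1))
            first = rng.normal(0, 1, n1)
            last = rng.normal(rng.uniform(-1.5, 1.5), 1, n2)
            # force the asymptotic path even where exact would be used
            res = stats.mannwhitneyu(
                last, first, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            )
            p_exact = exact_rank_permutation_p(first, last)
            assert abs(float(res.pvalue) - p_exact) < 0.05


class TestCles:
    @pytest.mark.parametrize("row", KSERIES_TRAIT_TESTS, ids=lambda r: r.code)
    def test_identity_on_published_rows(self, row):
        """U = CLES * n_first * n_last for every published trait row."""
        effect = cles(row.u_statistic, row.n_first, row.n_last)
        assert effect * row.n_first * row.n_last == pytest.approx(row.u_statistic, abs=1e-9)
        assert round(effect, 2) == pytest.approx(row.cles, abs=1e-12)

    def test_bounds(self):
        assert cles(0, 4, 5) == 0.0
        assert cles(20, 4, 5) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            cles(21, 4, 5)


class TestTraitDivergenceTable:
    def test_null_comparison_of_identical_groups(self, make_table):
        rng = np.random.default_rng(3)
        vals = np.abs(rng.normal(10, 2, 30))
        table = make_table({"g1": {"stl": vals}, "g2": {"stl": vals.copy()}})
        tt = trait_divergence_table(table, "g1", "g2")
        row = next(r for r in tt.rows if r.trait == "stl")
        assert row.effect_size == pytest.approx(0.5)
        assert not row.significant
        assert tt.n_significant == 0

    def test_family_alpha_is_bonferroni(self, make_table):
        table = make_table({"g1": {"stl": [1.0, 2.0]}, "g2": {"stl": [1.5, 2.5]}})
        tt = trait_divergence_table(table, "g1", "g2", alpha_total=0.05)
        assert tt.alpha_family == pytest.approx(0.05 / 16)

    def test_separated_trait_significant_with_cles_zero(self, make_table):
        rng = np.random.default_rng(4)
        table = make_table(
            {"g1": {"stl": np.abs(rng.normal(50, 1, 40))},
             "g2": {"stl": np.abs(rng.normal(20, 1, 40))}}
        )
        tt = trait_divergence_table(table, "g1", "g2")
        row = next(r for r in tt.rows if r.trait == "stl")
        assert row.significant
        assert row.effect_size == 0.0
        assert row.mean_diff == pytest.approx(-30.0, abs=1.5)

    def test_sparse_trait_flagged_untestable(self, make_table):
        table = make_table(
            {"g1": {"stl": [30.0, 31.0], "mds": [2.0, np.nan]},
             "g2": {"stl": [30.0, 31.0], "mds": [1.0, 1.0]}}
        )
        tt = trait_divergence_table(table, "g1", "g2")
        row = next(r for r in tt.rows if r.trait == "mds")
        assert not row.testable and not row.significant


class TestEuclideanD:
    @pytest.mark.parametrize(
        "v1,v2,expected",
        [(((0.0, 0.0)), ((3.0, 4.0)), 5.0),
         (((1.0, 2.0, 2.0)), ((0.0, 0.0, 0.0)), 3.0),
         (((2.0, 7.0)), ((2.0, 7.0)), 0.0)],
    )
    def test_known_distances(self, v1, v2, expected):
        assert euclidean_d(np.array(v1), np.array(v2)) == expected

    def test_missing_entries_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            euclidean_d(np.array([1.0, np.nan]), np.array([0.0, 0.0]))


class TestMeanVector:
    def test_identical_specimens(self, make_table):
        table = make_table({"g1": {"stl": [30.0, 30.0], "mds": [2.0, 2.0]}})
        v = mean_vector(table, "g1", ("stl", "mds"))
        np.testing.assert_allclose(v, [30.0, 2.0])

    def test_traitwise_missingness(self, make_table):
        table = make_table({"g1": {"stl": [30.0, np.nan, 40.0], "mds": [2.0, 3.0, np.nan]}})
        v = mean_vector(table, "g1", ("stl", "mds"))
        np.testing.assert_allclose(v, [35.0, 2.5])

    def test_all_missing_trait_rejected(self, make_table):
        table = make_table({"g1": {"stl": [30.0, 40.0]}})
        with pytest.raises(ValueError, match="mds.*g1"):
            mean_vector(table, "g1", ("stl", "mds"))


class TestBootstrapD:
    def _two_group_table(self, make_table, seed=0, n=40, shift=5.0):
        rng = np.random.default_rng(seed)
        return make_table(
            {"g1": {"stl": np.abs(rng.normal(40, 3, n)), "mds": rng.integers(2, 4, n)},
             "g2": {"stl": np.abs(rng.normal(40 - shift, 3, n)), "mds": rng.integers(0, 2, n)}}
        )

    def test_point_d_within_three_boot_sd(self, make_table):
        table = self._two_group_table(make_table)
        res = bootstrap_d(table, "g1", "g2", seed=1, traits=("stl", "mds"))
        assert res.boot_sd > 0
        assert abs(res.d - res.boot_mean) < 3 * res.boot_sd

    def test_same_group_small_positive_bias(self, make_table):
        table = self._two_group_table(make_table, shift=0.0)
        res = bootstrap_d(table, "g1", "g1", seed=2, traits=("stl", "mds"))
        assert all(v >= 0 for v in res.boot_values)
        assert res.boot_mean < 3.0  # concentrated near small positive values

    def test_determinism(self, make_table):
        table = self._two_group_table(make_table)
        r1 = bootstrap_d(table, "g1", "g2", seed=3, traits=("stl", "mds"))
        r2 = bootstrap_d(table, "g1", "g2", seed=3, traits=("stl", "mds"))
        assert r1.boot_values == r2.boot_values

    def test_boot_sd_shrinks_with_sample_size(self, make_table):
        """Quadrupling group sizes should roughly halve the bootstrap s.d."""
        small = self._two_group_table(make_table, seed=5, n=30)
        big = self._two_group_table(make_table, seed=5, n=120)
        sd_small = bootstrap_d(small, "g1", "g2", seed=6, traits=("stl", "mds")).boot_sd
        sd_big = bootstrap_d(big, "g1", "g2", seed=6, traits=("stl", "mds")).boot_sd
        assert sd_big < sd_small
        assert sd_small / sd_big == pytest.approx(2.0, rel=0.5)


class TestPermutationD:
    def test_separated_groups_min_p(self, make_table):
        rng = np.random.default_rng(0)
        table = make_table(
            {"g1": {"stl": np.abs(rng.normal(60, 1, 30))},
             "g2": {"stl": np.abs(rng.normal(20, 1, 30))}}
        )
        p, perms = permutation_test_d(table, "g1", "g2", P=99, seed=1, traits=("stl",))
        assert p == pytest.approx(0.01)
        assert len(perms) == 99

    def test_determinism(self, make_table):
        rng = np.random.default_rng(1)
        table = make_table(
            {"g1": {"stl": np.abs(rng.normal(40, 3, 20))},
             "g2": {"stl": np.abs(rng.normal(41, 3, 20))}}
        )
        p1, v1 = permutation_test_d(table, "g1", "g2", seed=7, traits=("stl",))
        p2, v2 = permutation_test_d(table, "g1", "g2", seed=7, traits=("stl",))
        assert p1 == p2 and v1 == v2


class TestWelch:
    def test_hand_computed_three_vs_three(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 9.0])
        t, df, p = compare_d_distributions(a, b)
        # textbook Welch formulas
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_hand = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert df == pytest.approx(df_hand, rel=1e-12)
        assert 0 < p < 1

    def test_equal_distributions_df_near_maximum(self):
        rng = np.random.default_rng(8)
        a = rng.normal(10, 1, 99)
        b = rng.normal(10, 1, 99)
        t, df, p = compare_d_distributions(a, b)
        assert df <= 196
        assert df > 150
        assert abs(t) < 3

    def test_separated_distributions(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 99)
        b = rng.normal(30, 1, 99)
        _, _, p = compare_d_distributions(a, b)
        assert p < 1e-4


class TestTrajectory:
    def test_entry_count(self):
        table, _ = generate_fossil_series(default_fossil_params(seed=21))
        traj = divergence_trajectory(table, B=25, seed=1)
        assert len(traj.points) == 17
        ages = [p.age_years for p in traj.points]
        assert all(b > a for a, b in zip(ages, ages[1:]))
        assert traj.points[0].generations == pytest.approx(traj.points[0].age_years / 2)

    def test_monotone_series_gives_increasing_d(self):
        """Averaged over seeds, d from the first sample increases through a
        monotone-reduction series."""
        curves = []
        for seed in range(8):
            params = default_fossil_params(seed=seed, n_samples=8)
            table, _ = generate_fossil_series(params)
            traj = divergence_trajectory(table, B=10, seed=seed)
            curves.append([p.d for p in traj.points])
        mean_curve = np.mean(curves, axis=0)
        rho = stats.spearmanr(mean_curve, np.arange(mean_curve.size)).statistic
        assert rho > 0.95

    def test_stationary_series_shows_no_trend(self):
        params = default_fossil_params(seed=3, n_samples=8)
        trajectories = {
            c: replace(t, end_mean=t.start_mean, lag_years=0.0)
            for c, t in params.trait_trajectories.items()
        }
        params = replace(params, trait_trajectories=trajectories)
        slopes = []
        for seed in range(6):
            table, _ = generate_fossil_series(replace(params, seed=seed))
            traj = divergence_trajectory(table, B=10, seed=seed)
            d = [p.d for p in traj.points]
            ages = [p.age_years for p in traj.points]
            slopes.append(stats.linregress(ages, d).slope)
        # mean slope indistinguishable from zero at the d scale (units/year)
        assert abs(np.mean(slopes)) < 1e-4


class TestFirstOverlap:
    def _traj(self, boot_means, boot_sd=0.5):
        points = tuple(
            TrajectoryPoint(
                group=f"K{k+2:02d}", age_years=1000.0 * (k + 1),
                generations=500.0 * (k + 1), d=m, boot_mean=m, boot_sd=boot_sd,
            )
            for k, m in enumerate(boot_means)
        )
        return DivergenceTrajectory(points, "K01", ("stl",))

    def _ref(self, mean, sd, values=()):
        return MultivariateDivergence(
            d=mean, boot_values=tuple(values), boot_mean=mean, boot_sd=sd
        )

    def test_crossing_at_known_entry(self):
        traj = self._traj([1.0, 3.0, 6.0, 9.0])
        age, gens = first_overlap_time(traj, self._ref(7.0, 0.5))
        assert age == 3000.0  # entry 3: 6 +/- 0.5 meets 7 +/- 0.5
        assert gens == 1500.0

    def test_never_overlapping(self):
        traj = self._traj([1.0, 2.0, 3.0])
        age, gens = first_overlap_time(traj, self._ref(50.0, 1.0))
        assert age is None and gens is None

    def test_zero_sd_reference_is_point_test(self):
        traj = self._traj([1.0, 5.0], boot_sd=0.5)
        age, _ = first_overlap_time(traj, self._ref(5.2, 0.0))
        assert age == 2000.0

    def test_range_criterion_uses_bootstrap_range(self):
        traj = self._traj([1.0, 4.0, 8.0])
        ref = self._ref(5.0, 0.1, values=(3.5, 4.5, 5.0))
        age, _ = first_overlap_time(traj, ref, criterion="range")
        assert age == 2000.0

    def test_unknown_criterion_rejected(self):
        traj = self._traj([1.0])
        with pytest.raises(ValueError, match="criterion"):
            first_overlap_time(traj, self._ref(1.0, 1.0), criterion="banana")


class TestTraitMeanCorrelations:
    def test_exact_linear_relationships(self, make_table):
        groups = {
            f"g{k}": {"stl": [30.0 + k] * 3, "lps.sc": [8.0 - 0.5 * k] * 3,
                      "ect.sc": [2.0 + 0.25 * k] * 3}
            for k in range(4)
        }
        # remaining traits constant: their correlations are undefined and
        # must be excluded from the off-diagonal summary
        table = make_table(groups, dataset="fossil", fill=2.0)
        summary = trait_mean_correlations(table, list(groups))
        i = summary.traits.index("stl")
        j = summary.traits.index("lps.sc")
        k = summary.traits.index("ect.sc")
        # stl increases while lps.sc decreases linearly -> r = -1
        assert summary.matrix[i][j] == pytest.approx(-1.0)
        # two increasing linear trends -> r = +1
        assert summary.matrix[i][k] == pytest.approx(1.0)
        assert summary.matrix[i][i] == 1.0

    def test_synthetic_series_shows_correlated_reduction(self):
        table, _ = generate_fossil_series(default_fossil_params(seed=17))
        summary = trait_mean_correlations(table)
        assert summary.offdiag_mean > 0
        k = len(summary.traits)
        offdiag = [
            summary.matrix[i][j] for i in range(k) for j in range(k) if i != j
        ]
        assert len(offdiag) == 240  # 120 unordered pairs for 16 traits
        # symmetry
        mat = np.array(summary.matrix)
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)


def test_divergence_report_combines_boot_and_perm(make_table):
    rng = np.random.default_rng(12)
    table = make_table(
        {"g1": {"stl": np.abs(rng.normal(50, 2, 25))},
         "g2": {"stl": np.abs(rng.normal(30, 2, 25))}}
    )
    rep = divergence_report(table, "g1", "g2", B=25, P=25, seed=4, traits=("stl",))
    assert len(rep.boot_values) == 25
    assert len(rep.perm_values) == 25
    assert rep.perm_p == pytest.approx(1 / 26)
    assert rep.d == pytest.approx(20.0, abs=2.0)


def test_drop_trait_excludes_coordinate(make_table):
    rng = np.random.default_rng(13)
    table = make_table(
        {"g1": {"stl": np.abs(rng.normal(50, 2, 25)), "mds": np.full(25, 3.0)},
         "g2": {"stl": np.abs(rng.normal(30, 2, 25)), "mds": np.full(25, 1.0)}}
    )
    full = divergence_report(table, "g1", "g2", B=9, P=9, seed=1, traits=("stl", "mds"))
    dropped = divergence_report(
        table, "g1", "g2", B=9, P=9, seed=1, traits=("stl", "mds"), drop_traits=("stl",)
    )
    assert dropped.traits_used == ("mds",)
    # removing the large-scale coordinate removes most of d
    assert dropped.d == pytest.approx(2.0, abs=0.2)
    assert full.d > dropped.d
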