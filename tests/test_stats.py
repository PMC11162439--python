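"""Test battery: trend/rank tests against enumeration oracles, speed relations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from flumetrack import stats


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra


class TestJonckheereTerpstra:
    def test_fully_ordered_data_attains_maximum(self):
        res = stats.jonckheere_terpstra([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == 12  # sum over pairs of n_i * n_j
        assert res.p < 0.05

    def test_all_ties_centres_the_statistic(self):
        res = stats.jonckheere_terpstra([[5, 5], [5, 5], [5, 5]])
        assert res.z_or_chi2 == 0.0
        assert res.p == 0.5

    def test_untied_variance_closed_form(self):
        groups = [[0.1, 0.9, 0.4, 0.7], [0.2, 0.5, 0.8], [0.3, 0.6, 1.0]]
        res = stats.jonckheere_terpstra(groups)
        ns = np.array([4.0, 3, 3])
        N = 10.0
        var = (N**2 * (2 * N + 3) - (ns**2 * (2 * ns + 3)).sum()) / 72.0
        mu = (N**2 - (ns**2).sum()) / 4.0
        assert res.z_or_chi2 == pytest.approx((res.statistic - mu) / math.sqrt(var))

    def _exact_p(self, groups):
        """Oracle: full enumeration of group-label assignments."""
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        J_obs = stats._jt_statistic([np.asarray(g, float) for g in groups])
        idx = range(len(pooled))
        count = total = 0
        for combo1 in itertools.combinations(idx, sizes[0]):
            rest = [i for i in idx if i not in combo1]
            for combo2 in itertools.combinations(rest, sizes[1]):
                g3 = [i for i in rest if i not in combo2]
                perm_groups = [pooled[list(combo1)], pooled[list(combo2)], pooled[g3]]
                total += 1
                if stats._jt_statistic(perm_groups) >= J_obs - 1e-12:
                    count += 1
        return count / total

    @pytest.mark.parametrize("seed", [0, 1])
    def test_normal_approximation_tracks_exact_permutation(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(0, 1, 4), rng.normal(0.3, 1, 3), rng.normal(0.6, 1, 3)]
        res = stats.jonckheere_terpstra(groups)
        p_exact = self._exact_p(groups)
        assert abs(res.p - p_exact) < 0.05

    def test_permutation_method_tracks_exact(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, 1, 4), rng.normal(0.3, 1, 3), rng.normal(0.6, 1, 3)]
        res = stats.jonckheere_terpstra(groups, method="permutation",
                                        n_perm=20_000, seed=3)
        p_exact = self._exact_p(groups)
        assert abs(res.p - p_exact) < 0.02

    def test_antisymmetry_under_order_reversal(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, 5), rng.normal(0.5, 1, 4), rng.normal(1.0, 1, 4)]
        fwd = stats.jonckheere_terpstra(groups)
        rev = stats.jonckheere_terpstra(groups[::-1])
        assert rev.z_or_chi2 == pytest.approx(-fwd.z_or_chi2, abs=1e-9)
        # conservation: J + J_reversed = sum_{i<j} n_i n_j for untied data
        assert fwd.statistic + rev.statistic == pytest.approx(5 * 4 + 5 * 4 + 4 * 4)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(0, 1, 5), rng.normal(0.4, 1, 4), rng.normal(0.9, 1, 4)]
        a = stats.jonckheere_terpstra(groups)
        b = stats.jonckheere_terpstra([np.exp(g) for g in groups])
        assert a.statistic == b.statistic and a.p == b.p

    def test_input_validation(self):
        with pytest.raises(ValueError):
            stats.jonckheere_terpstra([[1.0]])
        with pytest.raises(ValueError):
            stats.jonckheere_terpstra([[1.0], []])


# ---------------------------------------------------------------------------
# Kruskal-Wallis / Friedman / Wilcoxon


class TestKruskalWallis:
    def test_identical_groups_null(self):
        res = stats.kruskal_wallis([[3.0, 3.0], [3.0, 3.0]])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_two_separated_pairs_hand_value(self):
        # ranks 1,2 vs 3,4: H = 12/(4*5) * (3^2/2 + 7^2/2) - 3*5 = 2.4
        res = stats.kruskal_wallis([[1.0, 2.0], [3.0, 4.0]])
        assert res.statistic == pytest.approx(2.4)
        assert res.df == 1

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(0, 1, 6), rng.normal(1, 1, 5)]
        a = stats.kruskal_wallis(groups)
        b = stats.kruskal_wallis([g**3 for g in groups])
        assert a.statistic == pytest.approx(b.statistic)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.kruskal_wallis([[1.0], []])


class TestFriedman:
    def test_constant_blocks_null(self):
        mat = np.tile([2.0, 2.0, 2.0], (4, 1))
        res = stats.friedman(mat)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_perfectly_ordered_blocks_attain_maximum(self):
        n = 5
        mat = np.tile([1.0, 2.0, 3.0], (n, 1))
        res = stats.friedman(mat)
        assert res.statistic == pytest.approx(2 * n)  # k=3 maximum
        assert res.df == 2

    def test_block_shift_invariance(self):
        rng = np.random.default_rng(7)
        mat = rng.normal(0, 1, size=(5, 3))
        shifted = mat.copy()
        shifted[2] += 100.0
        assert stats.friedman(mat).statistic == pytest.approx(
            stats.friedman(shifted).statistic)

    def test_exhaustive_permutation_oracle(self):
        """Permutation p equals full enumeration of the 6^n within-block orderings."""
        rng = np.random.default_rng(8)
        mat = rng.normal(0, 1, size=(4, 3))
        res = stats.friedman(mat, method="permutation")
        assert res.method == "permutation-exhaustive"
        # independent oracle: enumerate orderings with scipy ranks
        perms = list(itertools.permutations(range(3)))
        obs = stats._friedman_statistic(mat)
        count = total = 0
        for combo in itertools.product(perms, repeat=4):
            pm = np.array([mat[i, list(c)] for i, c in enumerate(combo)])
            total += 1
            if stats._friedman_statistic(pm) >= obs - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / total)

    def test_matches_scipy(self):
        rng = np.random.default_rng(9)
        mat = rng.normal(0, 1, size=(8, 3))
        res = stats.friedman(mat)
        chi2, p = sps.friedmanchisquare(*[mat[:, j] for j in range(3)])
        assert res.statistic == pytest.approx(chi2)
        assert res.p == pytest.approx(p)

    def test_incomplete_blocks_dropped(self):
        mat = np.array([[1.0, 2.0, 3.0], [2.0, 1.0, 3.0], [np.nan, 1.0, 2.0],
                        [1.0, 3.0, 2.0]])
        res = stats.friedman(mat)
        assert res.n == 3


class TestWilcoxon:
    def test_three_positive_differences_exact(self):
        res = stats.wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert res.statistic == 6.0  # W+ on ranks 1+2+3
        assert res.p == pytest.approx(0.25)  # 2/8 sign patterns as extreme, doubled
        assert res.method == "exact"

    def test_sign_flip_symmetry(self):
        d = np.array([0.5, -1.2, 2.0, 3.1, -0.4])
        a = stats.wilcoxon_signed_rank(d)
        b = stats.wilcoxon_signed_rank(-d)
        assert a.p == pytest.approx(b.p)

    def test_single_pair(self):
        res = stats.wilcoxon_signed_rank([5.0])
        assert res.p == pytest.approx(1.0)

    def test_all_zero_differences_degenerate(self):
        res = stats.wilcoxon_signed_rank([0.0, 0.0])
        assert res.p == 1.0 and res.method == "degenerate"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_sign_enumeration(self, seed):
        """Oracle: enumerate all 2^n sign patterns of |d|."""
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, size=8)
        d = d[d != 0]
        res = stats.wilcoxon_signed_rank(d)
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        n = len(d)
        total_w = ranks.sum()
        count = 0
        for signs in itertools.product([0, 1], repeat=n):
            w = ranks[np.array(signs, dtype=bool)].sum()
            # two-sided: as or more extreme in either direction
            if min(w, total_w - w) <= min(w_obs, total_w - w_obs) + 1e-12:
                count += 1
        assert res.p == pytest.approx(count / 2**n)


class TestBonferroni:
    def test_scaling_cap_and_identity(self):
        assert stats.bonferroni([0.01], m=3) == [pytest.approx(0.03)]
        assert stats.bonferroni([0.5], m=3) == [1.0]
        assert stats.bonferroni([0.2], m=1) == [pytest.approx(0.2)]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            stats.bonferroni([1.5])
        with pytest.raises(ValueError):
            stats.bonferroni([0.1, 0.2], m=1)


# ---------------------------------------------------------------------------
# the battery layout


def _toy_metrics(seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    trial = 0
    for gs, n in [(1, 20), (2, 10), (6, 10)]:
        for _ in range(n):
            base = rng.lognormal(0, 0.4)
            for vel in (10.0, 20.0, 35.0):
                boost = 1.0 + effect * (gs - 1) * (vel >= 20.0)
                rows.append({
                    "trial_id": trial, "group_size": gs, "velocity": vel,
                    "EA": base * boost * (1 + 0.1 * rng.normal()),
                    "TL_m": base * boost * (1 + 0.1 * rng.normal()),
                    "median_x": rng.uniform(10, 50) + vel / 10,
                    "median_y": rng.uniform(10, 20),
                    "median_z": rng.uniform(1, 5) - vel / 20,
                })
            trial += 1
    return pd.DataFrame(rows)


class TestBattery:
    def test_layout_row_counts(self):
        out = stats.run_battery(_toy_metrics())
        assert (out.test == "jonckheere-terpstra").sum() == 6
        assert (out.test == "kruskal-wallis").sum() == 9
        assert (out.test == "friedman").sum() == 15
        n_sig_friedman = ((out.test == "friedman") & (out.p < 0.05)).sum()
        assert (out.test == "wilcoxon").sum() == 3 * n_sig_friedman

    def test_posthoc_adjustment_caps(self):
        out = stats.run_battery(_toy_metrics(seed=1))
        post = out[out.test == "wilcoxon"]
        if len(post):
            assert (post.p_adj >= post.p - 1e-12).all()
            assert (post.p_adj <= 1.0).all()

    def test_programmed_effect_detected(self):
        out = stats.run_battery(_toy_metrics(seed=2, effect=0.4))
        jt = out[out.test == "jonckheere-terpstra"]
        high = jt[jt.cluster.isin(["20 cm/s", "35 cm/s"])]
        assert (high.p < 0.05).all()


# ---------------------------------------------------------------------------
# reference swimming speeds


class TestSwimSpeeds:
    def test_videler_relation_reference_points(self):
        assert stats.videler_ums(5.0) == pytest.approx(27.0)
        assert stats.videler_ums(1e-9) == pytest.approx(15.0, abs=1e-6)
        # frozen regression value computed from the linear relation directly
        assert stats.videler_ums(5.14) == pytest.approx(27.336)

    def test_body_length_rate_conversion(self):
        assert stats.bl_rate_to_speed(5.0, 5.14, round_cm_s=True) == 26.0
        assert stats.bl_rate_to_speed(1.0, 10.0) == pytest.approx(10.0)
        assert stats.bl_rate_to_speed(0.0, 5.0) == 0.0

    def test_invalid_lengths(self):
        with pytest.raises(ValueError):
            stats.videler_ums(0.0)
        with pytest.raises(ValueError):
            stats.bl_rate_to_speed(1.0, -2.0)
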