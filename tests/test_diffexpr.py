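"""Mann-Whitney, AUC, multiplicity adjustment, and selection rules,
checked against independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigrev.containers import OmicsMatrix
from sigrev.diffexpr import (
    SelectionRule,
    adjust_pvalues,
    auc_from_u,
    exclude_contaminants,
    mann_whitney,
    proteomic_stats,
    select_degs,
    transcriptomic_stats,
)
from sigrev.synth import CohortSpec, gen_proteomic_cohort, gen_transcriptomic_cohort


def brute_u(g1, g2):
    """Oracle: count group2-over-group1 wins over all pairs, ties half."""
    u = 0.0
    for x in g1:
        for y in g2:
            if y > x:
                u += 1.0
            elif y == x:
                u += 0.5
    return u


def exact_two_sided_p(g1, g2):
    """Oracle: enumerate every group labeling of the pooled sample."""
    pooled = list(g1) + list(g2)
    n1 = len(g1)
    u_obs = brute_u(g1, g2)
    mean_u = n1 * len(g2) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = brute_u(a, b)
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_separated_groups_max_u_exact_p(self):
        U, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert U == 9
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(exact_two_sided_p([1, 2, 3], [4, 5, 6]))

    def test_identical_multisets_give_half_auc(self):
        U, _ = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert auc_from_u(U, 4, 4) == 0.5

    def test_interleaved_pair_count(self):
        U, _ = mann_whitney([1, 3], [2, 4])
        assert U == 3
        assert auc_from_u(U, 2, 2) == 0.75

    def test_missing_values_dropped_before_testing(self):
        U, p = mann_whitney([1, 2, 3, np.nan], [4, np.nan, 5, 6])
        U2, p2 = mann_whitney([1, 2, 3], [4, 5, 6])
        assert (U, p) == (U2, p2)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="2 usable values"):
            mann_whitney([1.0], [2.0, 3.0])

    @given(
        g1=st.lists(st.integers(0, 6), min_size=2, max_size=8),
        g2=st.lists(st.integers(0, 6), min_size=2, max_size=8),
    )
    def test_u_equals_brute_force_pair_count(self, g1, g2):
        U, _ = mann_whitney(g1, g2)
        assert U == pytest.approx(brute_u(g1, g2))

    @given(
        g1=st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=5,
                    unique=True),
        g2=st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=5,
                    unique=True),
    )
    @settings(max_examples=30)
    def test_exact_small_sample_p_matches_enumeration(self, g1, g2):
        pooled = g1 + g2
        if len(set(pooled)) < len(pooled):
            return  # tie across groups: exact path not used
        _, p = mann_whitney(g1, g2)
        assert p == pytest.approx(exact_two_sided_p(g1, g2), abs=1e-9)


class TestAuc:
    @pytest.mark.parametrize(
        "U,n1,n2,expected", [(9, 3, 3, 1.0), (0, 3, 3, 0.0), (3, 2, 2, 0.75)]
    )
    def test_known_values(self, U, n1, n2, expected):
        assert auc_from_u(U, n1, n2) == expected

    def test_out_of_range_u_rejected(self):
        with pytest.raises(ValueError, match="must lie in"):
            auc_from_u(10, 3, 3)

    @given(n1=st.integers(1, 8), n2=st.integers(1, 8), data=st.data())
    def test_complement_identity(self, n1, n2, data):
        U = data.draw(st.integers(0, n1 * n2))
        assert auc_from_u(U, n1, n2) + auc_from_u(n1 * n2 - U, n1, n2) == pytest.approx(1.0)


def bh_oracle(p):
    """Naive O(m^2) step-up: adj_i = min over all j with p_j >= p_i of
    min(1, m * p_j / rank_j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    adj = np.empty(m)
    for i in range(m):
        candidates = [
            min(1.0, m * p[j] / ranks[j]) for j in range(m) if ranks[j] >= ranks[i]
        ]
        adj[i] = min(candidates)
    return adj


class TestAdjustment:
    def test_bh_hand_stepup(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH")
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("method", ["BH", "Bonferroni"])
    def test_single_p_identity(self, method):
        assert adjust_pvalues([0.03], method) == pytest.approx([0.03])

    def test_bonferroni_scales_by_m(self):
        assert adjust_pvalues([0.01, 0.2], "Bonferroni") == pytest.approx([0.02, 0.4])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        for method in ("BH", "Bonferroni"):
            assert np.all(adjust_pvalues(p, method) >= p - 1e-12)

    def test_nan_passthrough(self):
        out = adjust_pvalues([0.01, np.nan, 0.02], "BH")
        assert np.isnan(out[1]) and np.isfinite(out[0])

    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50)
    )
    @settings(max_examples=50)
    def test_bh_matches_quadratic_oracle(self, p):
        assert adjust_pvalues(p, "BH") == pytest.approx(bh_oracle(p), abs=1e-12)


def _matrix_from_arrays(a1, a2):
    n1, n2 = a1.shape[1], a2.shape[1]
    vals = np.hstack([a1, a2])
    cols = [f"N{i}" for i in range(n1)] + [f"M{i}" for i in range(n2)]
    values = pd.DataFrame(vals, index=[f"F{i}" for i in range(vals.shape[0])], columns=cols)
    groups = pd.Series(["NMIBC"] * n1 + ["MIBC"] * n2, index=cols)
    return OmicsMatrix(values, groups, ("NMIBC", "MIBC"))


class TestTranscriptomicStats:
    def test_planted_cohort_mostly_recovered(self, small_cohort):
        mat, truth = small_cohort
        stats = transcriptomic_stats(mat)
        selected = set(select_degs(stats, SelectionRule()))
        planted = set(truth["feature_id"])
        assert len(selected & planted) >= 0.8 * len(planted)

    def test_planted_directions_match_truth(self, small_cohort):
        mat, truth = small_cohort
        stats = {s.feature_id: s for s in transcriptomic_stats(mat)}
        agree = sum(
            stats[f].direction == d for f, d in zip(truth["feature_id"], truth["direction"])
        )
        assert agree >= 0.95 * len(truth)

    def test_null_cohort_selects_almost_nothing(self):
        mat, _ = gen_transcriptomic_cohort(
            CohortSpec(n_features=2000, frac_shifted=0.0, seed=11)
        )
        stats = transcriptomic_stats(mat)
        assert len(select_degs(stats, SelectionRule())) <= 0.01 * 2000

    def test_constant_matrix_selects_nothing(self):
        a = np.full((10, 6), 5.0)
        stats = transcriptomic_stats(_matrix_from_arrays(a[:, :3], a[:, 3:]))
        assert select_degs(stats, SelectionRule()) == []
        assert all(s.auc == 0.5 for s in stats)

    def test_vectorized_and_looped_paths_agree(self):
        rng = np.random.default_rng(5)
        a1 = np.exp2(rng.normal(7, 1, (30, 10)))
        a2 = np.exp2(rng.normal(7.5, 1, (30, 9)))
        mat = _matrix_from_arrays(a1, a2)
        fast = transcriptomic_stats(mat)
        # force the per-feature path by planting a single NaN
        vals = mat.values.copy()
        slow_mat = OmicsMatrix(vals, mat.groups, mat.group_levels)
        slow_mat.values.iloc[0, 0] = np.nan
        slow = transcriptomic_stats(slow_mat)
        for f, s in list(zip(fast, slow))[1:]:
            assert f.p_value == pytest.approx(s.p_value)
            assert f.auc == pytest.approx(s.auc)
            assert f.log_fc == pytest.approx(s.log_fc)

    def test_direction_iff_positive_logfc(self, small_cohort):
        mat, _ = small_cohort
        for s in transcriptomic_stats(mat):
            assert (s.direction == "up") == (s.log_fc > 0)


class TestTypeIControl:
    def test_bh_fdr_under_null_generator(self):
        """Under the null, BH-selected fraction stays below alpha (10 seeds)."""
        fracs = []
        for seed in range(10):
            mat, _ = gen_transcriptomic_cohort(
                CohortSpec(n_features=2000, frac_shifted=0.0, seed=100 + seed)
            )
            stats = transcriptomic_stats(mat)
            n_sig = sum(1 for s in stats if s.p_adjusted < 0.05)
            fracs.append(n_sig / 2000)
        assert all(f <= 0.05 for f in fracs)


class TestProteomicStats:
    def test_contaminant_funnel(self):
        ids = [f"P{i:04d}" for i in range(870)]
        contaminants = ids[100:144]
        retained, excluded = exclude_contaminants(ids, contaminants)
        assert len(retained) == 826
        assert len(excluded) == 44

    def test_dual_platform_selection_and_exclusion_reasons(self):
        spec = CohortSpec(
            n_group1=15, n_group2=15, n_features=300, frac_shifted=0.2,
            effect_size=2.5, missing_rate=0.1, platform_corr=0.9, seed=3,
        )
        a, b, truth = gen_proteomic_cohort(spec)
        stats, daps, excl = proteomic_stats(a, b, SelectionRule())
        planted = set(truth["feature_id"])
        assert len(set(daps) & planted) >= 0.7 * len(planted)
        assert set(excl["reason"]) <= {
            "not significant", "low detection", "directional conflict", "contaminant"
        }
        assert len(daps) + len(excl) == 300

    def test_directional_conflict_excluded(self):
        # platform A: strong increase; platform B: strong decrease
        rng = np.random.default_rng(0)
        base = np.exp2(rng.normal(7, 0.2, (1, 20)))
        up = base.copy(); up[0, 10:] *= 8.0
        down = base.copy(); down[0, 10:] /= 8.0
        a = _matrix_from_arrays(up[:, :10], up[:, 10:])
        b = _matrix_from_arrays(down[:, :10], down[:, 10:])
        _, daps, excl = proteomic_stats(a, b, SelectionRule())
        assert daps == []
        assert list(excl["reason"]) == ["directional conflict"]

    def test_low_detection_excluded_regardless_of_p(self):
        rng = np.random.default_rng(1)
        vals = np.exp2(rng.normal(7, 0.2, (1, 40)))
        vals[0, 20:] *= 16.0
        vals[0, 2:20] = np.nan  # detected in 2/20 of group1...
        vals[0, 22:] = np.nan   # ...and 2/20 of group2 -> 10% overall
        m = _matrix_from_arrays(vals[:, :20], vals[:, 20:])
        _, daps, excl = proteomic_stats(m, m, SelectionRule())
        assert daps == []
        assert "low detection" in set(excl["reason"])

    def test_contaminants_excluded_from_daps(self):
        spec = CohortSpec(
            n_group1=15, n_group2=15, n_features=100, frac_shifted=0.3,
            effect_size=3.0, seed=9,
        )
        a, b, _ = gen_proteomic_cohort(spec)
        _, daps_all, _ = proteomic_stats(a, b, SelectionRule())
        rule = SelectionRule(contaminants=frozenset(daps_all[:5]))
        _, daps, excl = proteomic_stats(a, b, rule)
        assert set(daps_all) - set(daps) == set(daps_all[:5])
        assert (excl["reason"] == "contaminant").sum() == 5
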