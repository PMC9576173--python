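import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atriopv.io import ValidationError
from atriopv.simulate import CohortParams, sample_cohort_parameters
from atriopv.stats import (
    bonferroni_gate,
    bootstrap_ci,
    icc,
    mann_whitney,
    median_split,
    run_cohort_analysis,
    shapiro_wilk,
    spearman,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------------------
# enumeration oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------


def wilcoxon_enumeration_p(diffs):
    """Two-tailed signed-rank p by full enumeration of all 2^n sign
    assignments of the ranked absolute differences."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    w_all = []
    for signs in itertools.product([0, 1], repeat=n):
        w_all.append(np.sum(ranks * np.array(signs)))
    w_all = np.array(w_all)
    mu = n * (n + 1) / 4.0
    p = np.mean(np.abs(w_all - mu) >= abs(w_obs - mu) - 1e-12)
    return p


def mann_whitney_enumeration_p(a, b):
    """Two-tailed Mann-Whitney p by enumerating all C(n1+n2, n1) group
    labelings of the pooled sample."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = a.size
    u_obs = sum(np.sum(x > b) + 0.5 * np.sum(x == b) for x in a)
    n = pooled.size
    mu = n1 * (n - n1) / 2.0
    us = []
    for combo in itertools.combinations(range(n), n1):
        ga = pooled[list(combo)]
        gb = pooled[[i for i in range(n) if i not in combo]]
        us.append(sum(np.sum(x > gb) + 0.5 * np.sum(x == gb) for x in ga))
    us = np.array(us)
    return np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)


def spearman_enumeration(x, y):
    """rs and exact two-tailed permutation p via all n! pairings."""
    from scipy.stats import pearsonr, rankdata

    rx, ry = rankdata(x), rankdata(y)
    rs_obs = pearsonr(rx, ry)[0]
    count = total = 0
    for perm in itertools.permutations(ry):
        rs = pearsonr(rx, np.array(perm))[0]
        count += abs(rs) >= abs(rs_obs) - 1e-12
        total += 1
    return rs_obs, count / total


class TestWilcoxon:
    def test_all_positive_n6_closed_form(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], seed=0)
        assert res.p_value == pytest.approx(0.03125, abs=1e-12)  # 2 / 2^6

    def test_symmetric_pair_with_padding_balanced(self):
        # perfectly antisymmetric differences -> p = 1
        res = wilcoxon_signed_rank([1.0, -1.0, 2.0, -2.0, 3.0, -3.0], seed=0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle_exactly(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            d = rng.normal(0.3, 1.0, 8)
            res = wilcoxon_signed_rank(d, seed=0)
            assert res.p_value == pytest.approx(wilcoxon_enumeration_p(d), abs=1e-12)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank(np.zeros(8))

    def test_ci_brackets_median_difference(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.25, 0.2, 25)
        res = wilcoxon_signed_rank(d, seed=5)
        assert res.ci[0] <= res.estimate <= res.ci[1]


class TestMannWhitney:
    def test_separated_groups_closed_form(self):
        res = mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0], seed=0)
        assert res.p_value == pytest.approx(0.1, abs=1e-12)  # 2 / C(6,3)

    def test_identical_groups(self):
        res = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], seed=0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle_exactly(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.8, 1, 5)
            res = mann_whitney(a, b, seed=0)
            assert res.p_value == pytest.approx(mann_whitney_enumeration_p(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0, 2.0, 3.0])


class TestBootstrap:
    def test_constant_data_degenerate_interval(self):
        lo, hi = bootstrap_ci(np.full(10, 7.0), seed=0)
        assert lo == hi == 7.0

    def test_seed_reproducibility(self, rng):
        x = rng.lognormal(0, 1, 25)
        assert bootstrap_ci(x, seed=11) == bootstrap_ci(x, seed=11)

    def test_higher_level_widens_interval(self, rng):
        x = rng.lognormal(0, 1, 25)
        lo95, hi95 = bootstrap_ci(x, level_pct=95, seed=3)
        lo99, hi99 = bootstrap_ci(x, level_pct=98.75, seed=3)
        assert lo99 <= lo95 and hi99 >= hi95

    def test_two_sample_median_difference(self, rng):
        a = rng.normal(5, 1, 30)
        b = rng.normal(3, 1, 30)
        lo, hi = bootstrap_ci((a, b), seed=4)
        assert lo < np.median(a) - np.median(b) < hi

    def test_degenerate_n_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_ci(np.array([1.0, 2.0]), seed=0)


class TestBonferroni:
    def test_family_of_four_gives_00125(self):
        flags, thr = bonferroni_gate([0.013, 0.012], family_size=4)
        assert thr == pytest.approx(0.0125)
        assert flags.tolist() == [False, True]

    def test_family_one_uncorrected(self):
        flags, thr = bonferroni_gate([0.013], family_size=1)
        assert thr == pytest.approx(0.05)
        assert flags.tolist() == [True]


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(6, dtype=float)
        assert spearman(x, 2 * x + 1).rs == pytest.approx(1.0)
        assert spearman(x, -(x**3)).rs == pytest.approx(-1.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-100, 100), min_size=12, max_size=12, unique=True), st.integers(0, 10_000))
    def test_sign_flip_antisymmetry(self, xs, seed):
        x = np.array(xs)
        y = np.random.default_rng(seed).normal(size=12)
        assert spearman(x, -y).rs == pytest.approx(-spearman(x, y).rs, abs=1e-12)

    def test_matches_full_permutation_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            x = rng.integers(0, 5, 8).astype(float)  # ties likely
            y = rng.integers(0, 5, 8).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = spearman(x, y)
            rs_oracle, p_oracle = spearman_enumeration(x, y)
            assert res.rs == pytest.approx(rs_oracle, abs=1e-12)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValidationError):
            spearman(np.ones(6), np.arange(6.0))


class TestShapiro:
    def test_heavy_tailed_mixture_detected(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = np.where(rng.random(25) < 0.8, rng.normal(0, 1, 25), rng.normal(0, 8, 25))
            hits += shapiro_wilk(x)[1] < 0.05
        assert hits >= 180  # >= 90% of replicates

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            shapiro_wilk(np.full(10, 3.0))

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValidationError):
            shapiro_wilk([1.0, 2.0])


class TestMedianSplit:
    def _cohort(self, values):
        n = len(values)
        return pd.DataFrame(
            {"patient_id": [f"P{i:02d}" for i in range(n)], "lap_mean_t2": values}
        )

    def test_even_split(self):
        split = median_split(self._cohort([1.0, 2, 3, 4, 5, 6]), "lap_mean_t2")
        assert len(split.low_ids) == len(split.high_ids) == 3
        assert split.low_bounds == (1.0, 3.0)
        assert split.high_bounds == (4.0, 6.0)

    def test_odd_n_gives_13_12(self, rng):
        split = median_split(self._cohort(list(rng.normal(23, 4, 25))), "lap_mean_t2")
        assert (len(split.low_ids), len(split.high_ids)) == (13, 12)

    def test_all_equal_warns_and_splits_by_id(self):
        with pytest.warns(UserWarning, match="ties"):
            split = median_split(self._cohort([5.0] * 6), "lap_mean_t2")
        assert split.low_ids == ["P00", "P01", "P02"]


def icc_pingouin_oracle(x, model):
    """Independent ICC oracle via pingouin's ANOVA-based implementation."""
    import pingouin as pg

    n = x.shape[0]
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 2),
            "rater": np.tile([0, 1], n),
            "score": x.reshape(-1),
        }
    )
    res = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    label = "ICC(A,1)" if model == "icc21" else "ICC(C,1)"
    return float(res.loc[res["Type"] == label, "ICC"].iloc[0])


class TestICC:
    def test_identical_duplicates_give_unity(self, rng):
        col = rng.normal(70, 10, 12)
        x = np.column_stack([col, col])
        assert icc(x, "icc21").icc == pytest.approx(1.0)
        assert icc(x, "icc31").icc == pytest.approx(1.0)

    def test_independent_ratings_near_zero(self, rng):
        x = rng.normal(0, 1, size=(200, 2))
        assert abs(icc(x, "icc21").icc) < 0.15
        assert abs(icc(x, "icc31").icc) < 0.15

    @pytest.mark.parametrize("model", ["icc21", "icc31"])
    def test_matches_anova_oracle(self, model, rng):
        subj = rng.normal(0, 10, 10)
        x = subj[:, None] + np.array([0.0, 1.5]) + rng.normal(0, 2, (10, 2))
        res = icc(x, model)
        assert res.icc == pytest.approx(icc_pingouin_oracle(x, model), abs=1e-9)
        assert res.ci[0] <= res.icc <= res.ci[1]

    def test_consistency_form_exceeds_agreement_form_under_rater_bias(self, rng):
        subj = rng.normal(0, 10, 30)
        x = subj[:, None] + np.array([0.0, 6.0]) + rng.normal(0, 2, (30, 2))
        assert icc(x, "icc31").icc > icc(x, "icc21").icc

    def test_missing_cells_rejected(self):
        x = np.ones((6, 2))
        x[2, 1] = np.nan
        with pytest.raises(ValidationError):
            icc(x)


class TestCohortAnalysis:
    @pytest.fixture
    def cohort(self):
        return sample_cohort_parameters(CohortParams(n_patients=25), seed=17)

    def test_schema_contains_all_groupings(self, cohort):
        res = run_cohort_analysis(cohort, seed=0, n_resamples=1000)
        assert set(res["analyses"]) == {"all", "rhythm", "lap_mean", "vmax_indexed", "laad_indexed"}
        assert set(res["analyses"]["rhythm"]["groups"]) == {"paroxysmal", "persistent"}
        assert set(res["analyses"]["laad_indexed"]["groups"]) == {"low", "high"}
        assert "delta_stiff_vs_laa_depth_idx" in res["correlations"]

    def test_configured_shift_flags_significance(self, cohort):
        res = run_cohort_analysis(cohort, seed=0, n_resamples=1000)
        assert res["analyses"]["all"]["groups"]["all"]["paired_wilcoxon"].p_value < 0.05

    def test_copula_correlation_visible(self, cohort):
        rs = res = run_cohort_analysis(cohort, seed=0, n_resamples=1000)["correlations"][
            "delta_stiff_vs_laa_depth_idx"
        ].rs
        assert rs > 0.3

    def test_small_group_rejected(self):
        small = sample_cohort_parameters(CohortParams(n_patients=6), seed=1)
        with pytest.raises(ValidationError, match="group size"):
            run_cohort_analysis(small, seed=0, n_resamples=1000)

    def test_type_one_error_controlled(self):
        rejections = 0
        n_trials = 300
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            d = rng.normal(0, 0.2, 25)
            rejections += (
                wilcoxon_signed_rank(d, seed=0, n_resamples=1000).p_value < 0.05
            )
        assert rejections / n_trials <= 0.06 + 0.02
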