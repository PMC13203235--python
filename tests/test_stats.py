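import itertools
import math

import numpy as np
import pytest

from troughvar.errors import InsufficientDataError, RowValidationError
from troughvar.metrics import VariabilityProfile
from troughvar.stats import (
    build_comparison_table,
    comparison_to_frame,
    comparison_to_markdown,
    explore_predictors,
    fisher_exact_2x2,
    holm_adjust,
    mann_whitney,
    rank_biserial,
    spearman_rho,
)
from troughvar.data import PatientCovariates


# --- independent oracles -------------------------------------------------

def mw_null_distribution(n_a, n_b):
    """Exact null distribution of U_a by enumeration of rank assignments."""
    total = n_a + n_b
    counts = {}
    for a_ranks in itertools.combinations(range(total), n_a):
        a_set = set(a_ranks)
        u = sum(sum(1 for r in range(rank) if r not in a_set) for rank in a_ranks)
        counts[u] = counts.get(u, 0) + 1
    n_configs = math.comb(total, n_a)
    return counts, n_configs


def mw_exact_p_oracle(u, n_a, n_b):
    """Two-sided exact p: mass at least as far from the center as observed."""
    counts, n_configs = mw_null_distribution(n_a, n_b)
    center = n_a * n_b / 2.0
    dist = abs(u - center)
    mass = sum(c for v, c in counts.items() if abs(v - center) >= dist - 1e-9)
    return mass / n_configs


def cliff_delta_oracle(a, b):
    """Brute-force all-pairs Cliff's delta; ties contribute zero."""
    gt = sum(1 for x in a for y in b if y > x)
    lt = sum(1 for x in a for y in b if y < x)
    return (gt - lt) / (len(a) * len(b))


def fisher_p_oracle(a, b, c, d):
    """Point-probability two-sided Fisher p by direct table enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = table_prob(a)
    p = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = table_prob(k)
        if pk <= p_obs * (1 + 1e-7):
            p += pk
    return p


def midranks(vals):
    order = sorted(range(len(vals)), key=lambda i: vals[i])
    ranks = [0.0] * len(vals)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and vals[order[j + 1]] == vals[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    mx, my = sum(x) / len(x), sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    return num / den


def make_profile(pid, cohort, cv=30.0, swing=1.0, mssd_val=5.0, rng_val=10.0,
                 changes=2, mean=17.0, stable=False):
    return VariabilityProfile(
        patient_id=pid, cohort=cohort, n_measurements=4, mean_trough=mean,
        min_trough=mean - rng_val / 2, max_trough=mean + rng_val / 2,
        cv_pct=cv, swing_index=swing, mssd=mssd_val, trough_range=rng_val,
        n_zone_changes=changes, stable=stable,
    )


# --- Mann-Whitney --------------------------------------------------------

class TestMannWhitney:
    def test_complete_separation_small(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0
        assert res.method == "exact"
        # enumeration of all C(6,3)=20 labelings: 2/20
        assert res.p_value == pytest.approx(0.1)

    def test_identical_samples(self):
        res = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value >= 0.99
        assert res.method == "asymptotic"  # ties force the approximation

    def test_empty_sample(self):
        with pytest.raises(InsufficientDataError):
            mann_whitney([], [1.0])

    def test_exact_path_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n_a, n_b = rng.integers(2, 7, size=2)
            pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))
            a, b = pooled[:n_a], pooled[n_a:]
            res = mann_whitney(a, b)
            assert res.method == "exact"
            expected = mw_exact_p_oracle(res.u_statistic, n_a, n_b)
            assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_asymptotic_close_to_exact_at_8_per_group(self):
        # every achievable U for n_a = n_b = 8, tie-free: the two methods
        # must agree within 0.02
        n_a = n_b = 8
        for u in range(n_a * n_b + 1):
            a, b = sample_with_u(u, n_a, n_b)
            exact = mann_whitney(a, b, exact_limit=400)
            asym = mann_whitney(a, b, exact_limit=0)
            assert exact.method == "exact" and asym.method == "asymptotic"
            assert abs(exact.p_value - asym.p_value) <= 0.02

    def test_ties_fall_back_to_asymptotic(self):
        res = mann_whitney([1, 2, 2, 3], [2, 4, 5])
        assert res.method == "asymptotic"
        assert 0 < res.p_value <= 1


def sample_with_u(u, n_a, n_b):
    """Construct tie-free samples with exactly u pairs (a > b).

    Start from a-ranks at the bottom (u=0) and bubble them up one position
    at a time; each upward swap increases U_a by one.
    """
    a_ranks = list(range(n_a))
    remaining = u
    for i in reversed(range(n_a)):
        lift = min(remaining, n_b)
        a_ranks[i] = a_ranks[i] + lift
        remaining -= lift
        if remaining == 0:
            break
    assert remaining == 0
    a_set = set(a_ranks)
    b_ranks = [r for r in range(n_a + n_b) if r not in a_set]
    return [float(r) for r in a_ranks], [float(r) for r in b_ranks]


class TestSampleWithU:
    def test_construction_covers_all_u(self):
        for u in range(65):
            a, b = sample_with_u(u, 8, 8)
            observed = sum(1 for x in a for y in b if x > y)
            assert observed == u


# --- rank-biserial -------------------------------------------------------

class TestRankBiserial:
    def test_complete_separation(self):
        assert rank_biserial([1, 2, 3], [4, 5, 6]) == pytest.approx(1.0)
        assert rank_biserial([4, 5, 6], [1, 2, 3]) == pytest.approx(-1.0)

    def test_identical_samples(self):
        assert rank_biserial([1.0, 2.0], [1.0, 2.0]) == pytest.approx(0.0)

    def test_sign_convention_post_lower_is_negative(self):
        assert rank_biserial([10.0, 11.0, 12.0], [1.0, 2.0]) < 0

    def test_matches_all_pairs_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n_a, n_b = rng.integers(2, 12, size=2)
            a = rng.integers(0, 8, n_a).astype(float)
            b = rng.integers(0, 8, n_b).astype(float)
            assert rank_biserial(a, b) == pytest.approx(
                cliff_delta_oracle(list(a), list(b)), abs=1e-12
            )

    def test_bounded(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            a = rng.normal(size=rng.integers(1, 10))
            b = rng.normal(size=rng.integers(1, 10))
            assert abs(rank_biserial(a, b)) <= 1.0 + 1e-12

    def test_empty_sample(self):
        with pytest.raises(InsufficientDataError):
            rank_biserial([], [1.0])


# --- Fisher's exact ------------------------------------------------------

class TestFisherExact:
    def test_stable_patient_table(self):
        # printed 2x2: 5/46 vs 3/14
        assert fisher_exact_2x2([[5, 46], [3, 14]]) == pytest.approx(0.402, abs=5e-4)

    def test_no_association_possible(self):
        assert fisher_exact_2x2([[0, 10], [0, 10]]) == pytest.approx(1.0)

    def test_modal_table_gives_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 15, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                fisher_p_oracle(int(a), int(b), int(c), int(d)), abs=1e-10
            )

    def test_two_sided_at_least_one_sided(self):
        from scipy.stats import fisher_exact as scipy_fisher

        table = [[12, 3], [4, 11]]
        two = fisher_exact_2x2(table)
        one = min(
            scipy_fisher(table, alternative="less").pvalue,
            scipy_fisher(table, alternative="greater").pvalue,
        )
        assert two >= one

    def test_negative_cell_rejected(self):
        with pytest.raises(RowValidationError):
            fisher_exact_2x2([[1, -2], [3, 4]])

    def test_non_2x2_rejected(self):
        with pytest.raises(RowValidationError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])


# --- Spearman ------------------------------------------------------------

class TestSpearman:
    def test_monotone_increasing(self):
        res = spearman_rho([1, 2, 3, 4], [10, 20, 25, 40])
        assert res.rho == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        res = spearman_rho([1, 2, 3, 4], [9, 7, 4, 1])
        assert res.rho == pytest.approx(-1.0)

    def test_tied_data_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(4, 15))
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if len(set(x)) == 1 or len(set(y)) == 1:
                continue
            res = spearman_rho(x, y)
            expected = pearson(midranks(list(x)), midranks(list(y)))
            assert res.rho == pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete_dropping(self):
        x = [1.0, 2.0, math.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, math.nan]
        res = spearman_rho(x, y)
        assert res.n_pairs == 3
        assert res.rho == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(RowValidationError):
            spearman_rho([1, 2, 3], [1, 2])

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            spearman_rho([1, 2], [3, 4])

    def test_permutation_p_close_to_t_approx(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=7)
        y = x + rng.normal(scale=2.0, size=7)
        p_perm = spearman_rho(x, y, method="permutation").p_value
        p_t = spearman_rho(x, y, method="t_approx").p_value
        assert abs(p_perm - p_t) < 0.12

    def test_permutation_refused_for_large_n(self):
        with pytest.raises(InsufficientDataError):
            spearman_rho(list(range(12)), list(range(12)), method="permutation")


# --- comparison table ----------------------------------------------------

class TestComparisonTable:
    def test_identical_cohorts(self):
        pre = [make_profile(f"a{i}", "pre", cv=20 + i) for i in range(6)]
        post = [make_profile(f"b{i}", "post", cv=20 + i) for i in range(6)]
        rows = build_comparison_table(pre, post)
        for r in rows:
            if r.test == "mann_whitney":
                assert r.effect_size_rrb == pytest.approx(0.0)
                assert r.p_value >= 0.99

    def test_complete_separation_gives_minus_one(self):
        pre = [
            make_profile(f"a{i}", "pre", cv=40 + i, swing=1.0 + i / 10,
                         mssd_val=8 + i, rng_val=18 + i, changes=4 + i, mean=20 + i)
            for i in range(6)
        ]
        post = [
            make_profile(f"b{i}", "post", cv=10 + i, swing=0.1 + i / 100,
                         mssd_val=1 + i / 10, rng_val=2 + i / 10, changes=i % 2,
                         mean=10 + i / 10)
            for i in range(6)
        ]
        for r in build_comparison_table(pre, post):
            if r.test == "mann_whitney":
                assert r.effect_size_rrb == pytest.approx(-1.0)

    def test_stable_row_matches_printed_counts(self):
        pre = [make_profile(f"a{i}", "pre", stable=(i < 5)) for i in range(51)]
        post = [make_profile(f"b{i}", "post", stable=(i < 3)) for i in range(17)]
        (row,) = [r for r in build_comparison_table(pre, post) if r.test == "fisher_exact"]
        assert row.pre_counts == (5, 51)
        assert row.post_counts == (3, 17)
        assert row.p_value == pytest.approx(0.402, abs=5e-4)

    def test_empty_cohort_rejected(self):
        with pytest.raises(InsufficientDataError):
            build_comparison_table([], [make_profile("b", "post")])

    def test_rrb_consistent_with_u(self):
        rng = np.random.default_rng(21)
        pre = [make_profile(f"a{i}", "pre", cv=float(rng.normal(40, 10))) for i in range(12)]
        post = [make_profile(f"b{i}", "post", cv=float(rng.normal(30, 10))) for i in range(8)]
        rows = build_comparison_table(pre, post)
        cv_row = next(r for r in rows if r.metric == "cv_pct")
        # U reported is U_a (pairs a > b); r_rb = 1 - 2 U_a / (n_a n_b)
        assert cv_row.effect_size_rrb == pytest.approx(
            1.0 - 2.0 * cv_row.u_statistic / (12 * 8)
        )

    def test_outputs_render(self):
        pre = [make_profile(f"a{i}", "pre", cv=40.0 + i) for i in range(5)]
        post = [make_profile(f"b{i}", "post", cv=30.0 + i) for i in range(5)]
        rows = build_comparison_table(pre, post)
        frame = comparison_to_frame(rows)
        assert len(frame) == 7
        md = comparison_to_markdown(rows)
        assert "stable_patients" in md


class TestHolm:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(23)
        p = rng.uniform(0, 1, 9)
        expected = multipletests(p, method="holm")[1]
        assert holm_adjust(p) == pytest.approx(expected)


class TestExplorePredictors:
    @staticmethod
    def _covariates(pids, **overrides):
        return {
            pid: PatientCovariates(
                patient_id=pid,
                age=overrides.get("age", {}).get(pid, 60.0),
                egfr=80.0,
                weight=80.0,
                therapy_duration=overrides.get("therapy_duration", {}).get(pid, 10.0),
                n_dose_adjustments=2.0,
                loading_dose=25.0,
                loading_dose_given=True,
            )
            for pid in pids
        }

    def test_covariate_identical_to_cv(self):
        profiles = [make_profile(f"p{i}", "post", cv=20.0 + 3 * i) for i in range(8)]
        cov = self._covariates(
            [p.patient_id for p in profiles],
            age={p.patient_id: p.cv_pct for p in profiles},
        )
        results, n_unmatched = explore_predictors(profiles, cov, ("age",))
        assert n_unmatched == 0
        assert results[0].rho == pytest.approx(1.0)

    def test_independent_covariate_near_zero(self):
        rng = np.random.default_rng(31)
        profiles = [
            make_profile(f"p{i}", "post", cv=float(rng.normal(35, 8)))
            for i in range(1000)
        ]
        cov = self._covariates(
            [p.patient_id for p in profiles],
            age={p.patient_id: float(rng.normal(60, 10)) for p in profiles},
        )
        results, _ = explore_predictors(profiles, cov, ("age",))
        assert abs(results[0].rho) < 0.1

    def test_unmatched_patients_counted(self):
        profiles = [make_profile(f"p{i}", "post", cv=20.0 + i) for i in range(6)]
        cov = self._covariates([p.patient_id for p in profiles[:4]])
        _, n_unmatched = explore_predictors(profiles, cov, ("age",))
        assert n_unmatched == 2

    def test_no_matches_raises(self):
        profiles = [make_profile("p1", "post")] * 1
        with pytest.raises(InsufficientDataError):
            explore_predictors(profiles, {}, ("age",))
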