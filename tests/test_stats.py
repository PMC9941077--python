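"""Session selection, quantiles and nonparametric group comparison."""

import itertools
import math

import numpy as np
import pytest

from suturemetrics.session import SessionRecord
from suturemetrics.stats import (
    build_report,
    count_achievement,
    kruskal_wallis,
    mann_whitney,
    median_iqr,
    select_sessions,
)
from suturemetrics.synthetic import simulate_cohort


def brute_force_kw_p(groups):
    """Exact permutation p-value of the Kruskal-Wallis H for distinct data."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    sizes = [len(g) for g in groups]
    n = pooled.size
    ranks = {v: r for r, v in enumerate(np.sort(pooled), start=1)}

    def h_of(assignment):
        h = 0.0
        for size, rs in zip(sizes, assignment):
            h += rs**2 / size
        return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)

    obs_sums = []
    i = 0
    for size in sizes:
        obs_sums.append(sum(ranks[v] for v in pooled[i : i + size]))
        i += size
    h_obs = h_of(obs_sums)

    all_ranks = list(range(1, n + 1))
    count = ge = 0

    def recurse(remaining, sizes_left, sums):
        nonlocal count, ge
        if len(sizes_left) == 1:
            h = h_of(sums + [sum(remaining)])
            count += 1
            ge += h >= h_obs - 1e-12
            return
        for combo in itertools.combinations(remaining, sizes_left[0]):
            rest = [r for r in remaining if r not in combo]
            recurse(rest, sizes_left[1:], sums + [sum(combo)])

    recurse(all_ranks, sizes, [])
    return h_obs, ge / count


def brute_force_mw_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    pooled = sorted(list(a) + list(b))
    na = len(a)

    # U as min(U_a, U_b) is symmetric; enumerate assignments of which pooled
    # values form group a.
    u_obs = sum(1 for x in a for y in b if x > y)
    n_total = len(pooled)
    u_b_obs = na * (n_total - na) - u_obs
    stat_obs = min(u_obs, u_b_obs)
    count = le = 0
    for combo in itertools.combinations(range(n_total), na):
        sa = [pooled[i] for i in combo]
        sb = [pooled[i] for i in range(n_total) if i not in combo]
        u = sum(1 for x in sa for y in sb if x > y)
        ub = na * (n_total - na) - u
        count += 1
        le += min(u, ub) <= stat_obs
    return le / count


class TestSelectSessions:
    def _cohort(self, n=(5, 8, 11), sessions=3):
        records = []
        for group, count in zip(("senior", "junior", "novice"), n):
            for p in range(count):
                for s in range(1, sessions + 1):
                    records.append(
                        SessionRecord(
                            participant=f"{group}_{p}", group=group,
                            session_index=s,
                        )
                    )
        return records

    def test_paper_policy_counts(self):
        selected = select_sessions(self._cohort(), "paper")
        by_group = {g: sum(1 for r in selected if r.group == g)
                    for g in ("senior", "junior", "novice")}
        assert by_group == {"senior": 5, "junior": 8, "novice": 33}

    def test_first_policy_one_session_each(self):
        selected = select_sessions(self._cohort(), "first")
        assert len(selected) == 24
        assert all(r.session_index == 1 for r in selected)

    def test_all_policy_is_identity(self):
        cohort = self._cohort()
        assert select_sessions(cohort, "all") == cohort

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            select_sessions(self._cohort(), "latest")


class TestMedianIQR:
    def test_five_values(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)

    def test_single_value(self):
        assert median_iqr([7.5]) == (7.5, 7.5, 7.5)

    def test_matches_sort_and_interpolate_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            vals = rng.normal(size=int(rng.integers(2, 40)))
            med, q1, q3 = median_iqr(vals)
            s = np.sort(vals)

            def interp(q):
                pos = q * (s.size - 1)
                lo, hi = int(math.floor(pos)), int(math.ceil(pos))
                frac = pos - lo
                return s[lo] * (1 - frac) + s[hi] * frac

            assert med == pytest.approx(interp(0.5))
            assert q1 == pytest.approx(interp(0.25))
            assert q3 == pytest.approx(interp(0.75))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])
        assert h == 0.0 and p == 1.0

    def test_separated_groups_match_rank_arithmetic(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        h, p = kruskal_wallis(groups, method="asymptotic")
        # Rank sums 6, 15, 24 with n = 9:
        # H = 12/(9*10) * (36/3 + 225/3 + 576/3) - 3*10 = 7.2
        assert h == pytest.approx(7.2)
        from scipy.stats import chi2

        assert p == pytest.approx(float(chi2.sf(7.2, df=2)))

    def test_group_order_invariance(self):
        rng = np.random.default_rng(13)
        groups = [list(rng.normal(size=5)) for _ in range(3)]
        base = kruskal_wallis(groups)
        for perm in itertools.permutations(groups):
            assert kruskal_wallis(list(perm)) == pytest.approx(base)

    @pytest.mark.parametrize(
        "groups",
        [
            [[1.0, 5.0, 2.5], [3.0, 8.0, 0.5], [4.0, 9.0, 6.0]],
            [[10.0, 1.0], [2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]],
            [[0.1, 0.9], [0.5, 0.3], [0.7, 0.2]],
        ],
    )
    def test_exact_matches_bruteforce_permutation_null(self, groups):
        h, p = kruskal_wallis(groups, method="exact")
        h_bf, p_bf = brute_force_kw_p(groups)
        assert h == pytest.approx(h_bf)
        assert p == pytest.approx(p_bf, abs=1e-12)

    def test_auto_exact_agrees_with_bruteforce_within_tolerance(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            groups = [list(rng.normal(size=3)) for _ in range(3)]
            _, p = kruskal_wallis(groups)  # auto -> exact at n = 9
            _, p_bf = brute_force_kw_p(groups)
            assert abs(p - p_bf) <= 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_fully_separated_small_samples(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        # 20 equally likely orderings, the two extremes are as or more
        # extreme: p = 2/20
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(brute_force_mw_p([1, 2, 3], [4, 5, 6]))

    def test_swap_symmetry(self):
        rng = np.random.default_rng(19)
        a, b = list(rng.normal(size=4)), list(rng.normal(size=6))
        u_ab, p_ab = mann_whitney(a, b)
        u_ba, p_ba = mann_whitney(b, a)
        assert p_ab == pytest.approx(p_ba)
        assert u_ba == pytest.approx(len(a) * len(b) - u_ab)

    def test_exact_matches_bruteforce_within_tolerance(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            a = list(rng.normal(size=4))
            b = list(rng.normal(size=5))
            _, p = mann_whitney(a, b)
            assert abs(p - brute_force_mw_p(a, b)) <= 0.01


class TestAchievementAndReport:
    def test_count_achievement_matches_tally(self):
        cohort = simulate_cohort(n_per_group=2, sessions_per_participant=2,
                                 seed=5)
        counts = count_achievement(cohort)
        for group, table in counts.items():
            sessions = [r for r in cohort if r.group == group]
            assert sum(table.values()) == len(sessions)
            for k, c in table.items():
                assert c == sum(1 for r in sessions if r.n_completed == k)

    def test_report_has_16_rows(self):
        cohort = simulate_cohort(n_per_group=2, sessions_per_participant=1,
                                 seed=7)
        report = build_report(cohort, policy="all")
        assert len(report.rows) == 16

    def test_report_invariant_to_session_order(self):
        cohort = simulate_cohort(n_per_group=2, sessions_per_participant=2,
                                 seed=9)
        a = build_report(cohort, policy="all").to_dataframe()
        b = build_report(cohort[::-1], policy="all").to_dataframe()
        assert a.equals(b)

    def test_identical_sessions_across_groups_p_one(self):
        from suturemetrics.synthetic import default_profiles, simulate_session

        profile = default_profiles()["senior"]
        records = []
        for group in ("senior", "junior", "novice"):
            for p in range(3):
                rec = simulate_session(profile, seed=42, participant=f"{group}_{p}",
                                       session_index=1)
                rec.group = group
                rec.meta["group"] = group
                records.append(rec)
        report = build_report(records, policy="all")
        for row in report.rows:
            if math.isfinite(row.p):
                assert row.p == pytest.approx(1.0)
                medians = [v["median"] for v in row.per_group.values()]
                if all(math.isfinite(m) for m in medians):
                    assert max(medians) == pytest.approx(min(medians))
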