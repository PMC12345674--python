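"""Normality screen, rank-sum test, and FDR adjustment."""

import itertools
import math
from collections import Counter
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uretox.cohort import Group, assign_strata
from uretox.inference import bh_adjust, compare_groups, normality_test, rank_sum_test
from uretox.simulate import SimulationConfig, default_calibration, generate_cohort
from uretox.toxins import Toxin


# --- independent oracles -----------------------------------------------------


@lru_cache(maxsize=None)
def _exact_u_distribution(n_a: int, n_b: int) -> Counter:
    """Null distribution of the Mann–Whitney U statistic of group A by
    brute-force enumeration of all C(n_a+n_b, n_a) rank assignments."""
    n = n_a + n_b
    dist: Counter = Counter()
    for positions in itertools.combinations(range(n), n_a):
        rank_sum = sum(positions) + n_a  # 1-based ranks
        dist[rank_sum - n_a * (n_a + 1) // 2] += 1
    return dist


def brute_force_two_sided_p(a, b) -> float:
    """Exact two-sided p from the enumerated null distribution:
    2·min(P(U ≤ u), P(U ≥ u)), capped at 1."""
    a, b = np.asarray(a), np.asarray(b)
    u_obs = sum((x > y) for x in a for y in b)
    dist = _exact_u_distribution(len(a), len(b))
    total = sum(dist.values())
    lo = sum(c for u, c in dist.items() if u <= u_obs) / total
    hi = sum(c for u, c in dist.items() if u >= u_obs) / total
    return min(1.0, 2 * min(lo, hi))


def step_up_bh(p):
    """Hand implementation of the BH step-up formula used as an oracle."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        adj[order[i]] = running
    return adj


# --- normality ---------------------------------------------------------------


class TestNormalityScreen:
    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0])
        with pytest.raises(ValueError):
            normality_test([3.0] * 10)

    def test_skewed_alternative_rejected(self):
        """Draws from a fitted toxin log-normal are flagged non-normal in
        ≥95% of seeded replicates — the non-normality gate that motivates
        the rank-based pipeline."""
        params = default_calibration().params(Group.CONTROL, Toxin.PCS)
        rng = np.random.default_rng(42)
        rejections = sum(
            normality_test(np.exp(params.mu + params.sigma * rng.standard_normal(500)))[1] < 0.05
            for _ in range(200)
        )
        assert rejections >= 190

    def test_type_i_error_near_alpha(self):
        """Under a true normal, the screen rejects at ≈ the nominal 5%."""
        rng = np.random.default_rng(7)
        rejections = sum(
            normality_test(rng.standard_normal(500))[1] < 0.05 for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.075


# --- rank-sum ----------------------------------------------------------------


class TestRankSum:
    def test_most_extreme_small_case(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(2 / 20)

    def test_self_comparison_p_one(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pvalue == 1.0
        assert res.method == "asymptotic"  # ties force the approximate path

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_ties_use_asymptotic_path(self):
        res = rank_sum_test([1, 2, 2], [3, 4, 5])
        assert res.method == "asymptotic"

    def test_large_groups_use_asymptotic_path(self, rng):
        res = rank_sum_test(rng.normal(size=50), rng.normal(size=50))
        assert res.method == "asymptotic"

    def test_exact_path_matches_brute_force_enumeration(self):
        """The exact path agrees with full permutation enumeration for
        all group sizes ≤ 7 over ≥1,000 random tie-free instances."""
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 1000:
            n_a, n_b = rng.integers(1, 8, size=2)
            pooled = rng.normal(size=int(n_a + n_b))
            if np.unique(pooled).size < pooled.size:
                continue
            a, b = pooled[:n_a], pooled[n_a:]
            res = rank_sum_test(a, b)
            assert res.method == "exact"
            assert res.pvalue == pytest.approx(brute_force_two_sided_p(a, b), abs=1e-12)
            checked += 1


# --- Benjamini–Hochberg ------------------------------------------------------


class TestBH:
    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_computed_step_up_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05]), [0.05] * 5
        )

    def test_identical_p_family(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        p=st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=20)
    )
    def test_matches_oracle_and_core_properties(self, p):
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, step_up_bh(p), atol=1e-12)
        p_arr = np.asarray(p)
        assert np.all(adj >= p_arr - 1e-15) and np.all(adj <= 1.0 + 1e-15)
        # order-preserving in the input ranks
        order = np.argsort(p_arr, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    @given(
        p=st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=12),
        seed=st.integers(min_value=0, max_value=100),
    )
    def test_permutation_equivariance(self, p, seed):
        perm = np.random.default_rng(seed).permutation(len(p))
        adj = bh_adjust(p)
        np.testing.assert_allclose(bh_adjust(np.asarray(p)[perm]), adj[perm], atol=1e-12)

    def test_constant_sequences_are_fixed_points(self):
        # BH is not idempotent on arbitrary adjusted sequences, but any
        # constant family is a fixed point of the step-up formula.
        for c in (0.0, 0.05, 0.5, 1.0):
            np.testing.assert_allclose(bh_adjust(bh_adjust([c] * 5)), [c] * 5)


# --- stratified family -------------------------------------------------------


class TestCompareGroups:
    def test_family_structure(self, study_strata):
        results = compare_groups(study_strata)
        assert len(results) == 5
        assert [r.toxin.value for r in results] == ["IS", "PCS", "TMAO", "ADMA", "SDMA"]
        for r in results:
            assert r.p_adj >= r.p_raw
            assert r.n_case == 161 and r.n_ref == 71
            assert r.test == "rank-sum (asymptotic)"

    def test_adjustment_is_within_family(self, study_strata):
        results = compare_groups(study_strata)
        np.testing.assert_allclose(
            [r.p_adj for r in results], step_up_bh([r.p_raw for r in results]), atol=1e-12
        )

    def test_empty_family(self, study_strata):
        assert compare_groups(study_strata, case_label="nonexistent") == []

    def test_injected_effect_detected(self):
        """A ln(2) median shift on one toxin yields the smallest adjusted
        p for that toxin in the majority of replicate cohorts."""
        from uretox.simulate import inject_effect

        cal = inject_effect(default_calibration(), Toxin.PCS, Group.ASD, math.log(2))
        wins = 0
        n_rep = 50
        for seed in range(n_rep):
            cohort = generate_cohort(cal, SimulationConfig(seed=seed))
            results = compare_groups(assign_strata(cohort))
            best = min(results, key=lambda r: r.p_adj)
            wins += best.toxin is Toxin.PCS
        assert wins >= 0.8 * n_rep
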