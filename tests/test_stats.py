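"""Statistical layer: exact-enumeration oracles, KM properties, overlap test."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from polyhcc import (
    GeneratorConfig,
    chi_square_2xk,
    fisher_exact_2x2,
    generate_cohort,
    hypergeom_overlap,
    km_curve,
    km_logrank,
    mann_whitney_one_sided,
)
from polyhcc.errors import EmptyGroupError, InputError


# ---------------------------------------------------------------- oracles

def mw_enumeration_p(x, y, alternative):
    """Exact Mann-Whitney p by enumerating all label assignments."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_of(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_of(x, y)
    us = []
    for idx in combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_of(xs, ys))
    us = np.array(us)
    if alternative == "greater":
        return float(np.mean(us >= u_obs))
    return float(np.mean(us <= u_obs))


def fisher_enumeration_p(table):
    """Two-sided Fisher p: sum of hypergeometric pmfs <= observed."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return 0.0
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = pmf(a)
    return sum(pmf(k) for k in range(c1 + 1) if pmf(k) <= p_obs * (1 + 1e-7))


def hypergeom_enumeration_p(k, n_a, n_b, n_universe):
    """Upper-tail overlap probability by direct pmf summation."""
    total = math.comb(n_universe, n_b)
    return sum(
        math.comb(n_a, j) * math.comb(n_universe - n_a, n_b - j) / total
        for j in range(k, min(n_a, n_b) + 1)
    )


# ------------------------------------------------------------ Mann-Whitney

class TestMannWhitney:
    def test_extreme_separation_exact_p(self):
        # y entirely above x: one-sided p for "x less" is 1 / C(6,3)
        res = mann_whitney_one_sided([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.u_statistic == 0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 20)

    def test_identical_samples_null(self):
        res = mann_whitney_one_sided([1.0, 2.0, 3.0], [1.5, 2.5, 3.5], "greater")
        assert res.p_value >= 0.5

    def test_tail_swap_complementarity(self):
        x, y = [3, 9, 1, 7], [2, 8, 4]
        pg = mann_whitney_one_sided(x, y, "greater").p_value
        pl = mann_whitney_one_sided(x, y, "less").p_value
        assert pg + pl >= 1.0  # discrete exact tails overlap at the observed U

    @pytest.mark.parametrize(
        "x,y",
        [([1, 4, 6], [2, 3, 5]), ([10, 20], [5, 15, 25, 35]),
         ([1, 2, 3, 4], [5, 6, 7]), ([7], [1, 2, 9])],
    )
    @pytest.mark.parametrize("alternative", ["greater", "less"])
    def test_matches_enumeration_oracle(self, x, y, alternative):
        res = mann_whitney_one_sided(x, y, alternative)
        assert res.p_value == pytest.approx(mw_enumeration_p(x, y, alternative))

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            mann_whitney_one_sided([], [1.0], "greater")


# ----------------------------------------------------------------- Fisher

class TestFisher:
    def test_perfect_diagonal(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_zero_margin_is_one(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == pytest.approx(1.0)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = rng.integers(0, 10, size=(2, 2))
            assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(t.T))

    def test_all_small_tables_match_enumeration(self):
        # every 2x2 table with total count <= 12
        for total in range(1, 13):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        table = [[a, b], [c, d]]
                        assert fisher_exact_2x2(table) == pytest.approx(
                            fisher_enumeration_p(table), rel=1e-9
                        ), table

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            fisher_exact_2x2([[1, -1], [2, 3]])


# ------------------------------------------------------------- chi-square

class TestChiSquare:
    def test_uniform_table_statistic_zero(self):
        res = chi_square_2xk([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association_closed_form(self):
        res = chi_square_2xk([[20, 0], [0, 20]])
        assert res.statistic == pytest.approx(40.0)
        assert res.dof == 1

    def test_statistic_linear_in_total(self):
        small = chi_square_2xk([[12, 4], [6, 10]])
        doubled = chi_square_2xk([[24, 8], [12, 20]])
        assert doubled.statistic == pytest.approx(2 * small.statistic)

    def test_zero_expected_suggests_fisher(self):
        with pytest.raises(InputError, match="[Ff]isher"):
            chi_square_2xk([[0, 0], [3, 4]])


# ------------------------------------------------------------------- KM

class TestKaplanMeier:
    def test_product_limit_closed_form(self):
        curve = km_curve([1.0, 2.0, 3.0], [True, True, True])
        assert list(curve["time"]) == [0.0, 1.0, 2.0, 3.0]
        np.testing.assert_allclose(curve["survival"], [1.0, 2 / 3, 1 / 3, 0.0])

    def test_censoring_removes_step(self):
        curve = km_curve([1.0, 2.0, 3.0], [True, False, True])
        # S = 2/3 after t=1; censored at 2; single subject at risk at t=3
        np.testing.assert_allclose(curve["survival"], [1.0, 2 / 3, 2 / 3, 0.0])

    def test_curve_monotone_and_anchored(self, study_cohort):
        surv = study_cohort.survival
        curve = km_curve(surv["time_years"], surv["event"])
        s = curve["survival"].to_numpy()
        assert curve["time"].iloc[0] == 0.0 and s[0] == 1.0
        assert (np.diff(s) <= 1e-12).all()

    def test_identical_groups_statistic_zero(self):
        records = pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                "event": [True, True, False, True, True, False],
                "group": ["a"] * 3 + ["b"] * 3,
            }
        )
        res = km_logrank(records, "a", "b")
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert set(res.curves["group"]) == {"a", "b"}

    def test_empty_group_rejected(self):
        records = pd.DataFrame(
            {"time": [1.0], "event": [True], "group": ["a"]}
        )
        with pytest.raises(EmptyGroupError):
            km_logrank(records, "a", "b")

    def test_hazard_ratio_detected_across_replicates(self):
        # HR 3.5 with near-complete follow-up: log-rank flags nearly every
        # replicate of the default cohort size
        detected = 0
        for seed in range(1, 21):
            cfg = GeneratorConfig(
                nuclei_per_tumor=10, fields_per_tumor=2,
                censor_window=(30.0, 40.0), seed=seed,
            )
            cohort = generate_cohort(cfg)
            truth = {t.tumor_id: t.true_class for t in cohort.truths}
            records = pd.DataFrame(
                {
                    "time": cohort.survival["time_years"],
                    "event": cohort.survival["event"],
                    "group": cohort.survival["tumor_id"].map(truth),
                }
            )
            res = km_logrank(records, "polyploid", "near_diploid")
            detected += res.p_value < 0.05
        assert detected >= 18


# ------------------------------------------------------------ hypergeometric

class TestHypergeomOverlap:
    def test_zero_overlap_certain(self):
        assert hypergeom_overlap(0, 5, 5, 10).p_value == pytest.approx(1.0)

    def test_complete_overlap_single_table(self):
        res = hypergeom_overlap(5, 5, 5, 10)
        assert res.p_value == pytest.approx(1 / 252)

    def test_tail_monotone_in_k(self):
        ps = [hypergeom_overlap(k, 8, 9, 30).p_value for k in range(9)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_matches_enumeration_small_universe(self):
        for k in range(6):
            assert hypergeom_overlap(k, 5, 6, 12).p_value == pytest.approx(
                hypergeom_enumeration_p(k, 5, 6, 12), rel=1e-12
            )

    def test_log_tail_survives_extreme_significance(self):
        res = hypergeom_overlap(900, 1000, 1000, 20_000)
        assert res.log10_p < -300  # beyond double underflow
        assert math.isfinite(res.log10_p)

    def test_overlap_larger_than_lists_rejected(self):
        with pytest.raises(InputError):
            hypergeom_overlap(6, 5, 9, 30)

    def test_gene_list_scale_significance(self):
        # overlap of ~39 genes between two few-hundred-gene lists in a
        # 20k universe is astronomically unlikely by chance
        res = hypergeom_overlap(39, 200, 334, 20_000)
        assert res.log10_p < -17
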