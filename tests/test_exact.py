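"""Exact joint pmf, scenario algorithms, and probability-ordering p-values.

The brute-force enumerator over all (X2, X3, Y2, Y3) combinations is the
independent oracle; every optimized scenario path must agree with it to
1e-10.
"""

import math

import numpy as np
import pytest

from catrend import (
    NullGenotypeProbs,
    ResourceError,
    ValidationError,
    exact_pvalue,
    exact_pvalue_coprime,
    exact_pvalue_equal,
    exact_pvalue_general,
    gcd_scenario,
    joint_pmf_brute_force,
    make_table,
    null_genotype_probs,
    triangle_count,
    triangle_overlap_counts,
    z_coordinates,
)
from .conftest import random_table

UNIFORM = NullGenotypeProbs((1 / 3, 1 / 3, 1 / 3), (1 / 3, 1 / 3, 1 / 3))


def brute_pvalue(table, probs, tie_tol=1e-12):
    pmf = joint_pmf_brute_force(table.r_x, table.r_y, probs)
    return pmf.pvalue_at(*z_coordinates(table), tie_tol=tie_tol)


class TestNullProbs:
    def test_pooled_enos(self, enos_table):
        probs = null_genotype_probs(enos_table, "pooled")
        expected = (370 / 844, 385 / 844, 89 / 844)
        assert probs.p == pytest.approx(expected, abs=1e-15)
        assert probs.q == probs.p

    def test_separate_enos(self, enos_table):
        probs = null_genotype_probs(enos_table, "separate")
        assert probs.p == pytest.approx((167 / 421, 200 / 421, 54 / 421))
        assert probs.q == pytest.approx((203 / 423, 185 / 423, 35 / 423))

    def test_fixed_roundtrip(self, enos_table):
        t = (1 / 3, 1 / 3, 1 / 3)
        probs = null_genotype_probs(enos_table, "fixed", fixed=(t, t))
        assert probs.p == t and probs.q == t

    @pytest.mark.parametrize(
        "bad", [((0.5, 0.2, 0.2), (1 / 3, 1 / 3, 1 / 3)),
                ((0.5, 0.6, -0.1), (1 / 3, 1 / 3, 1 / 3))]
    )
    def test_fixed_validation(self, enos_table, bad):
        with pytest.raises(ValidationError):
            null_genotype_probs(enos_table, "fixed", fixed=bad)


class TestScenarioClassification:
    @pytest.mark.parametrize(
        "rx,ry,expected",
        [(19, 2, "coprime"), (5, 5, "equal"), (10, 2, "general"),
         (1, 1, "equal"), (421, 423, "coprime"), (6, 4, "general")],
    )
    def test_gcd_scenario(self, rx, ry, expected):
        assert gcd_scenario(rx, ry) == expected

    @pytest.mark.parametrize("ry,expected", [(0, 1), (2, 6), (3, 10), (5, 21)])
    def test_triangle_count(self, ry, expected):
        assert triangle_count(ry) == expected

    def test_triangle_count_negative(self):
        with pytest.raises(ValidationError):
            triangle_count(-1)


class TestBruteForce:
    @pytest.mark.parametrize("rx,ry", [(2, 2), (5, 5), (7, 3), (10, 4)])
    def test_normalization(self, rx, ry):
        rng = np.random.default_rng(rx * 100 + ry)
        probs = NullGenotypeProbs(
            tuple(rng.dirichlet([1, 1, 1])), tuple(rng.dirichlet([1, 1, 1]))
        )
        for pr in (UNIFORM, probs):
            assert joint_pmf_brute_force(rx, ry, pr).total_mass == pytest.approx(
                1.0, abs=1e-10
            )

    def test_support_bounded_by_triangles(self):
        pmf = joint_pmf_brute_force(5, 5, UNIFORM)
        assert len(pmf.masses) <= triangle_count(5) * triangle_count(5)

    def test_guard(self):
        with pytest.raises(ResourceError):
            joint_pmf_brute_force(300, 300, UNIFORM)


class TestTriangleCombinatorics:
    def test_coprime_overlap_only_at_origin(self):
        # gcd = 1: triangles share no lattice point except the origin,
        # where exactly three meet.
        counts = triangle_overlap_counts(19, 2)
        assert counts[(0, 0)] == 3
        assert all(c == 1 for point, c in counts.items() if point != (0, 0))
        assert sum(counts.values()) == triangle_count(19) * triangle_count(2)

    def test_gcd2_overlaps_away_from_origin(self):
        counts = triangle_overlap_counts(4, 2)
        off_origin = [p for p, c in counts.items() if c >= 2 and p != (0, 0)]
        assert off_origin  # gcd=2 pools cells at multiples of the gcd
        g = math.gcd(4, 2)
        assert all(z1 % g == 0 and z2 % g == 0 for z1, z2 in counts)

    def test_equal_arms_origin_pools_all_triangles(self):
        # R_X = R_Y: each (Y2,Y3) triangle contributes its own (X=Y) cell
        # to the origin, so the origin pools all (R+1)(R+2)/2 triangles.
        counts = triangle_overlap_counts(10, 10)
        assert counts[(0, 0)] == triangle_count(10)


class TestCoprimePath:
    def test_matches_oracle(self):
        rng = np.random.default_rng(1)
        for rx, ry in [(3, 2), (19, 2), (7, 5), (15, 4)]:
            for _ in range(10):
                t = random_table(rng, rx, ry)
                probs = null_genotype_probs(t, "pooled")
                res = exact_pvalue_coprime(t, probs)
                assert res.p_value == pytest.approx(
                    brute_pvalue(t, probs), abs=1e-10
                )

    def test_most_extreme_cell_is_own_mass(self):
        # all cases aa, all controls AA: the observed cell is an extreme
        # corner with nothing below it in probability except ties
        t = make_table(0, 0, 3, 2, 0, 0)
        probs = UNIFORM
        res = exact_pvalue_coprime(t, probs)
        pmf = joint_pmf_brute_force(3, 2, probs)
        f_obs = pmf.mass_at(*z_coordinates(t))
        assert res.p_value == pytest.approx(
            sum(v for v in pmf.masses.values() if v <= f_obs * (1 + 1e-12)),
            abs=1e-12,
        )

    def test_modal_cell_gives_p_one(self):
        # observed at the unique modal cell: every cell is "equally or less
        # probable", so p = 1
        rng = np.random.default_rng(5)
        for rx, ry in [(4, 3), (7, 2)]:
            probs = NullGenotypeProbs(
                tuple(rng.dirichlet([5, 5, 5])), tuple(rng.dirichlet([5, 5, 5]))
            )
            pmf = joint_pmf_brute_force(rx, ry, probs)
            (z1m, z2m) = max(pmf.masses, key=pmf.masses.get)
            assert pmf.pvalue_at(z1m, z2m) == pytest.approx(1.0, abs=1e-10)


class TestEqualPath:
    def test_all_observations_match_oracle_r5(self):
        # every possible (X2,X3,Y2,Y3) observation at R=5, pooled probs
        checked = 0
        for x2 in range(6):
            for x3 in range(6 - x2):
                for y2 in range(6):
                    for y3 in range(6 - y2):
                        t = make_table(5 - x2 - x3, x2, x3, 5 - y2 - y3, y2, y3)
                        probs = null_genotype_probs(t, "pooled")
                        res = exact_pvalue_equal(t, probs)
                        assert res.p_value == pytest.approx(
                            brute_pvalue(t, probs), abs=1e-10
                        )
                        checked += 1
        assert checked == 441

    def test_identical_arms_symmetric_probs(self):
        t = make_table(2, 2, 1, 2, 2, 1)
        res = exact_pvalue_equal(t, UNIFORM)
        assert z_coordinates(t) == (0, 0)
        assert res.p_value == pytest.approx(brute_pvalue(t, UNIFORM), abs=1e-10)


class TestGeneralPath:
    def test_matches_oracle(self):
        rng = np.random.default_rng(2)
        for rx, ry in [(10, 2), (6, 4), (12, 9), (15, 6)]:
            for _ in range(10):
                t = random_table(rng, rx, ry)
                probs = null_genotype_probs(t, "pooled")
                res = exact_pvalue_general(t, probs)
                assert res.p_value == pytest.approx(
                    brute_pvalue(t, probs), abs=1e-10
                )


class TestDispatcher:
    def test_scenario_recorded(self):
        rng = np.random.default_rng(3)
        for rx, ry, scen in [(7, 5, "coprime"), (6, 6, "equal"), (10, 4, "general")]:
            t = random_table(rng, rx, ry)
            assert exact_pvalue(t).scenario == scen

    def test_minimal_arms(self):
        # r_x = r_y = 1: 9 outcomes, oracle by full enumeration
        for cells in [(1, 0, 0, 0, 1, 0), (0, 1, 0, 0, 1, 0), (0, 0, 1, 1, 0, 0)]:
            t = make_table(*cells)
            res = exact_pvalue(t, probs_mode="fixed",
                               fixed=((1 / 3, 1 / 3, 1 / 3), (1 / 3, 1 / 3, 1 / 3)))
            assert res.p_value == pytest.approx(
                brute_pvalue(t, UNIFORM), abs=1e-10
            )

    def test_swap_invariance(self):
        rng = np.random.default_rng(4)
        for rx, ry in [(7, 5), (6, 6), (10, 4)]:
            for _ in range(5):
                t = random_table(rng, rx, ry)
                a = exact_pvalue(t)
                b = exact_pvalue(t.swapped())
                assert b.p_value == pytest.approx(a.p_value, abs=1e-10)

    def test_p_bounds_and_f_obs(self):
        rng = np.random.default_rng(6)
        for rx, ry in [(7, 5), (8, 8), (10, 4)]:
            for _ in range(10):
                t = random_table(rng, rx, ry)
                res = exact_pvalue(t)
                assert 0.0 < res.p_value <= 1.0
                assert res.p_value >= res.f_obs - 1e-15

    def test_rejection_region_monotonicity(self):
        # On one pmf, a less probable observation never has a larger p-value.
        rng = np.random.default_rng(8)
        fixed = (tuple(rng.dirichlet([2, 2, 2])), tuple(rng.dirichlet([2, 2, 2])))
        results = []
        for _ in range(15):
            t = random_table(rng, 9, 7)
            res = exact_pvalue(t, probs_mode="fixed", fixed=fixed)
            results.append(res)
        results.sort(key=lambda r: r.f_obs)
        for a, b in zip(results, results[1:]):
            assert a.p_value <= b.p_value + 1e-10

    def test_cell_budget(self):
        t = make_table(400, 300, 300, 400, 300, 300)
        with pytest.raises(ResourceError):
            exact_pvalue(t, max_cells=1e6)

    def test_determinism(self, enos_table):
        a = exact_pvalue(enos_table)
        b = exact_pvalue(enos_table)
        assert a.p_value == b.p_value  # bit-identical


class TestLevelControl:
    def test_pooled_null_level(self):
        # Under a pooled-null multinomial simulation the exact test holds
        # its level up to discreteness and Monte-Carlo error.
        rng = np.random.default_rng(2024)
        r = 30
        pi = (0.36, 0.48, 0.16)  # HWE at MAF 0.4
        n_sims = 4000
        pvals = np.empty(n_sims)
        for i in range(n_sims):
            x = rng.multinomial(r, pi)
            y = rng.multinomial(r, pi)
            # skip tables with an empty arm (cannot happen here: arms fixed)
            t = make_table(*x.tolist(), *y.tolist())
            pvals[i] = exact_pvalue(t).p_value
        for alpha in (0.01, 0.05):
            rate = float(np.mean(pvals <= alpha))
            se = math.sqrt(max(rate, alpha) * (1 - min(rate, alpha)) / n_sims)
            assert rate <= alpha + 3 * se
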