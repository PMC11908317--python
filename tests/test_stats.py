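"""Statistical procedures checked against exact/permutation oracles.

Every oracle here is an independent re-derivation: exact Fraction
arithmetic over hypergeometric enumerations for Fisher's test, full
permutation enumeration for the Mann-Whitney U test, the definitional
step-up formula for Benjamini-Hochberg, hand-tabulated risk tables for the
logrank test, and the closed-form t statistic.  None of them call the
implementation path they check.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from phenogpc import (
    MtcMethod,
    adjust_pvalues,
    fisher_exact,
    logrank,
    mann_whitney_u,
    t_test,
)

TOL = Fraction(10**7 + 1, 10**7)  # same boundary tolerance the test uses


# -- oracles -------------------------------------------------------------


def fet_2x2_oracle(table):
    """Two-sided Fisher p by exact hypergeometric enumeration (Fractions)."""
    (a, b), (c, d) = table
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d

    def pmf(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return Fraction(0)
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))

    p0 = pmf(a)
    return float(sum(p for x in range(min(r1, c1) + 1) if (p := pmf(x)) <= p0 * TOL))


def freeman_halton_oracle(rows):
    """k x 2 exact p by full margin-preserving table enumeration (Fractions)."""
    r = [sum(row) for row in rows]
    c1 = sum(row[0] for row in rows)
    denom = math.comb(sum(r), c1)

    def prob(xs):
        return Fraction(math.prod(math.comb(ri, xi) for ri, xi in zip(r, xs)), denom)

    p0 = prob([row[0] for row in rows])
    total = Fraction(0)

    def rec(i, remaining, xs):
        nonlocal total
        if i == len(r) - 1:
            if 0 <= remaining <= r[i]:
                p = prob(xs + [remaining])
                if p <= p0 * TOL:
                    total += p
            return
        for x in range(min(r[i], remaining) + 1):
            rec(i + 1, remaining - x, xs + [x])

    rec(0, c1, [])
    return float(total)


def mwu_permutation_oracle(a, b):
    """Two-sided exact MWU p by enumerating every split of the pooled sample."""
    pooled = list(a) + list(b)
    n = len(a)

    def u_stat(xs, ys):
        return sum(1.0 for x in xs for y in ys if x > y) + 0.5 * sum(
            1 for x in xs for y in ys if x == y
        )

    u_obs = u_stat(a, b)
    us = [
        u_stat([pooled[i] for i in comb], [pooled[i] for i in range(len(pooled)) if i not in comb])
        for comb in itertools.combinations(range(len(pooled)), n)
    ]
    ge = sum(1 for u in us if u >= u_obs - 1e-12)
    le = sum(1 for u in us if u <= u_obs + 1e-12)
    return min(1.0, 2 * min(ge, le) / len(us))


def bh_stepup_oracle(p):
    """Definitional BH: q_(i) = min_{j>=i} (m p_(j) / j), clipped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


def logrank_oracle(da, ea, db, eb):
    """Chi-square from a hand-built risk table with hypergeometric variance."""
    event_times = sorted({t for t, e in zip(list(da) + list(db), list(ea) + list(eb)) if e})
    o1 = e1 = v = 0.0
    for t in event_times:
        n1 = sum(1 for x in da if x >= t)
        n2 = sum(1 for x in db if x >= t)
        d1 = sum(1 for x, e in zip(da, ea) if e and x == t)
        d2 = sum(1 for x, e in zip(db, eb) if e and x == t)
        d, n = d1 + d2, n1 + n2
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (o1 - e1) ** 2 / v


# -- Fisher exact --------------------------------------------------------


class TestFisherExact:
    def test_symmetric_table_is_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_degenerate_margin_is_one_by_convention(self):
        assert fisher_exact([[0, 0], [3, 4]]) == 1.0
        assert fisher_exact([[0, 3], [0, 4]]) == 1.0

    def test_2x2_matches_enumeration_oracle(self):
        rng = np.random.default_rng(20240601)
        checked = 0
        while checked < 200:
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum() > 40 or t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
                continue
            expected = fet_2x2_oracle(t.tolist())
            assert fisher_exact(t) == pytest.approx(expected, rel=1e-9)
            checked += 1

    def test_3x2_matches_freeman_halton_oracle(self):
        rng = np.random.default_rng(20240602)
        checked = 0
        while checked < 200:
            t = rng.integers(0, 8, size=(3, 2))
            if t.sum() > 40 or t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
                continue
            expected = freeman_halton_oracle(t.tolist())
            assert fisher_exact(t) == pytest.approx(expected, rel=1e-9)
            checked += 1

    def test_2x2_agrees_with_freeman_halton_path(self):
        """The k x 2 enumeration restricted to k=2 equals the 2x2 path."""
        from phenogpc.stats import _freeman_halton_kx2

        rng = np.random.default_rng(20240603)
        checked = 0
        while checked < 200:
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
                continue
            assert fisher_exact(t) == pytest.approx(
                _freeman_halton_kx2(np.asarray(t)), rel=1e-7
            )
            checked += 1

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])  # k x 3 not supported
        with pytest.raises(ValueError):
            fisher_exact([[-1, 2], [3, 4]])


# -- multiple-testing correction -----------------------------------------


class TestAdjustPvalues:
    def test_single_p_is_identity_under_bh(self):
        assert adjust_pvalues([0.04], MtcMethod.BH) == [pytest.approx(0.04)]

    def test_bh_hand_case(self):
        # step-up on (0.01, 0.02, 0.03, 0.04): q_i = min_j>=i 4 p_(j)/j = 0.04 each
        assert adjust_pvalues([0.01, 0.02, 0.03, 0.04], MtcMethod.BH) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_bh_matches_definitional_stepup_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            p = rng.random(rng.integers(1, 25)).tolist()
            assert adjust_pvalues(p, MtcMethod.BH) == pytest.approx(bh_stepup_oracle(p))

    def test_bonferroni_dominates_holm_dominates_raw(self):
        rng = np.random.default_rng(8)
        p = rng.random(15).tolist()
        bonf = adjust_pvalues(p, MtcMethod.BONFERRONI)
        holm = adjust_pvalues(p, MtcMethod.HOLM)
        for pb, ph, pr in zip(bonf, holm, p):
            assert pb >= ph - 1e-12 >= 0
            assert ph >= pr - 1e-12

    def test_bh_monotone_in_rank_order(self):
        rng = np.random.default_rng(9)
        p = sorted(rng.random(20))
        q = adjust_pvalues(p, MtcMethod.BH)
        assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(q, q[1:]))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2])

    def test_none_method_is_identity(self):
        assert adjust_pvalues([0.3, 0.01], MtcMethod.NONE) == [0.3, 0.01]

    def test_all_named_methods_available(self):
        p = [0.01, 0.2, 0.5]
        for method in MtcMethod:
            out = adjust_pvalues(p, method)
            assert len(out) == 3 and all(0 <= x <= 1 for x in out)


# -- Mann-Whitney U ------------------------------------------------------


class TestMannWhitneyU:
    def test_identical_multisets_p_one(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_disjoint_small_samples_attain_minimal_exact_p(self):
        # n=m=3: C(6,3)=20 splits; extreme split has two-sided p = 2/20
        _, p = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(2 / 20)

    def test_exact_regime_matches_permutation_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            n, m = rng.integers(2, 7), rng.integers(2, 7)
            vals = rng.permutation(100)[: n + m].astype(float)  # distinct: no ties
            a, b = list(vals[:n]), list(vals[n:])
            _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(mwu_permutation_oracle(a, b), abs=1e-9)

    def test_nan_scores_dropped(self):
        res_with_nan = mann_whitney_u([1.0, 2.0, float("nan")], [3.0, 4.0])
        res_clean = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert res_with_nan == res_clean

    def test_empty_group_not_performed(self):
        assert mann_whitney_u([float("nan")], [1.0, 2.0]) is None

    def test_order_invariance(self):
        a, b = [3.0, 1.0, 5.0, 2.0], [4.0, 9.0, 0.5]
        assert mann_whitney_u(a, b)[1] == mann_whitney_u(a[::-1], b[::-1])[1]


# -- t-test --------------------------------------------------------------


class TestTTest:
    def test_identical_groups(self):
        t, p = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_hand_computation(self):
        # a=(1,2,3), b=(2,4,6): means 2, 4; s2p = (2+8)/4 = 2.5
        # t = -2 / sqrt(2.5 * (2/3)) = -1.549193...
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        t, p = t_test(a, b)
        expected_t = -2 / math.sqrt(2.5 * (2 / 3))
        assert t == pytest.approx(expected_t, rel=1e-12)
        from scipy.stats import t as tdist

        assert p == pytest.approx(2 * tdist.sf(abs(expected_t), df=4), rel=1e-12)

    def test_scale_invariance(self):
        a, b = [1.0, 2.5, 3.0, 4.0], [2.0, 4.0, 6.0]
        t1, _ = t_test(a, b)
        t2, _ = t_test([7 * x for x in a], [7 * x for x in b])
        assert t1 == pytest.approx(t2)

    def test_zero_variance_equal_means(self):
        assert t_test([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_undersized_group_not_performed(self):
        assert t_test([1.0], [2.0, 3.0]) is None


# -- logrank -------------------------------------------------------------


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        chi2, p = logrank([1, 2, 3], [1, 1, 0], [1, 2, 3], [1, 1, 0])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_toy_hand_computation(self):
        # A events at 1, 2; B events at 3, 4; no censoring
        chi2, _ = logrank([1, 2], [1, 1], [3, 4], [1, 1])
        assert chi2 == pytest.approx(logrank_oracle([1, 2], [1, 1], [3, 4], [1, 1]), rel=1e-9)

    def test_censoring_only_group_risk_sets(self):
        # group A contributes only censored individuals; the one still at
        # risk when B's first event occurs must appear in the risk set
        da, ea = [1.0, 2.0, 6.0], [0, 0, 0]
        db, eb = [4.0, 5.0], [1, 1]
        chi2, _ = logrank(da, ea, db, eb)
        assert chi2 == pytest.approx(logrank_oracle(da, ea, db, eb), rel=1e-9)

    def test_random_samples_match_risk_table_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            na, nb = rng.integers(3, 10), rng.integers(3, 10)
            da = rng.integers(1, 15, size=na).astype(float)
            db = rng.integers(1, 15, size=nb).astype(float)
            ea = rng.random(na) < 0.7
            eb = rng.random(nb) < 0.7
            if not (ea.any() or eb.any()):
                continue
            chi2, _ = logrank(da, ea, db, eb)
            assert chi2 == pytest.approx(logrank_oracle(da, ea, db, eb), rel=1e-6)

    def test_no_events_not_performed(self):
        assert logrank([1, 2], [0, 0], [3], [0]) is None

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            logrank([0.0, 2.0], [1, 1], [3.0], [1])
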