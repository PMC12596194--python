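"""Statistical battery: TOST equivalence, Spearman, concurrence rate,
regression, ANOVA — each checked against an independent oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from patflow.stats import (
    concurrence_rate,
    oneway_anova,
    ols_regression,
    spearman,
    tost_paired,
)


# ---------------------------------------------------------------- oracles
def t_tail_quadrature(t_val, df, upper=True):
    """One-sided Student-t tail probability via numerical quadrature."""

    def pdf(x):
        c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    if upper:
        val, _ = integrate.quad(pdf, t_val, np.inf, epsabs=1e-13, epsrel=1e-13)
    else:
        val, _ = integrate.quad(pdf, -np.inf, t_val, epsabs=1e-13, epsrel=1e-13)
    return val


def midranks(x):
    """Brute-force mid-rank assignment (average rank over ties)."""
    x = np.asarray(x, dtype=float)
    out = np.empty(x.size)
    for i, v in enumerate(x):
        less = np.sum(x < v)
        eq = np.sum(x == v)
        out[i] = less + (eq + 1) / 2.0
    return out


def fixed_vector(n=25, mean=1.0, sd=5.0):
    base = np.arange(n, dtype=float)
    base = (base - base.mean()) / base.std(ddof=1)
    return mean + sd * base


# ---------------------------------------------------------------- TOST
class TestTOST:
    def test_point_mass_at_center_equivalent(self):
        d = np.zeros(10)
        res = tost_paired(d, np.zeros(10))
        assert res.p1 == 0.0 and res.p2 == 0.0 and res.equivalent

    def test_mean_exactly_at_margin_not_equivalent(self):
        icpat = fixed_vector(20, mean=5.0, sd=2.0)
        res = tost_paired(icpat, np.zeros(20), margin=5.0)
        assert res.p2 == pytest.approx(0.5, abs=1e-12)
        assert not res.equivalent

    def test_pvalues_match_quadrature_oracle(self):
        d = fixed_vector(25, mean=1.0, sd=5.0)
        res = tost_paired(d, np.zeros(25), margin=5.0)
        se = 5.0 / math.sqrt(25)
        p1_oracle = t_tail_quadrature((1.0 + 5.0) / se, 24, upper=True)
        p2_oracle = t_tail_quadrature((1.0 - 5.0) / se, 24, upper=False)
        assert res.p1 == pytest.approx(p1_oracle, abs=1e-10)
        assert res.p2 == pytest.approx(p2_oracle, abs=1e-10)

    def test_type_one_error_at_margin(self):
        # true mean at +margin: equivalence declared ~ alpha of the time
        rng = np.random.default_rng(2024)
        n, reps = 20, 10_000
        d = rng.normal(5.0, 5.0, size=(reps, n))
        means = d.mean(axis=1)
        sds = d.std(axis=1, ddof=1)
        se = sds / math.sqrt(n)
        from scipy import stats as ss

        p1 = ss.t.sf((means + 5.0) / se, df=n - 1)
        p2 = ss.t.cdf((means - 5.0) / se, df=n - 1)
        # cross-check vectorised computation against the package on a few draws
        for i in (0, 117, 9_999):
            res = tost_paired(d[i], np.zeros(n), margin=5.0)
            assert res.p1 == pytest.approx(p1[i]) and res.p2 == pytest.approx(p2[i])
        rate = np.mean((p1 < 0.05) & (p2 < 0.05))
        assert 0.04 <= rate <= 0.06

    def test_power_monotone_in_true_mean(self):
        rng = np.random.default_rng(7)
        n, reps = 20, 20_000
        noise = rng.normal(0.0, 5.0, size=(reps, n))
        rates = []
        for mu in (0.0, 1.25, 2.5, 3.75, 5.0):
            rejected = 0
            d = noise + mu
            means = d.mean(axis=1)
            se = d.std(axis=1, ddof=1) / math.sqrt(n)
            from scipy import stats as ss

            p1 = ss.t.sf((means + 5.0) / se, df=n - 1)
            p2 = ss.t.cdf((means - 5.0) / se, df=n - 1)
            rates.append(np.mean((p1 < 0.05) & (p2 < 0.05)))
        assert all(a >= b - 0.01 for a, b in zip(rates, rates[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            tost_paired(np.array([1.0, 2.0]), np.zeros(2))

    def test_degenerate_sd_outside_margin_not_equivalent(self):
        res = tost_paired(np.full(5, 7.0), np.zeros(5), margin=5.0)
        assert not res.equivalent and res.p2 == 1.0


# ---------------------------------------------------------------- Spearman
class TestSpearman:
    def test_perfect_antitone(self):
        rho, p = spearman([1, 2, 3], [3, 2, 1])
        assert rho == pytest.approx(-1.0) and p == 0.0

    def test_ties_midrank(self):
        rho, _ = spearman([1, 2, 2, 4], [10, 20, 20, 40])
        assert rho == pytest.approx(1.0)

    def test_identity_permutation(self, rng):
        x = rng.permutation(np.arange(1, 9)).astype(float)
        rho, _ = spearman(x, x)
        assert rho == pytest.approx(1.0)

    def test_matches_bruteforce_midrank_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(4, 51))
            x = rng.integers(0, 10, n).astype(float)  # ties likely
            y = rng.integers(0, 10, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman(x, y)
            oracle = np.corrcoef(midranks(x), midranks(y))[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_constant_vector_undefined(self):
        rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(rho) and math.isnan(p)

    def test_exact_permutation_small_n(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        rho, p_exact = spearman(x, y, method="exact")
        # oracle: count permutations with |rho| >= observed among all 720
        import itertools

        rx = midranks(x)
        obs = np.corrcoef(rx, midranks(y))[0, 1]
        count = 0
        for perm in itertools.permutations(midranks(y)):
            if abs(np.corrcoef(rx, perm)[0, 1]) >= abs(obs) - 1e-12:
                count += 1
        assert p_exact == pytest.approx(count / math.factorial(6))


# ---------------------------------------------------------------- CCR
class TestConcurrenceRate:
    def test_all_opposite(self):
        res = concurrence_rate([5.0, -3.0], [-4.0, 2.0])
        assert res.ccr == 1.0

    def test_zeros_stay_in_denominator(self):
        res = concurrence_rate([5.0, -3.0, 2.0, 0.0], [-4.0, 2.0, 1.0, -1.0])
        assert res.ccr == pytest.approx(0.5)
        assert res.n_total == 4 and res.n_opposite == 2

    def test_exact_mirror(self, rng):
        d = rng.normal(size=50)
        d = d[d != 0]
        assert concurrence_rate(d, -d).ccr == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 30))
            a = rng.integers(-2, 3, n).astype(float)
            b = rng.integers(-2, 3, n).astype(float)
            n_opp = sum(
                1 for x, y in zip(a, b) if (x > 0 and y < 0) or (x < 0 and y > 0)
            )
            res = concurrence_rate(a, b)
            assert res.n_opposite == n_opp and res.n_total == n

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.integers(-3, 3), min_size=1, max_size=30),
        st.integers(0, 2**31 - 1),
    )
    def test_sign_and_argument_symmetry(self, a_list, seed):
        rng = np.random.default_rng(seed)
        a = np.array(a_list, dtype=float)
        b = rng.integers(-3, 4, a.size).astype(float)
        base = concurrence_rate(a, b).ccr
        assert concurrence_rate(-a, -b).ccr == base
        assert concurrence_rate(b, a).ccr == base

    def test_drop_zeros_sensitivity(self):
        res = concurrence_rate([5.0, 0.0], [-4.0, 3.0], drop_zeros=True)
        assert res.n_total == 1 and res.ccr == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            concurrence_rate([], [])

    def test_subgroup_restriction(self):
        mask = np.array([True, False, True])
        res = concurrence_rate([5.0, 1.0, -2.0], [-1.0, 1.0, 3.0], subgroup_mask=mask)
        assert res.n_total == 2 and res.ccr == 1.0


# ---------------------------------------------------------------- regression
class TestOLS:
    def test_exact_line(self):
        import pandas as pd

        x = np.arange(10, dtype=float)
        res = ols_regression(2 * x, pd.DataFrame({"x": x}))
        assert res.params["x"] == pytest.approx(2.0, abs=1e-10)
        assert res.params["const"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equation_oracle(self):
        import pandas as pd

        rng = np.random.default_rng(5)
        n = 12
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = 1.5 + 2.0 * X["a"].to_numpy() - 0.7 * X["b"].to_numpy() + rng.normal(0, 0.5, n)
        res = ols_regression(y, X)
        D = np.column_stack([np.ones(n), X["a"], X["b"]])
        beta = np.linalg.inv(D.T @ D) @ D.T @ y
        resid = y - D @ beta
        sigma2 = resid @ resid / (n - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(D.T @ D)))
        for i, name in enumerate(["const", "a", "b"]):
            assert res.params[name] == pytest.approx(beta[i], abs=1e-10)
            assert res.bse[name] == pytest.approx(se[i], abs=1e-10)

    def test_irrelevant_covariate_keeps_slope(self):
        import pandas as pd

        rng = np.random.default_rng(42)
        n = 200
        x = rng.normal(size=n)
        y = 3.0 * x + rng.normal(0, 1.0, n)
        uni = ols_regression(y, pd.DataFrame({"x": x}))
        adj = ols_regression(y, pd.DataFrame({"x": x, "z": rng.normal(size=n)}))
        ci = 1.96 * uni.bse["x"]
        assert abs(adj.params["x"] - uni.params["x"]) < ci

    def test_collinear_rejected_with_names(self):
        import pandas as pd

        x = np.arange(10, dtype=float)
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="x2"):
            ols_regression(x, X)


# ---------------------------------------------------------------- ANOVA
class TestANOVA:
    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0])
        f, p = oneway_anova([g, g.copy(), g.copy()])
        assert f == 0.0 and p == 1.0

    def test_hand_computed_f(self):
        f, p = oneway_anova(
            [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([3.0, 4, 5])]
        )
        # SSB = 3*((2-3)^2+(3-3)^2+(4-3)^2) = 6; SSW = 6; F = (6/2)/(6/6) = 3
        assert f == pytest.approx(3.0)
        from scipy import stats as ss

        assert p == pytest.approx(ss.f.sf(3.0, 2, 6))

    def test_large_shift_tiny_p(self, rng):
        base = rng.normal(0, 1, 30)
        f, p = oneway_anova([base, base + 0.1, base + 100.0])
        assert p < 1e-6

    def test_degenerate_zero_variance_identical_means(self):
        f, p = oneway_anova([np.array([5.0, 5.0]), np.array([5.0, 5.0])])
        assert f == 0.0 and p == 1.0

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            oneway_anova([np.array([1.0, 2.0])])
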