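"""Statistics: published-value reproduction, brute-force oracles,
bounds and invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import quasicw as q

# --- independent oracles -------------------------------------------------


def cii_bruteforce(obs, calc):
    """Naive n-pass recomputation of the correlation intensity index."""
    obs, calc = np.asarray(obs, float), np.asarray(calc, float)
    full = np.corrcoef(obs, calc)[0, 1] ** 2
    protests = 0.0
    for k in range(len(obs)):
        o = np.delete(obs, k)
        c = np.delete(calc, k)
        rk = np.corrcoef(o, c)[0, 1] ** 2
        if rk - full > 0:
            protests += rk - full
    return 1.0 - protests


def q2_refit_loop(x, y):
    """Explicit leave-one-out refit of the simple regression."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    press = 0.0
    for k in range(len(x)):
        xs, ys = np.delete(x, k), np.delete(y, k)
        b1 = np.sum((xs - xs.mean()) * (ys - ys.mean())) / np.sum(
            (xs - xs.mean()) ** 2
        )
        b0 = ys.mean() - b1 * xs.mean()
        press += (y[k] - (b0 + b1 * x[k])) ** 2
    return 1.0 - press / np.sum((y - y.mean()) ** 2)


def _series(seed, n):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = 2 * x + rng.normal(scale=0.8, size=n)
    return y, 2 * x


# --- published split-1 values -------------------------------------------


def test_published_set_statistics_reproduce(set_series):
    """Observed vs published-calculated viability under the published
    split-1 labels reproduces the published summary statistics."""
    a_obs, a_calc = set_series["A"]
    c_obs, c_calc = set_series["C"]
    v_obs, v_calc = set_series["V"]
    assert q.r2(a_obs, a_calc) == pytest.approx(0.7094, abs=0.0005)
    assert q.ccc(a_obs, a_calc) == pytest.approx(0.8300, abs=0.0005)
    assert q.q2_loo(a_calc, a_obs) == pytest.approx(0.6683, abs=0.001)
    assert q.f_ratio(q.r2(a_obs, a_calc), len(a_obs)) == pytest.approx(66, abs=0.5)
    assert q.iic(c_obs, c_calc) == pytest.approx(0.7500, abs=0.0005)
    assert q.cii(c_obs, c_calc) == pytest.approx(0.7744, abs=0.0005)
    assert q.r2(v_obs, v_calc) == pytest.approx(0.7226, abs=0.0005)


def test_published_rmse_truncates_to_printed_decimals(set_series):
    """The published table truncates RMSE to one decimal; the sample
    (n-1) denominator matches all four set values simultaneously."""
    printed = {"A": 19.6, "P": 21.5, "C": 12.9, "V": 13.7}
    for lab, value in printed.items():
        obs, calc = set_series[lab]
        assert math.floor(q.rmse(obs, calc) * 10) / 10 == pytest.approx(value)


# --- elementary identities ----------------------------------------------


def test_identical_vectors_are_perfect():
    v = np.array([1.0, 2.0, 5.0, 7.0])
    assert q.r2(v, v) == pytest.approx(1.0)
    assert q.ccc(v, v) == pytest.approx(1.0)
    assert q.rmse(v, v) == 0.0
    assert q.iic(v, v) == 1.0


def test_ccc_reversed_concordance_is_minus_one():
    o = np.array([1.0, 2.0, 3.0, 4.0])
    c = -o + (o.mean() * 2)  # mirrored about the mean: matched moments
    assert q.ccc(o, c) == pytest.approx(-1.0)


def test_f_ratio_direct_substitution():
    assert q.f_ratio(0.5, 4) == pytest.approx(2.0)
    assert q.f_ratio(0.0, 10) == 0.0
    with pytest.raises(q.UndefinedStatisticError):
        q.f_ratio(1.0, 10)


def test_iic_balanced_errors_equal_r():
    o = np.array([1.0, 2.0, 3.0, 4.0])
    c = o + np.array([-0.5, 0.5, -0.5, 0.5])
    assert q.iic(o, c) == pytest.approx(q.pearson_r(o, c))


def test_iic_one_sided_errors_give_zero():
    o = np.array([1.0, 2.0, 3.0, 4.0])
    c = o - 0.5  # every residual positive
    assert q.iic(o, c) == 0.0


def test_cii_collinear_data_is_one():
    x = np.linspace(0, 1, 8)
    assert q.cii(3 * x + 1, x) == pytest.approx(1.0)


def test_r2_zero_variance_raises():
    with pytest.raises(q.UndefinedStatisticError):
        q.r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_exactly_linear_data_has_q2_one():
    x = np.arange(10.0)
    assert q.q2_loo(x, 3 * x - 2) == pytest.approx(1.0, abs=1e-12)


# --- oracle agreement ----------------------------------------------------


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_cii_matches_bruteforce_oracle(seed):
    obs, calc = _series(seed, 10)
    assert q.cii(obs, calc) == pytest.approx(cii_bruteforce(obs, calc), abs=1e-12)


@pytest.mark.parametrize("seed", [10, 11, 12])
def test_q2_hat_matrix_matches_refit_loop(seed):
    obs, calc = _series(seed, 12)
    assert q.q2_loo(calc, obs) == pytest.approx(q2_refit_loop(calc, obs), abs=1e-12)


def test_pearson_agrees_with_scipy(set_series):
    from scipy.stats import pearsonr

    obs, calc = set_series["A"]
    assert q.pearson_r(obs, calc) == pytest.approx(
        pearsonr(obs, calc).statistic, abs=1e-12
    )


# --- invariants (property tests) ----------------------------------------

finite_floats = st.floats(
    min_value=-100, max_value=100, allow_nan=False, allow_infinity=False
)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(finite_floats, finite_floats), min_size=4, max_size=25
    ).filter(
        lambda pts: np.std([p[0] for p in pts]) > 1e-6
        and np.std([p[1] for p in pts]) > 1e-6
    )
)
def test_metric_bounds_and_permutation_invariance(points):
    obs = np.array([p[0] for p in points])
    calc = np.array([p[1] for p in points])
    r = q.pearson_r(obs, calc)
    assert abs(q.iic(obs, calc)) <= abs(r) + 1e-12
    assert -1 - 1e-12 <= q.ccc(obs, calc) <= 1 + 1e-12
    try:
        c = q.cii(obs, calc)
        assert c <= 1 + 1e-12
    except q.UndefinedStatisticError:
        c = None
    perm = np.random.default_rng(0).permutation(len(obs))
    assert q.r2(obs[perm], calc[perm]) == pytest.approx(r**2, abs=1e-9)
    assert q.iic(obs[perm], calc[perm]) == pytest.approx(q.iic(obs, calc), abs=1e-9)
    if c is not None:
        assert q.cii(obs[perm], calc[perm]) == pytest.approx(c, abs=1e-9)


def test_cii_invariant_under_affine_rescaling():
    obs, calc = _series(3, 15)
    base = q.cii(obs, calc)
    assert q.cii(2.5 * obs - 7, 2.5 * calc - 7) == pytest.approx(base, abs=1e-10)


def test_q2_close_to_r2_on_wellconditioned_fixture(set_series):
    obs, calc = set_series["A"]
    assert q.q2_loo(calc, obs) <= q.r2(obs, calc) + 0.02


def test_set_statistics_bundles_all_columns(set_series):
    obs, calc = set_series["C"]
    stats = q.set_statistics(obs, calc)
    assert stats.n == 29
    assert stats.iic == pytest.approx(0.7500, abs=0.0005)
    assert 0 <= stats.r2 <= 1
    assert stats.rmse >= 0
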