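"""SAEM building blocks: samplers, sufficient statistics, M-step, loop."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import chisquare

from rcsaem.grid_spline import build_grid, discretized_normal, ramsay_pdf
from rcsaem.irt_core import ItemSet, ResponseMatrix, loglik_table, prob_correct
from rcsaem.saem_engine import (
    GainSchedule,
    ItemPriors,
    SAEMConfig,
    gain,
    identify_scale,
    mstep_items,
    run_saem,
    s1_sample_theta,
    s2_sample_w,
    s3_sample_z,
    sa_update,
    suffstats,
)
from rcsaem.synthesis import gen_responses


# ------------------------------------------------------------------ gain

def test_gain_schedule_values():
    sched = GainSchedule(burn=1000)
    assert gain(500, sched) == 1.0
    assert gain(1000, sched) == 1.0
    assert gain(1001, sched) == 1.0
    assert gain(1200, sched) == pytest.approx(0.005)
    ks = np.arange(1001, 3000)
    gs = np.array([gain(int(k), sched) for k in ks])
    assert np.all(np.diff(gs) < 0) and np.all((gs > 0) & (gs <= 1))


# --------------------------------------------------------------- S-steps

def test_s1_flat_likelihood_recovers_prior(basis63, rng):
    """With saturated guessing the likelihood is flat, so theta ~ g."""
    grid = basis63.grid
    density = ramsay_pdf(basis63, np.concatenate([np.zeros(4), [2.0, 3.0, 2.0, 0.0]]))
    n = 100_000
    table = np.zeros((n, grid.Q))  # flat likelihood
    idx = s1_sample_theta(table, density, rng)
    observed = np.bincount(idx, minlength=grid.Q)
    keep = density.g * n >= 5  # chi-square validity
    stat = chisquare(observed[keep], density.g[keep] / density.g[keep].sum()
                     * observed[keep].sum())
    assert stat.pvalue > 0.01


def test_s1_two_point_hand_posterior(rng):
    grid = build_grid(-1, 1, 2.0)  # two grid points
    item = ItemSet(a=np.array([1.0]), b=np.array([0.0]), c=np.array([0.2]))
    g = np.array([0.3, 0.7])
    p_correct = np.array([prob_correct(item[0], x) for x in grid.points])
    post = p_correct * g
    post /= post.sum()
    n = 100_000
    U = ResponseMatrix(np.ones((n, 1), dtype=int))
    table = loglik_table(U, item, grid)
    idx = s1_sample_theta(table, g, rng)
    freq = idx.mean()  # fraction at the second grid point
    se = np.sqrt(post[1] * post[0] / n)
    assert abs(freq - post[1]) < 3 * se


def test_s1_reproducible_with_seed(basis63):
    grid = basis63.grid
    density = ramsay_pdf(basis63, np.zeros(basis63.m))
    table = np.random.default_rng(3).normal(size=(50, grid.Q))
    i1 = s1_sample_theta(table, density, np.random.default_rng(11))
    i2 = s1_sample_theta(table, density, np.random.default_rng(11))
    assert np.array_equal(i1, i2)


def test_s2_zero_response_forces_w_zero(rng):
    items = ItemSet(a=np.ones(4), b=np.zeros(4), c=np.full(4, 0.2))
    U = ResponseMatrix(np.zeros((50, 4), dtype=int))
    w = s2_sample_w(U, items, rng.normal(size=50), rng)
    assert np.all(w == 0)


def test_s2_knowing_probability(rng):
    # u = 1, Phi = 0.5 (theta = 0, b = 0), c = 0.5 -> P(w=1) = 2/3
    n = 100_000
    items = ItemSet(a=np.array([1.0]), b=np.array([0.0]), c=np.array([0.5]))
    U = ResponseMatrix(np.ones((n, 1), dtype=int))
    w = s2_sample_w(U, items, np.zeros(n), rng)
    p = 2.0 / 3.0
    assert abs(w.mean() - p) < 3 * np.sqrt(p * (1 - p) / n)


def test_s2_small_guessing_makes_w_one(rng):
    n = 10_000
    items = ItemSet(a=np.array([1.0]), b=np.array([0.0]), c=np.array([1e-9]))
    U = ResponseMatrix(np.ones((n, 1), dtype=int))
    w = s2_sample_w(U, items, np.zeros(n), rng)
    assert w.mean() > 0.999


def test_s3_signs_match_w(rng):
    items = ItemSet(a=np.ones(3), b=np.array([-0.5, 0.0, 0.5]),
                    c=np.full(3, 0.2))
    theta = rng.normal(size=200)
    w = rng.integers(0, 2, size=(200, 3)).astype(np.int8)
    z = s3_sample_z(items, theta, w, rng)
    assert np.all(z[w == 1] > 0)
    assert np.all(z[w == 0] <= 0)


def test_s3_truncated_mean_formula(rng):
    """Sample mean of N(mu,1) truncated to (0, inf) is mu + phi(mu)/Phi(mu)."""
    n = 100_000
    for mu in (0.0, 5.0):
        items = ItemSet(a=np.array([1.0]), b=np.array([mu]),
                        c=np.array([0.2]))
        theta = np.zeros(n)
        w = np.ones((n, 1), dtype=np.int8)
        z = s3_sample_z(items, theta, w, rng)
        phi = np.exp(-0.5 * mu**2) / np.sqrt(2 * np.pi)
        expected = mu + phi / ndtr(mu)
        # truncated-normal variance <= 1
        assert abs(z.mean() - expected) < 3 / np.sqrt(n)


# ----------------------------------------------------- suffstats and SA

def test_suffstats_hand_example():
    theta = np.array([1.0, -1.0])
    z = np.array([[0.5], [-0.2]])
    w = np.array([[1], [0]], dtype=np.int8)
    U = ResponseMatrix(np.array([[1], [0]]))
    s = suffstats(theta, z, w, U)
    assert np.allclose(s.s1[0], [[2.0, 0.0], [0.0, 2.0]])
    assert np.allclose(s.s2[:, 0], [0.7, 0.3])
    assert s.s3[0] == 1.0 and s.s4[0] == 0.0


def test_suffstats_matches_scalar_loop(rng):
    N, J = 17, 5
    theta = rng.normal(size=N)
    z = rng.normal(size=(N, J))
    w = rng.integers(0, 2, size=(N, J)).astype(np.int8)
    U = ResponseMatrix(rng.integers(0, 2, size=(N, J)))
    s = suffstats(theta, z, w, U)
    for j in range(J):
        assert s.s1[j][0, 0] == pytest.approx(sum(t * t for t in theta))
        assert s.s1[j][0, 1] == pytest.approx(theta.sum())
        assert s.s2[0, j] == pytest.approx(sum(theta[i] * z[i, j]
                                               for i in range(N)))
        assert s.s2[1, j] == pytest.approx(z[:, j].sum())
        assert s.s3[j] == sum(1 - w[i, j] for i in range(N))
        assert s.s4[j] == sum((1 - w[i, j]) * U.u[i, j] for i in range(N))
    assert np.all(s.s4 <= s.s3) and np.all(s.s3 <= N)


def test_sa_update_is_convex_combination(rng):
    N, J = 8, 3
    def draw():
        return suffstats(rng.normal(size=N), rng.normal(size=(N, J)),
                         rng.integers(0, 2, (N, J)).astype(np.int8),
                         ResponseMatrix(rng.integers(0, 2, (N, J))))
    a, b = draw(), draw()
    out = sa_update(a, b, 1.0)
    assert np.allclose(out.s2, b.s2)
    half = sa_update(a, b, 0.5)
    assert np.allclose(half.s2, 0.5 * (a.s2 + b.s2))
    with pytest.raises(ValueError):
        sa_update(a, b, 0.0)


def test_sa_one_over_k_equals_running_mean(rng):
    """gamma_k = 1/k starting from the first draw reproduces the running
    arithmetic mean of the draws."""
    N, J = 6, 2
    draws = []
    state = None
    for k in range(1, 21):
        d = suffstats(rng.normal(size=N), rng.normal(size=(N, J)),
                      rng.integers(0, 2, (N, J)).astype(np.int8),
                      ResponseMatrix(rng.integers(0, 2, (N, J))))
        draws.append(d)
        state = d if state is None else sa_update(state, d, 1.0 / k)
    assert np.allclose(state.s2, np.mean([d.s2 for d in draws], axis=0))
    assert np.allclose(state.s3, np.mean([d.s3 for d in draws], axis=0))


# ---------------------------------------------------------------- M-step

def test_mstep_flat_prior_equals_ols(rng):
    N, J = 200, 4
    theta = rng.normal(size=N)
    z = rng.normal(size=(N, J))
    w = np.ones((N, J), dtype=np.int8)
    U = ResponseMatrix(np.ones((N, J), dtype=int))
    stats = suffstats(theta, z, w, U)
    items = mstep_items(stats, ItemPriors(), delta=1e-3)
    X = np.column_stack([theta, np.ones(N)])
    for j in range(J):
        coef, *_ = np.linalg.lstsq(X, z[:, j], rcond=None)
        if coef[0] > 0:
            assert items.a[j] == pytest.approx(coef[0], abs=1e-10)
        assert items.b[j] == pytest.approx(coef[1], abs=1e-10)


def test_mstep_beta_mode_and_delta_floor():
    from rcsaem.saem_engine import SuffStats

    s1 = np.broadcast_to(np.array([[150.0, 5.0], [5.0, 150.0]]), (2, 2, 2)).copy()
    # item 0: slope forced negative; item 1: c-mode arithmetic check
    s2 = np.array([[-400.0, 10.0], [3.0, 4.0]])
    stats = SuffStats(s1=s1, s2=s2, s3=np.array([100.0, 100.0]),
                      s4=np.array([20.0, 20.0]))
    items = mstep_items(stats, ItemPriors(alpha=5, beta=17), delta=1e-3,
                        c_estimator="mode")
    assert items.a[0] == pytest.approx(1e-3)  # positivity floor
    # alpha* = 25, beta* = 97 -> mode 24/120
    assert np.allclose(items.c, 24.0 / 120.0)
    mean_items = mstep_items(stats, ItemPriors(alpha=5, beta=17), delta=1e-3)
    assert np.allclose(mean_items.c, 25.0 / 122.0)  # posterior mean


def test_mstep_maximizes_complete_data_loglik(rng):
    """With gamma = 1 and flat priors the closed-form update matches a
    numerical maximizer of the complete-data log-likelihood."""
    N = 300
    theta = rng.normal(size=N)
    items_true = ItemSet(a=np.array([1.4, 0.9]), b=np.array([0.2, -0.5]),
                         c=np.array([0.2, 0.25]))
    U = gen_responses(theta, items_true, rng)
    w = s2_sample_w(U, items_true, theta, rng)
    z = s3_sample_z(items_true, theta, w, rng)
    stats = suffstats(theta, z, w, U)
    items = mstep_items(stats, ItemPriors(alpha=1.0 + 1e-9, beta=1.0 + 1e-9),
                        delta=1e-3, c_estimator="mode")

    for j in range(2):
        def neg_ll(p):
            a, b, c = p
            if not (0 < c < 1):
                return 1e12
            ll = -0.5 * np.sum((z[:, j] - a * theta - b) ** 2)
            n_guess = stats.s4[j]
            n_notknow = stats.s3[j]
            ll += n_guess * np.log(c) + (n_notknow - n_guess) * np.log(1 - c)
            return -ll

        ref = minimize(neg_ll, [1.0, 0.0, 0.2], method="Nelder-Mead",
                       options=dict(xatol=1e-9, fatol=1e-12, maxiter=10000))
        assert items.a[j] == pytest.approx(ref.x[0], abs=1e-5)
        assert items.b[j] == pytest.approx(ref.x[1], abs=1e-5)
        assert items.c[j] == pytest.approx(ref.x[2], abs=1e-4)


def test_identify_scale_algebra(rng):
    items = ItemSet(a=np.array([2.0]), b=np.array([1.0]), c=np.array([0.2]))
    out = identify_scale(items, theta_mean=0.5, theta_sd=2.0)
    assert out.a[0] == pytest.approx(4.0) and out.b[0] == pytest.approx(2.0)
    ident = identify_scale(items, 0.0, 1.0)
    assert np.allclose(ident.as_array(), items.as_array())
    # success probabilities are invariant under the paired transformation
    theta = rng.normal(size=20)
    mean, sd = 0.3, 1.7
    orig = prob_correct(items[0], theta)
    trans = prob_correct(identify_scale(items, mean, sd)[0],
                         (theta - mean) / sd)
    assert np.allclose(orig, trans, atol=1e-12)


# ------------------------------------------------------------- run_saem

@pytest.fixture(scope="module")
def tiny_responses():
    rng = np.random.default_rng(5150)
    items = ItemSet(a=rng.uniform(1, 2.5, 8), b=rng.normal(size=8),
                    c=rng.beta(5, 17, 8))
    theta = rng.normal(size=120)
    return gen_responses(theta, items, rng)


def test_run_saem_single_iteration_reports_no_convergence(tiny_responses):
    fit = run_saem(tiny_responses, knots=3, degree=3,
                   config=SAEMConfig(mode="rc", seed=1, max_iter=1))
    assert fit.iterations == 1 and not fit.converged
    assert fit.trajectory.shape == (1,)


def test_run_saem_reproducible(tiny_responses):
    cfg = SAEMConfig(mode="rc", seed=42, max_iter=40)
    f1 = run_saem(tiny_responses, knots=3, degree=3, config=cfg)
    f2 = run_saem(tiny_responses, knots=3, degree=3, config=cfg)
    assert np.array_equal(f1.items.as_array(), f2.items.as_array())
    assert np.array_equal(f1.eta, f2.eta)
    assert f1.marginal_loglik == f2.marginal_loglik


def test_run_saem_rejects_degenerate_items():
    u = np.ones((30, 3), dtype=int)
    u[:, 1] = np.random.default_rng(0).integers(0, 2, 30)
    with pytest.raises(ValueError):
        run_saem(ResponseMatrix(u), config=SAEMConfig(max_iter=2))


def test_run_saem_normal_mode_density_fixed(tiny_responses, grid):
    fit = run_saem(tiny_responses, config=SAEMConfig(mode="normal", seed=3,
                                                     max_iter=30))
    assert fit.eta is None
    assert np.allclose(fit.density, discretized_normal(grid))
    assert fit.n_params == 3 * tiny_responses.J


def test_run_saem_augmented_invariants_via_final_state(tiny_responses):
    # criteria dictionary is populated and finite
    fit = run_saem(tiny_responses, knots=3, degree=3,
                   config=SAEMConfig(mode="rc", seed=9, max_iter=25))
    assert np.isfinite(fit.marginal_loglik)
    assert fit.criteria["bic"] > fit.criteria["aic"]
    assert np.all(fit.items.a > 0)
    assert np.all((fit.items.c > 0) & (fit.items.c < 1))
    assert abs(fit.density.g.sum() - 1.0) < 1e-9
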