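"""Estimator correctness: likelihood stationarity, invariances, grid oracles."""

import numpy as np
import pytest

from eiwss import (METHODS, TwoSampleData, fit_joint, fit_lse_joint,
                   fit_mle_joint, fit_mle_single, fit_wlse_joint,
                   mle_standard_errors, make_fixture, uniform_spacings,
                   wls_weights)
from eiwss.estimators import _joint_loglik

MIN_DISTANCE = tuple(m for m in METHODS if m != "MLE")


# ---------------------------------------------------------------------------
# maximum likelihood


def _likelihood_gradient(data, p, h=1e-6):
    """Central-difference gradient of the joint log-likelihood (independent check)."""
    from eiwss import StressStrengthParams

    vals = np.array([p.theta1, p.theta2, p.beta])
    g = np.empty(3)
    for i in range(3):
        step = h * max(abs(vals[i]), 1.0)
        up, dn = vals.copy(), vals.copy()
        up[i] += step
        dn[i] -= step
        g[i] = (_joint_loglik(data, StressStrengthParams(*up))
                - _joint_loglik(data, StressStrengthParams(*dn))) / (2 * step)
    return g


@pytest.mark.parametrize("dataset_name, expected", [
    # frozen regression values; validated below by the stationarity conditions
    ("jute", (386.0612, 285.0976, 1.13321, 0.57522)),
    ("carbon", (103.9313, 30.6705, 4.57443, 0.77214)),
])
def test_joint_mle_is_stationary_point(dataset_name, expected, request):
    data = request.getfixturevalue(dataset_name)
    fit = fit_mle_joint(data)
    p = fit.params
    # scale equations hold exactly: theta_j = n / sum sample**-beta
    assert p.theta1 == pytest.approx(data.n / (data.x ** -p.beta).sum(), rel=1e-12)
    assert p.theta2 == pytest.approx(data.k / (data.y ** -p.beta).sum(), rel=1e-12)
    # full gradient vanishes (scaled by parameter magnitude)
    g = _likelihood_gradient(data, p)
    scale = np.array([p.theta1, p.theta2, p.beta])
    assert np.all(np.abs(g * scale) < 1e-4)
    assert fit.r_hat == p.theta1 / (p.theta1 + p.theta2)
    assert np.allclose([p.theta1, p.theta2, p.beta, fit.r_hat], expected, rtol=1e-4)


def test_joint_mle_symmetric_data_gives_half(jute):
    same = TwoSampleData(jute.x, jute.x.copy())
    assert fit_mle_joint(same).r_hat == pytest.approx(0.5, abs=1e-9)


def test_single_sample_mle(jute, carbon):
    fx = fit_mle_single(jute.x)
    # stationarity: theta = n / sum x**-beta at the fitted beta
    assert fx.params.theta == pytest.approx(
        jute.n / (jute.x ** -fx.params.beta).sum(), rel=1e-12)
    assert fx.params.theta == pytest.approx(491.6752, rel=1e-4)  # frozen
    assert fx.params.beta == pytest.approx(1.18336, rel=1e-4)
    # SE scale: hundreds for theta, ~0.15 for beta on this sample
    assert 100 < fx.se[0] < 800
    assert 0.05 < fx.se[1] < 0.4
    fy = fit_mle_single(carbon.y)
    assert fy.params.theta == pytest.approx(23.2618, rel=1e-4)
    assert fy.params.beta == pytest.approx(4.12673, rel=1e-4)


def test_single_sample_mle_scale_equivariance(jute):
    c = 5.7
    a = fit_mle_single(jute.x)
    b = fit_mle_single(c * jute.x)
    assert b.params.beta == pytest.approx(a.params.beta, rel=1e-8)
    assert b.params.theta == pytest.approx(a.params.theta * c ** a.params.beta, rel=1e-6)


def test_mle_standard_errors_properties(jute):
    from eiwss.estimators import _numerical_hessian
    fit = fit_mle_joint(jute)
    p0 = np.array([fit.params.theta1, fit.params.theta2, fit.params.beta])

    def nll(p):
        from eiwss import StressStrengthParams
        return -_joint_loglik(jute, StressStrengthParams(*p))

    H = _numerical_hessian(nll, p0)
    assert np.allclose(H, H.T, atol=1e-8 * np.abs(H).max())
    se = mle_standard_errors(jute, fit)
    assert all(s > 0 for s in se)


def test_mle_se_shrinks_at_root_n_rate():
    ses = {}
    for n in (500, 5000):
        ds = make_fixture(0.6, 0.45, 1.2, n, n, seed=5)
        data = TwoSampleData(ds.x, ds.y)
        fit = fit_mle_joint(data)
        ses[n] = np.array(mle_standard_errors(data, fit))
    ratio = ses[500] / ses[5000]
    assert np.all((ratio > 2.0) & (ratio < 5.0))  # sqrt(10) ~ 3.16


# ---------------------------------------------------------------------------
# shared invariants of all eight estimators


@pytest.mark.parametrize("method", METHODS)
def test_r_hat_identity_and_range(jute, method):
    fit = fit_joint(jute, method)
    p = fit.params
    assert fit.r_hat == p.theta1 / (p.theta1 + p.theta2)
    assert 0 < fit.r_hat < 1
    assert fit.converged


@pytest.mark.parametrize("method", METHODS)
def test_symmetric_samples_estimate_half(jute, method):
    same = TwoSampleData(jute.x, jute.x.copy())
    assert fit_joint(same, method).r_hat == pytest.approx(0.5, abs=1e-6)


@pytest.mark.parametrize("method", METHODS)
def test_label_swap_antisymmetry(jute, method):
    r = fit_joint(jute, method).r_hat
    r_swapped = fit_joint(jute.swapped(), method).r_hat
    assert r + r_swapped == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("method", ["MLE", "MPSE"])
def test_scale_equivariance(jute, method):
    c = 7.3
    a = fit_joint(jute, method)
    b = fit_joint(TwoSampleData(c * jute.x, c * jute.y), method)
    assert b.params.beta == pytest.approx(a.params.beta, abs=1e-6)
    assert b.r_hat == pytest.approx(a.r_hat, abs=1e-6)
    assert b.params.theta1 == pytest.approx(
        a.params.theta1 * c ** a.params.beta, rel=1e-5)


def test_wlse_with_unit_weights_reduces_to_lse(jute):
    w = fit_wlse_joint(jute, unit_weights=True)
    l = fit_lse_joint(jute)
    assert w.params.theta1 == pytest.approx(l.params.theta1, rel=1e-8)
    assert w.params.beta == pytest.approx(l.params.beta, rel=1e-8)


# ---------------------------------------------------------------------------
# spacing helpers


def test_spacings_sum_to_one_and_weights_symmetric(jute):
    xs = np.sort(jute.x)
    for theta, beta in [(0.1, 0.5), (386.06, 1.133), (1e4, 3.0)]:
        d = uniform_spacings(xs, theta, beta)
        assert d.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(d >= 0)
    w = wls_weights(9)
    assert np.allclose(w, w[::-1])
    assert np.all(w > 0)


# ---------------------------------------------------------------------------
# exhaustive grid oracles on the 4+4-point toy sample
#
# The objectives are re-implemented here from their definitions, independent
# of the package internals; the fitted parameters must score at least as well
# as the best point of a dense 3-D grid under this independent evaluation.


def _oracle_sample_part(method, v, th, beta):
    n = v.size
    Fv = np.exp(-th * np.sort(v) ** -beta)
    i = np.arange(1, n + 1)
    if method == "MPSE":
        d = np.clip(np.diff(np.concatenate(([0.0], Fv, [1.0]))), 1e-10, None)
        return -np.log(d).sum() / (n + 1)
    if method == "MSADE":
        d = np.diff(np.concatenate(([0.0], Fv, [1.0])))
        return np.abs(d - 1 / (n + 1)).sum()
    if method == "MSALDE":
        d = np.clip(np.diff(np.concatenate(([0.0], Fv, [1.0]))), 1e-10, None)
        return np.abs(np.log(d) - np.log(1 / (n + 1))).sum()
    if method == "LSE":
        return ((Fv - i / (n + 1)) ** 2).sum()
    if method == "WLSE":
        w = (n + 1) ** 2 * (n + 2) / (i * (n - i + 1))
        return (w * (Fv - i / (n + 1)) ** 2).sum()
    if method == "CME":
        return 1 / (12 * n) + ((Fv - (2 * i - 1) / (2 * n)) ** 2).sum()
    if method == "ADE":
        Fc = np.clip(Fv, 1e-12, 1 - 1e-12)
        return -n - ((2 * i - 1) * (np.log(Fc) + np.log(1 - Fc[::-1]))).sum() / n
    raise AssertionError(method)


def _oracle_objective(method, data, th1, th2, beta):
    return (_oracle_sample_part(method, data.x, th1, beta)
            + _oracle_sample_part(method, data.y, th2, beta))


@pytest.mark.parametrize("method", MIN_DISTANCE)
def test_optimizer_beats_exhaustive_grid(toy44, method):
    fit = fit_joint(toy44, method)
    # the objective separates into x- and y-parts sharing only beta, so the
    # exhaustive 3-D grid minimum is min over beta of (min over theta1) + (min over theta2)
    grid_best = np.inf
    thetas = np.geomspace(0.01, 200, 120)
    betas = np.geomspace(0.1, 10, 120)
    for b in betas:
        best_x = min(_oracle_sample_part(method, toy44.x, t, b) for t in thetas)
        best_y = min(_oracle_sample_part(method, toy44.y, t, b) for t in thetas)
        grid_best = min(grid_best, best_x + best_y)
    fitted_val = _oracle_objective(method, toy44, fit.params.theta1,
                                   fit.params.theta2, fit.params.beta)
    assert fitted_val <= grid_best + 1e-9


def test_minimizer_dominates_mle_point(jute):
    # any minimum-distance optimum scores no worse than the MLE plug-in
    mle = fit_mle_joint(jute).params
    for method in ("MSADE", "LSE", "CME"):
        fit = fit_joint(jute, method)
        at_mle = _oracle_objective(method, jute, mle.theta1, mle.theta2, mle.beta)
        at_fit = _oracle_objective(method, jute, fit.params.theta1,
                                   fit.params.theta2, fit.params.beta)
        assert at_fit <= at_mle + 1e-9


# ---------------------------------------------------------------------------
# input validation


def test_two_sample_data_validation():
    with pytest.raises(ValueError):
        TwoSampleData(np.array([1.0]), np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        TwoSampleData(np.array([1.0, -2.0]), np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        TwoSampleData(np.array([1.0, np.inf]), np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        fit_joint(TwoSampleData(np.ones(3) + np.arange(3), np.ones(3) + np.arange(3)),
                  "NOPE")
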