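"""From-scratch Gaussian mixture: EM pieces, full fits, invariants."""

import numpy as np
import pytest
from scipy import stats

from avsmotion import (
    GaussianMixtureEM,
    GMMParams,
    Responsibilities,
    assign,
    component_logpdf,
    e_step,
    init_params,
    log_likelihood,
    m_step,
)
from avsmotion import mixture


def two_blob_data(rng, n=200, sep=6.0):
    a = rng.normal(loc=(0.0, 0.0), scale=0.5, size=(n, 2))
    b = rng.normal(loc=(sep, sep), scale=0.5, size=(n, 2))
    return np.vstack([a, b])


def test_init_params_scheme_and_determinism():
    p = init_params(8, 16, seed=0)
    assert np.allclose(p.weights, 0.125)
    for cov in p.covariances:
        assert np.allclose(cov, np.eye(16))
    q = init_params(8, 16, seed=0)
    assert np.array_equal(p.means, q.means)
    r = init_params(8, 16, seed=1)
    assert not np.array_equal(p.means, r.means)

    X = np.arange(20, dtype=float).reshape(10, 2)
    dp = init_params(3, 2, seed=0, scheme="random_datapoint", X=X)
    for mu in dp.means:
        assert any(np.array_equal(mu, x) for x in X)
    assert len(np.unique(dp.means, axis=0)) == 3

    with pytest.raises(ValueError):
        init_params(3, 2, seed=0, scheme="nope")
    with pytest.raises(ValueError):
        init_params(0, 2, seed=0)


def test_component_logpdf_standard_normal_at_mode():
    val = component_logpdf(np.zeros(1), np.zeros(1), np.eye(1))
    assert val == pytest.approx(-0.5 * np.log(2 * np.pi))


def test_component_logpdf_symmetry(rng):
    mu = rng.normal(size=3)
    A = rng.normal(size=(3, 3))
    sigma = A @ A.T + np.eye(3)
    v = rng.normal(size=3)
    assert component_logpdf(mu + v, mu, sigma) == pytest.approx(
        component_logpdf(mu - v, mu, sigma), abs=1e-10
    )


def test_component_logpdf_matches_scipy(rng):
    """Cross-check against scipy's multivariate normal on random instances."""
    for _ in range(20):
        mu = rng.normal(size=3)
        A = rng.normal(size=(3, 3))
        sigma = A @ A.T + 0.5 * np.eye(3)
        x = rng.normal(size=3)
        expected = stats.multivariate_normal(mu, sigma).logpdf(x)
        assert component_logpdf(x, mu, sigma) == pytest.approx(expected, abs=1e-10)


def test_component_logpdf_regularization_rescues_singular():
    sigma = np.zeros((2, 2))  # singular without the ridge
    with pytest.raises(np.linalg.LinAlgError):
        component_logpdf(np.zeros(2), np.zeros(2), sigma, reg_eps=0.0)
    val = component_logpdf(np.zeros(2), np.zeros(2), sigma, reg_eps=1e-6)
    assert np.isfinite(val)


def test_e_step_single_and_symmetric_components():
    X = np.array([[0.0], [1.0], [2.0]])
    one = GMMParams(np.array([1.0]), np.zeros((1, 1)), np.eye(1)[None])
    assert np.allclose(e_step(one, X).values, 1.0)

    twin = GMMParams(
        np.array([0.5, 0.5]), np.zeros((2, 1)), np.stack([np.eye(1), np.eye(1)])
    )
    assert np.allclose(e_step(twin, X).values, 0.5)


def test_e_step_matches_bayes_ratio():
    """Two unit-variance 1-D components; responsibilities equal the Bayes
    posterior computed directly from normal densities."""
    params = GMMParams(
        np.array([0.3, 0.7]),
        np.array([[0.0], [4.0]]),
        np.stack([np.eye(1), np.eye(1)]),
        reg_eps=0.0,
    )
    X = np.array([[1.0], [3.0]])
    resp = e_step(params, X).values
    for i, x in enumerate(X[:, 0]):
        p0 = 0.3 * stats.norm.pdf(x, 0.0, 1.0)
        p1 = 0.7 * stats.norm.pdf(x, 4.0, 1.0)
        assert resp[i, 0] == pytest.approx(p0 / (p0 + p1), abs=1e-10)
    # normalization invariants
    assert np.allclose(resp.sum(axis=1), 1.0, atol=1e-10)
    assert e_step(params, X).effective_counts.sum() == pytest.approx(len(X), abs=1e-8)


def test_m_step_hard_and_uniform_responsibilities():
    X = np.array([[0.0, 0.0], [2.0, 2.0], [10.0, 10.0], [12.0, 12.0]])
    hard = Responsibilities(np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float))
    p = m_step(X, hard, reg_eps=0.0)
    assert np.allclose(p.means[0], [1.0, 1.0])
    assert np.allclose(p.means[1], [11.0, 11.0])
    assert np.allclose(p.weights, [0.5, 0.5])

    uniform = Responsibilities(np.full((4, 2), 0.5))
    p = m_step(X, uniform, reg_eps=0.0)
    assert np.allclose(p.means[0], X.mean(axis=0))
    assert np.allclose(p.means[1], X.mean(axis=0))


def test_m_step_matches_hand_computed_update():
    """Three weighted 1-D points, two components: the update equations
    evaluated by direct arithmetic."""
    X = np.array([[1.0], [2.0], [4.0]])
    R = np.array([[0.9, 0.1], [0.5, 0.5], [0.1, 0.9]])
    p = m_step(X, Responsibilities(R), reg_eps=0.0)
    n0, n1 = R.sum(axis=0)  # 1.5, 1.5
    mu0 = (0.9 * 1 + 0.5 * 2 + 0.1 * 4) / n0
    mu1 = (0.1 * 1 + 0.5 * 2 + 0.9 * 4) / n1
    var0 = (0.9 * (1 - mu0) ** 2 + 0.5 * (2 - mu0) ** 2 + 0.1 * (4 - mu0) ** 2) / n0
    assert p.means[0, 0] == pytest.approx(mu0, abs=1e-12)
    assert p.means[1, 0] == pytest.approx(mu1, abs=1e-12)
    assert p.covariances[0, 0, 0] == pytest.approx(var0, abs=1e-12)
    assert np.allclose(p.weights, [n0 / 3, n1 / 3], atol=1e-12)


def test_m_step_degenerate_component():
    X = np.array([[0.0], [1.0]])
    R = Responsibilities(np.array([[1.0, 0.0], [1.0, 0.0]]))
    with pytest.raises(FloatingPointError):
        m_step(X, R, rng=None)
    p = m_step(X, R, rng=np.random.default_rng(0))
    assert any(np.allclose(p.means[1], x) for x in X)  # reseeded to a data point


def test_log_likelihood_examples():
    one = GMMParams(np.array([1.0]), np.zeros((1, 2)), np.eye(2)[None], reg_eps=0.0)
    x = np.array([[0.3, -0.2]])
    assert log_likelihood(one, x) == pytest.approx(
        component_logpdf(x[0], one.means[0], one.covariances[0])
    )
    # additivity: duplicating the dataset doubles log L
    X = np.array([[0.0, 0.0], [1.0, 1.0]])
    assert log_likelihood(one, np.vstack([X, X])) == pytest.approx(
        2 * log_likelihood(one, X), abs=1e-8
    )


def test_log_likelihood_matches_naive_evaluation(rng):
    params = GMMParams(
        np.array([0.4, 0.6]),
        rng.normal(size=(2, 2)),
        np.stack([np.eye(2), 2 * np.eye(2)]),
        reg_eps=0.0,
    )
    X = rng.normal(size=(10, 2))
    naive = sum(
        np.log(
            sum(
                w * stats.multivariate_normal(m, c).pdf(x)
                for w, m, c in zip(params.weights, params.means, params.covariances)
            )
        )
        for x in X
    )
    assert log_likelihood(params, X) == pytest.approx(naive, abs=1e-8)


def test_fit_single_tight_gaussian_converges_fast(rng):
    X = rng.normal(loc=3.0, scale=0.01, size=(100, 2))
    res = mixture.fit(X, K=1, seed=0, n_init=1)
    assert res.converged and res.n_iter <= 3
    assert np.allclose(res.params.means[0], X.mean(axis=0), atol=1e-6)


def test_fit_two_blobs_recovers_means(rng):
    X = two_blob_data(rng)
    res = mixture.fit(X, K=2, seed=0, n_init=5, init_scheme="random_datapoint")
    recovered = res.params.means[np.argsort(res.params.means[:, 0])]
    assert np.abs(recovered[0] - [0.0, 0.0]).max() < 0.05
    assert np.abs(recovered[1] - [6.0, 6.0]).max() < 0.05


def test_fit_loglik_trace_monotone(rng):
    X = two_blob_data(rng, n=100)
    est = GaussianMixtureEM(n_components=2, n_init=3, random_state=0).fit(X)
    assert (np.diff(est.loglik_trace_) >= -1e-8).all()


def test_fit_requires_enough_points():
    with pytest.raises(ValueError):
        GaussianMixtureEM(n_components=8).fit(np.zeros((3, 2)))


def test_fit_deterministic_under_seed(rng):
    X = two_blob_data(rng, n=60)
    a = GaussianMixtureEM(n_components=2, n_init=3, random_state=42).fit(X)
    b = GaussianMixtureEM(n_components=2, n_init=3, random_state=42).fit(X)
    assert np.array_equal(a.means_, b.means_)
    assert np.array_equal(a.labels_, b.labels_)


def test_assign_consistency_and_ties(rng):
    X = two_blob_data(rng, n=50)
    est = GaussianMixtureEM(n_components=2, n_init=3, random_state=0).fit(X)
    labels = assign(est.params_, X)
    assert np.array_equal(labels, np.argmax(est.predict_proba(X), axis=1))

    # exact tie between identical components resolves to the lowest index
    twin = GMMParams(
        np.array([0.5, 0.5]), np.zeros((2, 2)), np.stack([np.eye(2), np.eye(2)])
    )
    assert (assign(twin, rng.normal(size=(20, 2))) == 0).all()

    one = GMMParams(np.array([1.0]), np.zeros((1, 2)), np.eye(2)[None])
    assert (assign(one, rng.normal(size=(5, 2))) == 0).all()


def test_permutation_equivariance(rng):
    X = two_blob_data(rng, n=40)
    est = GaussianMixtureEM(n_components=2, n_init=3, random_state=0).fit(X)
    perm = rng.permutation(len(X))
    assert np.array_equal(est.predict(X[perm]), est.predict(X)[perm])

    # relabeling components permutes responsibilities consistently
    p = est.params_
    swapped = GMMParams(p.weights[::-1], p.means[::-1], p.covariances[::-1], p.reg_eps)
    assert np.allclose(e_step(swapped, X).values, e_step(p, X).values[:, ::-1])


def test_fit_agrees_with_sklearn_on_blobs(rng):
    """Independent cross-check: our EM and scikit-learn's reach the same
    partition on well-separated blobs."""
    from sklearn.metrics import adjusted_rand_score
    from sklearn.mixture import GaussianMixture

    X = two_blob_data(rng, n=150)
    ours = GaussianMixtureEM(n_components=2, n_init=5, random_state=0).fit(X)
    theirs = GaussianMixture(n_components=2, n_init=5, random_state=0).fit(X)
    assert adjusted_rand_score(ours.labels_, theirs.predict(X)) == 1.0
    assert ours.score(X) == pytest.approx(theirs.score(X), abs=0.02)


def test_weight_and_responsibility_normalization_on_ideal(ideal_32):
    """After a short EM run on the ideal dataset the bookkeeping invariants
    hold: weights sum to 1, responsibility rows sum to 1, masses sum to N."""
    est = GaussianMixtureEM(n_components=8, n_init=1, max_iter=3, random_state=0)
    est.fit(ideal_32.vectors)
    assert est.weights_.sum() == pytest.approx(1.0, abs=1e-12)
    resp = est.predict_proba(ideal_32.vectors[::16])
    assert np.allclose(resp.sum(axis=1), 1.0, atol=1e-10)
    assert resp.min() >= 0 and resp.max() <= 1
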