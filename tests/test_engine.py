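import numpy as np
import pytest
from scipy import linalg
from scipy.stats import multivariate_normal, norm

from neurocorr import (
    ActivationSpec,
    NetworkParams,
    Topology,
    build_jacobian,
    complete_graph_correlation,
    covariance_terms,
    fundamental_matrix,
    gaussian_state,
    higher_order_correlation,
    make_block_circulant,
    make_complete,
    make_cyclic,
    make_hypercube,
    mean_trajectory,
    mutual_information,
    pairwise_correlation,
    phi_primitive,
    regular_family_terms,
    sigma_covariance,
    solve_equilibrium,
    thermodynamic_limit_correlation,
    validity_probability,
)
from neurocorr.engine import (
    GaussianState,
    brownian_covariance_lyapunov,
    complete_graph_terms,
    density,
    perturbation_means,
)
from neurocorr.experiments import reference_activation, reference_params


# ---------------------------------------------------------------------------
# scalar primitive and propagator


def test_phi_primitive_limits_and_series():
    assert phi_primitive(0.0, 2.5) == pytest.approx(2.5)
    # series branch must match a cancellation-free evaluation across the
    # switch point (expm1 avoids the loss of precision of exp(z) - 1)
    for z in (1e-7, 1e-5, -1e-7, 1e-3):
        direct = np.expm1(z * 1.0) / z
        assert phi_primitive(z, 1.0) == pytest.approx(direct, rel=1e-12)
    zc = 1e-3 * (1.0 + 1.0j)
    assert phi_primitive(zc, 1.0) == pytest.approx((np.exp(zc) - 1.0) / zc, rel=1e-10)
    # vectorized
    z = np.array([0.0, -1.0, 2.0 + 1.0j])
    out = phi_primitive(z, 0.5)
    assert out.shape == (3,)
    assert out[1] == pytest.approx((np.exp(-0.5) - 1.0) / -1.0)


def test_fundamental_matrix_against_expm(k10):
    _, _, jac = k10
    for t in (0.0, 0.3, 2.0):
        assert np.allclose(
            fundamental_matrix(jac, t), linalg.expm(jac.Jac * t), atol=1e-11
        )
    with pytest.raises(ValueError):
        fundamental_matrix(jac, -1.0)


# ---------------------------------------------------------------------------
# oracle triangle: eigenbasis closed form vs quadrature vs Lyapunov ODE


def _random_network(rng, N):
    while True:
        T = (rng.random((N, N)) < 0.5).astype(int)
        np.fill_diagonal(T, 0)
        if (T.sum(axis=1) >= 1).all():
            return Topology(T)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_oracle_triangle_random_networks(seed):
    rng = np.random.default_rng(seed)
    N = int(rng.integers(3, 9))
    top = _random_network(rng, N)
    act = ActivationSpec("logistic", nu_max=1.0, Lambda=1.0, V_T=0.0)
    p = NetworkParams(
        tau=1.0,
        Jbar_c=float(rng.uniform(0.5, 1.5)),
        I_c=rng.uniform(0.5, 1.5, N),
        sigma=np.full(5, 0.1),
        C0=0.4,
        C1=0.5,
        C2=0.6,
    )
    eq = solve_equilibrium(top, p, act)
    jac = build_jacobian(top, p, eq)
    t = float(rng.uniform(0.3, 1.5))
    if not jac.diagonalizable:
        pytest.skip("defective Jacobian drawn; eigen path not applicable")
    ce = covariance_terms(jac, top, eq, p, t, method="eigen")
    cq = covariance_terms(jac, top, eq, p, t, method="quadrature")
    for name in ("term0", "term1", "term2"):
        assert np.max(np.abs(getattr(ce, name) - getattr(cq, name))) < 1e-7
    lyap = brownian_covariance_lyapunov(jac, p.C0, t)
    assert np.max(np.abs(lyap - ce.term0)) < 1e-7


def test_terms_at_time_zero(k10, ref_params):
    g, eq, jac = k10
    cov = covariance_terms(jac, g.topology, eq, ref_params, 0.0)
    assert np.max(np.abs(cov.term0)) < 1e-14
    assert np.max(np.abs(cov.term2)) < 1e-14
    expect = 0.5 * np.ones((10, 10)) + 0.5 * np.eye(10)  # C1 = 0.5
    assert np.allclose(cov.term1, expect, atol=1e-12)


def test_chi_psi_values(k10, ref_params):
    g, eq, jac = k10
    cov = covariance_terms(jac, g.topology, eq, ref_params, 1.0)
    A = eq.A_mu[0]
    assert np.allclose(cov.chi, 9 * A**2)
    assert np.allclose(cov.psi, 9 * A)


# ---------------------------------------------------------------------------
# family closed forms


@pytest.mark.parametrize(
    "g",
    [make_cyclic(10), make_complete(10), make_block_circulant(3, 10, [2, 2, 2]),
     make_hypercube(4)],
)
def test_family_closed_forms_vs_generic(g, ref_act, ref_params):
    eq = solve_equilibrium(g.topology, ref_params, ref_act)
    jac = build_jacobian(g.topology, ref_params, eq)
    generic = covariance_terms(jac, g.topology, eq, ref_params, 1.0)
    fam = regular_family_terms(g, eq, ref_params, 1.0)
    for name in ("term0", "term1", "term2"):
        assert np.max(np.abs(getattr(fam, name) - getattr(generic, name))) < 1e-9


def test_complete_graph_entrywise_form(k10, ref_params):
    g, eq, jac = k10
    generic = covariance_terms(jac, g.topology, eq, ref_params, 1.0)
    cg = complete_graph_terms(10, float(eq.A_mu[0]), float(eq.A_prime_mu[0]),
                              ref_params, 1.0)
    for name in ("term0", "term1", "term2"):
        assert np.max(np.abs(getattr(cg, name) - getattr(generic, name))) < 1e-12


def test_complete_graph_correlation_matches_matrix_path(ref_act, ref_params, k10):
    g, eq, jac = k10
    cov = covariance_terms(jac, g.topology, eq, ref_params, 1.0)
    corr = pairwise_correlation(cov, ref_params)
    scalar = complete_graph_correlation(10, ref_params, ref_act, 1.0)
    assert scalar == pytest.approx(corr[0, 1], abs=1e-10)


def test_thermodynamic_limit_vs_large_N(ref_act, ref_params):
    # standalone limit formula vs the finite closed form at N = 10^6
    from neurocorr.model import _uniform_roots

    roots = _uniform_roots(1.0, 1.0, 1.0, ref_act, (-50, 50), 2001)
    mu = float(roots[np.argmin(np.abs(roots))])
    limit = thermodynamic_limit_correlation(ref_params, ref_act, 1.0, mu)
    finite = complete_graph_correlation(10**6, ref_params, ref_act, 1.0)
    assert limit == pytest.approx(finite, abs=1e-4)
    # all C = 0: propagation of chaos, the limit correlation vanishes
    p0 = NetworkParams(tau=1.0, Jbar_c=1.0, I_c=1.0, sigma=np.full(5, 0.1))
    assert thermodynamic_limit_correlation(p0, ref_act, 1.0, mu) == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# correlations


def test_correlation_matrix_properties(k10, ref_params):
    g, eq, jac = k10
    cov = covariance_terms(jac, g.topology, eq, ref_params, 1.0)
    corr = pairwise_correlation(cov, ref_params)
    assert np.allclose(corr, corr.T)
    assert np.allclose(np.diagonal(corr), 1.0)
    assert (np.abs(corr) <= 1.0).all()
    # covariance must be positive semidefinite
    lam = np.linalg.eigvalsh(sigma_covariance(cov, ref_params))
    assert lam.min() > -1e-12


def test_correlation_scale_invariance(k10, ref_params):
    g, eq, jac = k10
    cov = covariance_terms(jac, g.topology, eq, ref_params, 1.0)
    c1 = pairwise_correlation(cov, ref_params.with_sigma(np.full(5, 1e-3)))
    c2 = pairwise_correlation(cov, ref_params.with_sigma(np.full(5, 1.0)))
    assert np.allclose(c1, c2, atol=1e-12)


def test_zero_variance_gives_nan_with_warning(k10, ref_params):
    g, eq, jac = k10
    cov = covariance_terms(jac, g.topology, eq, ref_params, 1.0)
    silent = ref_params.with_sigma(np.zeros(5))
    with pytest.warns(RuntimeWarning):
        corr = pairwise_correlation(cov, silent)
    assert np.isnan(corr).all()


def _decoupled_cov(N, C0, t=1.0):
    """Decoupled network: the correlation matrix is exactly equicorrelated."""
    act = ActivationSpec("logistic")
    top = Topology(np.ones((N, N), dtype=int) - np.eye(N, dtype=int))
    p = NetworkParams(tau=1.0, Jbar_c=0.0, I_c=1.0, sigma=(0.1, 0, 0, 0, 0), C0=C0)
    eq = solve_equilibrium(top, p, act)
    jac = build_jacobian(top, p, eq)
    return covariance_terms(jac, top, eq, p, t), p


def test_higher_order_odd_is_zero():
    cov, p = _decoupled_cov(5, 0.3)
    assert higher_order_correlation(cov, p, [0, 1, 2]) == 0.0
    assert higher_order_correlation(cov, p, [0, 1, 2, 3, 4]) == 0.0


def test_higher_order_second_order_is_pearson():
    cov, p = _decoupled_cov(4, 0.3)
    corr = pairwise_correlation(cov, p)
    assert higher_order_correlation(cov, p, [0, 1]) == pytest.approx(corr[0, 1])


def test_higher_order_equicorrelated_fourth():
    # distinct indices, equicorrelation rho: the three pairings give
    # num = 3 rho^2 sigma^4, normalizer 3 sigma^4, so Corr_4 = rho^2
    cov, p = _decoupled_cov(6, 0.4)
    assert higher_order_correlation(cov, p, [0, 1, 2, 3]) == pytest.approx(0.16)
    # perfectly correlated: Corr_n = 1 for even n
    cov1, p1 = _decoupled_cov(4, 1.0)
    for idx in ([0, 1, 2, 3], [0, 1], [0, 0, 1, 1, 2, 2]):
        assert higher_order_correlation(cov1, p1, idx) == pytest.approx(1.0)


def test_higher_order_guards():
    cov, p = _decoupled_cov(4, 0.2)
    with pytest.raises(ValueError):
        higher_order_correlation(cov, p, [0])
    with pytest.raises(ValueError):
        higher_order_correlation(cov, p, [0, 1] * 6)


# ---------------------------------------------------------------------------
# deterministic mean drift


def test_mean_trajectory_uniform_modulation_oracle(ref_act):
    # on a regular uniform network with Iv = 1 and Jv = 1 the responses are
    # along the uniform mode: Y4 = phi(lam0, t), Y3 = A(mu) phi(lam0, t)
    g = make_complete(8)
    p = NetworkParams(
        tau=1.0, Jbar_c=1.0, I_c=1.0, sigma=(0, 0, 0, 0.1, 0.1),
        Jv=lambda t: np.ones((8, 8)), Iv=lambda t: np.ones(8),
    )
    eq = solve_equilibrium(g.topology, p, ref_act)
    jac = build_jacobian(g.topology, p, eq)
    t = 0.8
    lam0 = -1.0 + eq.A_prime_mu[0]  # leading Jacobian eigenvalue
    Y3, Y4 = perturbation_means(jac, g.topology, eq, p, t)
    expect4 = np.real(phi_primitive(lam0, t))
    assert np.allclose(Y4, expect4, atol=1e-9)
    assert np.allclose(Y3, eq.A_mu[0] * expect4, atol=1e-9)
    mv = mean_trajectory(jac, g.topology, eq, p, t)
    assert np.allclose(mv, eq.mu + 0.1 * Y3 + 0.1 * Y4)


def test_modulation_bound_enforced(ref_act):
    g = make_complete(4)
    p = NetworkParams(
        tau=1.0, Jbar_c=1.0, I_c=1.0, sigma=(0, 0, 0, 0, 0.1),
        Iv=lambda t: np.full(4, 1.5),
    )
    eq = solve_equilibrium(g.topology, p, ref_act)
    jac = build_jacobian(g.topology, p, eq)
    with pytest.raises(ValueError):
        mean_trajectory(jac, g.topology, eq, p, 1.0)


# ---------------------------------------------------------------------------
# Gaussian state, density, validity probability


def test_gaussian_state_consistency(ref_act, ref_params, k10):
    g, eq, jac = k10
    state = gaussian_state(jac, g.topology, eq, ref_params, ref_act, 1.0)
    gain = eq.A_prime_mu
    assert np.allclose(state.mean_nu, eq.A_mu + gain * (state.mean_V - eq.mu))
    assert np.allclose(state.cov_nu, np.outer(gain, gain) * state.cov_V)
    # rate and potential correlation matrices coincide at first order
    dV = np.sqrt(np.diagonal(state.cov_V))
    dn = np.sqrt(np.diagonal(state.cov_nu))
    assert np.allclose(
        state.cov_V / np.outer(dV, dV), state.cov_nu / np.outer(dn, dn)
    )
    m, v = state.marginal_V(0)
    assert m == pytest.approx(state.mean_V[0]) and v == pytest.approx(state.cov_V[0, 0])


def test_density_matches_scipy(ref_act, ref_params, k10):
    g, eq, jac = k10
    state = gaussian_state(jac, g.topology, eq, ref_params, ref_act, 1.0)
    point = state.mean_V + 0.05
    expect = multivariate_normal(state.mean_V, state.cov_V).pdf(point)
    assert density(state, point) == pytest.approx(expect, rel=1e-12)


def test_validity_probability_against_product_form():
    # independent two-neuron Gaussian: box mass factorizes into 1-D CDFs
    s = 0.7
    state = GaussianState(
        t=1.0,
        mu=np.zeros(2),
        mean_V=np.zeros(2),
        cov_V=np.diag([s**2, s**2]),
        mean_nu=np.zeros(2),
        cov_nu=np.diag([s**2, s**2]),
    )
    radii = np.array([1.0, 2.0])
    exact = (norm.cdf(1 / s) - norm.cdf(-1 / s)) * (norm.cdf(2 / s) - norm.cdf(-2 / s))
    vp = validity_probability(state, radii, seed=11)
    assert vp.value == pytest.approx(exact, abs=vp.error + 1e-3)
    # reproducible for a fixed seed
    vp2 = validity_probability(state, radii, seed=11)
    assert vp2.value == vp.value


def test_validity_probability_degenerate_and_errors():
    state = GaussianState(1.0, np.zeros(2), np.zeros(2), np.zeros((2, 2)),
                          np.zeros(2), np.zeros((2, 2)))
    vp = validity_probability(state, np.array([1.0, 1.0]))
    assert vp.value == 1.0 and vp.error == 0.0
    shifted = GaussianState(1.0, np.zeros(2), np.array([5.0, 0.0]),
                            np.zeros((2, 2)), np.zeros(2), np.zeros((2, 2)))
    assert validity_probability(shifted, np.array([1.0, 1.0])).value == 0.0
    with pytest.raises(ValueError):
        validity_probability(state, np.array([1.0, -1.0]))


# ---------------------------------------------------------------------------
# mutual information


def test_mutual_information_values():
    assert mutual_information(0.0) == 0.0
    assert mutual_information(0.5) == pytest.approx(-0.5 * np.log(0.75))
    assert mutual_information(0.5) == pytest.approx(0.14384103622589045)
    assert mutual_information(1.0) == np.inf
    assert mutual_information(-1.0) == np.inf
    out = mutual_information(np.array([0.0, 0.5]))
    assert out.shape == (2,)
    with pytest.raises(ValueError):
        mutual_information(1.5)
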