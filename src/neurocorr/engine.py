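"""First-order perturbative covariance and correlation structure.

Linearizing the network around its equilibrium ``mu`` gives an
Ornstein-Uhlenbeck-type system with propagator ``Phi(t) = exp(J t)``.  The
deviation of the potentials from their mean is a zero-mean Gaussian process
whose covariance splits into three contributions, one per randomness
source:

* ``term0`` - accumulated Brownian noise, an integral of
  ``Phi C^B Phi'`` over ``[0, t]``;
* ``term1`` - propagated initial-condition randomness, ``Phi(t) C^N Phi(t)'``;
* ``term2`` - quenched synaptic-weight randomness, built from
  ``U(t) = int_0^t Phi`` and the rate sums ``chi_i = sum_j T_ij A(mu_j)^2``,
  ``psi_i = sum_j T_ij A(mu_j)``.

The total covariance is ``Sigma^V = sum_m sigma_m^2 term_m`` (m = 0, 1, 2)
and the deterministic modulations (``sigma3``, ``sigma4``) only shift the
mean.  All time integrals reduce in the eigenbasis to the scalar primitive
``(exp(z t) - 1)/z``.  From ``Sigma^V`` follow pairwise Pearson
correlations, higher-order correlations via Isserlis pairings, the joint
Gaussian densities of potentials and rates, the Taylor-validity probability
and the Gaussian mutual information.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import integrate, linalg
from scipy.stats import multivariate_normal, qmc

from .activation import ActivationSpec
from .graphs import Graph
from .model import (
    EquilibriumState,
    JacobianSpec,
    NetworkParams,
    Topology,
    equicorrelated_covariance,
)

__all__ = [
    "phi_primitive",
    "fundamental_matrix",
    "CovarianceTerms",
    "covariance_terms",
    "brownian_covariance_lyapunov",
    "sigma_covariance",
    "pairwise_correlation",
    "higher_order_correlation",
    "perturbation_means",
    "mean_trajectory",
    "GaussianState",
    "gaussian_state",
    "density",
    "ValidityProbability",
    "validity_probability",
    "mutual_information",
    "jacobian_eigenvalues_regular",
    "regular_family_terms",
    "complete_graph_terms",
    "complete_graph_correlation",
    "thermodynamic_limit_correlation",
]

_IMAG_TOL = 1e-10


def phi_primitive(z, t: float):
    """Scalar time-integral primitive ``(exp(z t) - 1) / z``.

    For ``|z| t < 1e-6`` the series ``t (1 + z t/2 + (z t)^2/6)`` is used,
    which gives the correct limit ``t`` at ``z = 0`` (the marginally stable
    regime needed for stochastic synchronization).
    """
    z = np.asarray(z, dtype=complex)
    zt = z * t
    small = np.abs(zt) < 1e-6
    safe = np.where(small, 1.0, z)
    out = np.where(small, t * (1.0 + zt / 2.0 + zt * zt / 6.0), np.expm1(zt) / safe)
    return out if out.ndim else complex(out)


def _real(x: np.ndarray, what: str) -> np.ndarray:
    imag = np.max(np.abs(x.imag)) if np.iscomplexobj(x) else 0.0
    if imag > _IMAG_TOL * max(1.0, np.max(np.abs(x.real))):
        raise ValueError(f"{what}: imaginary residue {imag:.3e} exceeds tolerance")
    return np.ascontiguousarray(x.real) if np.iscomplexobj(x) else x


def fundamental_matrix(jac: JacobianSpec, t: float, *, allow_fallback: bool = True) -> np.ndarray:
    """Propagator ``Phi(t) = exp(J t)`` of the linearized dynamics.

    Computed in the eigenbasis when the Jacobian is diagonalizable, by
    scaling-and-squaring otherwise (``allow_fallback=False`` turns the
    fallback into an error).
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if jac.diagonalizable:
        Phi = (jac.P * np.exp(jac.eigenvalues * t)) @ jac.P_inv
        return _real(Phi, "fundamental matrix")
    if not allow_fallback:
        raise ValueError(
            "Jacobian is numerically defective; enable the quadrature fallback"
        )
    return linalg.expm(jac.Jac * t)


# ---------------------------------------------------------------------------
# covariance terms


@dataclass(frozen=True)
class CovarianceTerms:
    """The three covariance summands at time ``t`` (before sigma^2 scaling)
    plus the rate sums ``chi`` and ``psi`` entering the weight term."""

    t: float
    term0: np.ndarray
    term1: np.ndarray
    term2: np.ndarray
    chi: np.ndarray
    psi: np.ndarray


def _chi_psi(top: Topology, eq: EquilibriumState):
    # chi uses T^2, which equals T for a binary topology
    chi = top.T @ (eq.A_mu**2)
    psi = top.T @ eq.A_mu
    return chi, psi


def _sym(x: np.ndarray) -> np.ndarray:
    return 0.5 * (x + x.T)


def covariance_terms(
    jac: JacobianSpec,
    top: Topology,
    eq: EquilibriumState,
    params: NetworkParams,
    t: float,
    *,
    method: str = "auto",
) -> CovarianceTerms:
    """Compute the three covariance terms at time ``t``.

    ``method='eigen'`` evaluates the closed forms in the Jacobian eigenbasis;
    ``method='quadrature'`` integrates the defining expressions with adaptive
    Gauss-Kronrod quadrature (also the automatic fallback for a defective
    Jacobian).
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if method == "auto":
        method = "eigen" if jac.diagonalizable else "quadrature"
    N = top.N
    chi, psi = _chi_psi(top, eq)
    CB = equicorrelated_covariance(N, params.C0)
    CN = equicorrelated_covariance(N, params.C1)

    if method == "eigen":
        if not jac.diagonalizable:
            raise ValueError("eigenbasis method requires a diagonalizable Jacobian")
        lam, P, P_inv = jac.eigenvalues, jac.P, jac.P_inv
        # int_0^t Phi(u) CB Phi(u)' du  =  P [ M_ab phi(lam_a + lam_b, t) ] P'
        Mmat = P_inv @ CB @ P_inv.T
        term0 = P @ (Mmat * phi_primitive(lam[:, None] + lam[None, :], t)) @ P.T
        term0 = _real(term0, "Brownian covariance term")
        Phi_t = fundamental_matrix(jac, t)
        term1 = Phi_t @ CN @ Phi_t.T
        U = _real((P * phi_primitive(lam, t)) @ P_inv, "propagator integral")
    elif method == "quadrature":
        Phi = lambda u: fundamental_matrix(jac, u)
        term0 = integrate.quad_vec(
            lambda u: (lambda F: F @ CB @ F.T)(Phi(u)), 0.0, t,
            epsabs=1e-12, epsrel=1e-10,
        )[0]
        Phi_t = Phi(t)
        term1 = Phi_t @ CN @ Phi_t.T
        U = integrate.quad_vec(Phi, 0.0, t, epsabs=1e-12, epsrel=1e-10)[0]
    else:
        raise ValueError(f"unknown method {method!r}")

    M = top.M.astype(float)
    a = psi / M
    term2 = (1.0 - params.C2) * (U * (chi / M**2)) @ U.T
    Ua = U @ a
    term2 = term2 + params.C2 * np.outer(Ua, Ua)
    return CovarianceTerms(t, _sym(term0), _sym(term1), _sym(term2), chi, psi)


def brownian_covariance_lyapunov(
    jac: JacobianSpec, C0: float, t: float, *, rtol: float = 1e-10, atol: float = 1e-12
) -> np.ndarray:
    """Brownian covariance term via the differential Lyapunov equation
    ``dS/dt = J S + S J' + C^B`` with ``S(0) = 0`` (independent cross-check
    of the eigenbasis closed form)."""
    N = jac.Jac.shape[0]
    CB = equicorrelated_covariance(N, C0)
    J = jac.Jac

    def rhs(_, y):
        S = y.reshape(N, N)
        return (J @ S + S @ J.T + CB).reshape(-1)

    sol = integrate.solve_ivp(
        rhs, (0.0, t), np.zeros(N * N), rtol=rtol, atol=atol, method="RK45"
    )
    return _sym(sol.y[:, -1].reshape(N, N))


# ---------------------------------------------------------------------------
# correlations


def sigma_covariance(cov: CovarianceTerms, params: NetworkParams) -> np.ndarray:
    """Total potential covariance ``Sigma^V = sum_m sigma_m^2 term_m``."""
    s = params.sigma
    return s[0] ** 2 * cov.term0 + s[1] ** 2 * cov.term1 + s[2] ** 2 * cov.term2


def _correlation_from_covariance(Sigma: np.ndarray) -> np.ndarray:
    var = np.diagonal(Sigma).copy()
    bad = var <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} neuron(s) have zero variance; correlation entries "
            "involving them are NaN",
            RuntimeWarning,
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(bad, np.nan, np.sqrt(np.where(bad, 1.0, var)))
        corr = Sigma / np.outer(d, d)
    np.fill_diagonal(corr, np.where(bad, np.nan, 1.0))
    return np.clip(corr, -1.0, 1.0)


def pairwise_correlation(cov: CovarianceTerms, params: NetworkParams) -> np.ndarray:
    """Equal-time Pearson correlation matrix of the membrane potentials
    (identical to the firing-rate correlation at first order)."""
    return _correlation_from_covariance(sigma_covariance(cov, params))


def _isserlis_sum(C: np.ndarray, idx: list) -> float:
    """Sum over all perfect pairings of ``prod C[a, b]`` (hafnian)."""
    if not idx:
        return 1.0
    head, rest = idx[0], idx[1:]
    total = 0.0
    for pos, partner in enumerate(rest):
        total += C[head, partner] * _isserlis_sum(C, rest[:pos] + rest[pos + 1 :])
    return total


def higher_order_correlation(
    cov: CovarianceTerms, params: NetworkParams, indices: Sequence[int]
) -> float:
    """Normalized n-th order central correlation of the chosen neurons.

    For the zero-mean Gaussian deviations this vanishes for odd ``n``; for
    even ``n`` the numerator is the Isserlis sum over all ``(n-1)!!``
    pairings of pairwise covariances and the normalizer is
    ``(n-1)!! * prod_j std_j`` (the geometric mean of Gaussian absolute
    moments), so the result lies in ``[-1, 1]`` and reduces to the Pearson
    coefficient at ``n = 2``.  Repeated indices are allowed.
    """
    idx = list(indices)
    n = len(idx)
    if n < 2:
        raise ValueError("need at least two neuron indices")
    if n > 10:
        raise ValueError("pairing enumeration capped at order n = 10")
    if n % 2 == 1:
        return 0.0
    Sigma = sigma_covariance(cov, params)
    var = np.diagonal(Sigma)[idx]
    if (var <= 0).any():
        warnings.warn("zero variance in requested indices", RuntimeWarning)
        return float("nan")
    num = _isserlis_sum(Sigma, idx)
    double_fact = math.factorial(n) / (2 ** (n // 2) * math.factorial(n // 2))
    den = double_fact * float(np.prod(np.sqrt(var)))
    return float(num / den)


# ---------------------------------------------------------------------------
# deterministic mean drift


def _check_modulation(fun, t: float, what: str, shape_check) -> None:
    for s in np.linspace(0.0, t, 7):
        v = np.asarray(fun(s), dtype=float)
        shape_check(v)
        if np.max(np.abs(v)) > 1.0 + 1e-9:
            raise ValueError(
                f"{what} modulation exceeds the admissible bound |.| <= 1 at t={s:g}"
            )


def perturbation_means(
    jac: JacobianSpec,
    top: Topology,
    eq: EquilibriumState,
    params: NetworkParams,
    t: float,
    *,
    epsabs: float = 1e-11,
):
    """Deterministic first-order responses ``Y^(3)`` (weight modulation) and
    ``Y^(4)`` (input modulation) at time ``t``, by adaptive quadrature of
    the propagator against the bounded modulation series."""
    N = top.N
    Minv = 1.0 / top.M.astype(float)
    Phi = lambda u: fundamental_matrix(jac, u)

    if params.Jv is not None and params.sigma[3] > 0:
        _check_modulation(
            params.Jv, t, "synaptic weight",
            lambda v: None if v.shape == (N, N) else (_ for _ in ()).throw(
                ValueError("Jv must return an N x N array")
            ),
        )
        T = top.T.astype(float)

        def b(s):
            return Minv * ((T * np.asarray(params.Jv(s), dtype=float)) @ eq.A_mu)

        Y3 = integrate.quad_vec(lambda s: Phi(t - s) @ b(s), 0.0, t, epsabs=epsabs)[0]
    else:
        Y3 = np.zeros(N)

    if params.Iv is not None and params.sigma[4] > 0:
        _check_modulation(
            params.Iv, t, "input current",
            lambda v: None if v.shape == (N,) else (_ for _ in ()).throw(
                ValueError("Iv must return a length-N array")
            ),
        )
        Y4 = integrate.quad_vec(
            lambda s: Phi(t - s) @ np.asarray(params.Iv(s), dtype=float),
            0.0, t, epsabs=epsabs,
        )[0]
    else:
        Y4 = np.zeros(N)
    return Y3, Y4


def mean_trajectory(
    jac: JacobianSpec,
    top: Topology,
    eq: EquilibriumState,
    params: NetworkParams,
    t: float,
) -> np.ndarray:
    """Mean membrane potential ``V(t) = mu + sigma3 Y^(3) + sigma4 Y^(4)``."""
    Y3, Y4 = perturbation_means(jac, top, eq, params, t)
    return eq.mu + params.sigma[3] * Y3 + params.sigma[4] * Y4


# ---------------------------------------------------------------------------
# Gaussian state


@dataclass(frozen=True)
class GaussianState:
    """First-order multivariate-normal state of the network at time ``t``:
    potentials ``V ~ N(mean_V, cov_V)`` and rates ``nu ~ N(mean_nu, cov_nu)``
    (the two share the same correlation matrix)."""

    t: float
    mu: np.ndarray
    mean_V: np.ndarray
    cov_V: np.ndarray
    mean_nu: np.ndarray
    cov_nu: np.ndarray

    def marginal_V(self, i: int):
        """Mean and variance of the 1-D potential marginal of neuron ``i``."""
        return float(self.mean_V[i]), float(self.cov_V[i, i])

    def marginal_nu(self, i: int):
        return float(self.mean_nu[i]), float(self.cov_nu[i, i])


def gaussian_state(
    jac: JacobianSpec,
    top: Topology,
    eq: EquilibriumState,
    params: NetworkParams,
    act: ActivationSpec,
    t: float,
    *,
    cov: Optional[CovarianceTerms] = None,
) -> GaussianState:
    if cov is None:
        cov = covariance_terms(jac, top, eq, params, t)
    Sigma_V = sigma_covariance(cov, params)
    mean_V = mean_trajectory(jac, top, eq, params, t)
    gain = eq.A_prime_mu
    mean_nu = eq.A_mu + gain * (mean_V - eq.mu)
    cov_nu = np.outer(gain, gain) * Sigma_V
    return GaussianState(t, eq.mu, mean_V, Sigma_V, mean_nu, cov_nu)


def density(state: GaussianState, point, *, space: str = "V") -> float:
    """Joint probability density at ``point`` (``space`` = 'V' or 'nu')."""
    mean, covm = (
        (state.mean_V, state.cov_V) if space == "V" else (state.mean_nu, state.cov_nu)
    )
    try:
        return float(multivariate_normal(mean=mean, cov=covm).pdf(np.asarray(point)))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"singular covariance: {exc}") from exc


# ---------------------------------------------------------------------------
# validity probability


@dataclass(frozen=True)
class ValidityProbability:
    """Box probability estimate with its standard-error bound."""

    value: float
    error: float
    n_samples: int
    converged: bool


def validity_probability(
    state: GaussianState,
    radii: np.ndarray,
    *,
    n_samples: int = 2**13,
    batches: int = 8,
    seed: int = 0,
    target_error: Optional[float] = None,
) -> ValidityProbability:
    """Probability that every potential lies within the Taylor-convergence
    box ``prod_i (mu_i - r_i, mu_i + r_i)`` under the Gaussian state.

    Estimated with randomized quasi-Monte Carlo (scrambled-Sobol Gaussian
    samples in independent batches); the reported error is twice the
    standard error over batches.  When a ``target_error`` is requested but
    not achieved at the configured budget, the estimate is returned flagged
    rather than raising.
    """
    radii = np.asarray(radii, dtype=float)
    if (radii <= 0).any():
        raise ValueError("convergence radii must be positive")
    lo = state.mu - radii
    hi = state.mu + radii
    scale = float(np.max(np.abs(state.cov_V)))
    if scale == 0.0:  # degenerate point mass at the mean
        inside = bool(np.all((state.mean_V > lo) & (state.mean_V < hi)))
        return ValidityProbability(1.0 if inside else 0.0, 0.0, 0, True)
    rng = np.random.default_rng(seed)
    ps = []
    for _ in range(batches):
        engine = qmc.MultivariateNormalQMC(
            mean=state.mean_V, cov=state.cov_V, seed=rng
        )
        x = engine.random(n_samples)
        ps.append(np.mean(np.all((x > lo) & (x < hi), axis=1)))
    ps = np.asarray(ps)
    value = float(ps.mean())
    error = float(2.0 * ps.std(ddof=1) / np.sqrt(batches))
    converged = target_error is None or error <= target_error
    return ValidityProbability(value, error, n_samples * batches, converged)


# ---------------------------------------------------------------------------
# mutual information


def mutual_information(corr):
    """Gaussian mutual information ``-log(1 - Corr^2) / 2`` in nats;
    infinite at ``|Corr| = 1``."""
    c = np.asarray(corr, dtype=float)
    if (np.abs(c) > 1).any():
        raise ValueError("correlation must lie in [-1, 1]")
    with np.errstate(divide="ignore"):
        out = -0.5 * np.log1p(-(c * c))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# closed forms for regular families


def jacobian_eigenvalues_regular(
    topology_eigenvalues: np.ndarray,
    tau: float,
    Gamma: float,
    gain: float,
    M: int,
) -> np.ndarray:
    """Jacobian eigenvalues of a uniform regular network:
    ``-1/tau + Gamma A'(mu) lambda_k / M`` with ``lambda_k`` the adjacency
    eigenvalues (the eigenvectors coincide)."""
    return -1.0 / tau + (Gamma * gain / M) * np.asarray(topology_eigenvalues, complex)


def regular_family_terms(
    graph: Graph,
    eq: EquilibriumState,
    params: NetworkParams,
    t: float,
) -> CovarianceTerms:
    """Covariance terms via the family closed forms for a uniform regular
    graph with a known spectral decomposition (block-circulant families use
    Fourier eigenvectors, the hypercube Hadamard columns; both share the
    structure ``f_ijk = N P_ik conj(P_jk)`` with ``sum_j f_ijk = N delta_0k``).
    """
    if graph.spectrum is None or graph.degree is None:
        raise ValueError("closed forms need a regular graph with a spectrum")
    top = graph.topology
    N, M = graph.N, graph.degree
    A_mu = float(eq.A_mu[0])
    gain = float(eq.A_prime_mu[0])
    Jc = params.Jc_matrix(top)
    Gamma = float(Jc[np.unravel_index(np.argmax(top.T), top.T.shape)])
    lam_t = jacobian_eigenvalues_regular(
        graph.spectrum.eigenvalues, params.tau, Gamma, gain, M
    )
    P = graph.spectrum.P
    lt0 = lam_t[0]
    if abs(lt0.imag) > _IMAG_TOL:
        raise ValueError("leading eigenvalue of a regular graph must be real")
    lt0 = lt0.real

    def mode_sum(weights: np.ndarray) -> np.ndarray:
        w = np.asarray(weights, dtype=complex).copy()
        w[0] = 0.0  # k >= 1 only
        return _real(N * (P * w) @ P.conj().T, "regular-family mode sum")

    re2 = 2.0 * lam_t.real
    t0 = (1.0 - params.C0) / N * mode_sum(np.real(phi_primitive(re2, t))) + (
        1.0 / N + params.C0 * (1.0 - 1.0 / N)
    ) * np.real(phi_primitive(2.0 * lt0, t))
    t1 = (1.0 - params.C1) / N * mode_sum(np.exp(re2 * t)) + (
        1.0 / N + params.C1 * (1.0 - 1.0 / N)
    ) * np.exp(2.0 * lt0 * t)
    phis = phi_primitive(lam_t, t)
    t2 = A_mu**2 * (
        (1.0 - params.C2) / (M * N) * mode_sum(np.abs(phis) ** 2)
        + (1.0 / (M * N) + params.C2 * (1.0 - 1.0 / (M * N)))
        * np.real(phi_primitive(lt0, t)) ** 2
    )
    t0 = t0 + np.zeros((N, N))
    t1 = t1 + np.zeros((N, N))
    t2 = t2 + np.zeros((N, N))
    chi, psi = _chi_psi(top, eq)
    return CovarianceTerms(t, _sym(t0), _sym(t1), _sym(t2), chi, psi)


def complete_graph_terms(
    N: int,
    A_mu: float,
    gain: float,
    params: NetworkParams,
    t: float,
) -> CovarianceTerms:
    """Entrywise closed forms for the uniform complete graph ``K_N``:
    every term is ``a + (delta_ij - 1/N) b`` with mode amplitudes at the
    two distinct Jacobian eigenvalues
    ``lt0 = -1/tau + Gamma A'(mu)`` and ``lt1 = -1/tau - Gamma A'(mu)/(N-1)``.
    """
    Gamma = float(np.asarray(params.Jbar_c, dtype=float).flat[0])
    lt0 = -1.0 / params.tau + Gamma * gain
    lt1 = -1.0 / params.tau - Gamma * gain / (N - 1)
    delta = np.eye(N)
    dev = delta - 1.0 / N
    p = lambda z: np.real(phi_primitive(z, t))
    t0 = (1.0 / N + params.C0 * (1.0 - 1.0 / N)) * p(2 * lt0) * np.ones((N, N)) + (
        1.0 - params.C0
    ) * dev * p(2 * lt1)
    t1 = (1.0 / N + params.C1 * (1.0 - 1.0 / N)) * np.exp(2 * lt0 * t) * np.ones(
        (N, N)
    ) + (1.0 - params.C1) * dev * np.exp(2 * lt1 * t)
    t2 = (
        A_mu**2
        / (N - 1)
        * (
            (1.0 / N + params.C2 * (N - 1 - 1.0 / N)) * p(lt0) ** 2 * np.ones((N, N))
            + (1.0 - params.C2) * dev * p(lt1) ** 2
        )
    )
    chi = np.full(N, (N - 1) * A_mu**2)
    psi = np.full(N, (N - 1) * A_mu)
    return CovarianceTerms(t, t0, t1, t2, chi, psi)


def complete_graph_correlation(
    N: int,
    params: NetworkParams,
    act: ActivationSpec,
    t: float,
    *,
    mu: Optional[float] = None,
    select: str | float = "nearest-zero",
) -> float:
    """Pairwise correlation (equal for every pair) of the uniform ``K_N``
    network, via the complete-graph closed forms.  Evaluated entirely in
    scalars - cost is O(1) in ``N`` - so thermodynamic-limit behavior can
    be probed directly at any size."""
    if mu is None:
        from .model import _uniform_roots  # scalar uniform fixed-point equation

        Gamma = float(np.asarray(params.Jbar_c, dtype=float).flat[0])
        Ic = float(np.asarray(params.I_c, dtype=float).flat[0])
        roots = _uniform_roots(Gamma, Ic, params.tau, act, (-50.0, 50.0), 2001)
        if roots.size == 0:
            raise ValueError("no uniform equilibrium found in the default bracket")
        if isinstance(select, (int, float)) and not isinstance(select, bool):
            mu = float(roots[np.argmin(np.abs(roots - select))])
        elif select == "smallest":
            mu = float(roots[0])
        elif select == "largest":
            mu = float(roots[-1])
        else:
            mu = float(roots[np.argmin(np.abs(roots))])
    A_mu = act(mu)
    gain = act.derivative(mu)
    Gamma = float(np.asarray(params.Jbar_c, dtype=float).flat[0])
    lt0 = -1.0 / params.tau + Gamma * gain
    lt1 = -1.0 / params.tau - Gamma * gain / (N - 1)
    p = lambda z: float(np.real(phi_primitive(z, t)))
    # each term is a uniform part u plus (delta_ij - 1/N) times a mode part v
    u0, v0 = (1.0 / N + params.C0 * (1.0 - 1.0 / N)) * p(2 * lt0), (
        1.0 - params.C0
    ) * p(2 * lt1)
    u1, v1 = (1.0 / N + params.C1 * (1.0 - 1.0 / N)) * float(np.exp(2 * lt0 * t)), (
        1.0 - params.C1
    ) * float(np.exp(2 * lt1 * t))
    u2 = A_mu**2 / (N - 1) * (1.0 / N + params.C2 * (N - 1 - 1.0 / N)) * p(lt0) ** 2
    v2 = A_mu**2 / (N - 1) * (1.0 - params.C2) * p(lt1) ** 2
    s = params.sigma
    off = (
        s[0] ** 2 * (u0 - v0 / N)
        + s[1] ** 2 * (u1 - v1 / N)
        + s[2] ** 2 * (u2 - v2 / N)
    )
    var = (
        s[0] ** 2 * (u0 + v0 * (1.0 - 1.0 / N))
        + s[1] ** 2 * (u1 + v1 * (1.0 - 1.0 / N))
        + s[2] ** 2 * (u2 + v2 * (1.0 - 1.0 / N))
    )
    return float(off / var)


def thermodynamic_limit_correlation(
    params: NetworkParams,
    act: ActivationSpec,
    t: float,
    mu: float,
) -> float:
    """Pairwise correlation of the uniform complete graph in the
    ``N -> infinity`` limit.  Nonzero whenever any of ``C0, C1, C2`` is
    nonzero - the analytic statement that correlated randomness sources
    preclude propagation of chaos."""
    Gamma = float(np.asarray(params.Jbar_c, dtype=float).flat[0])
    lt0 = -1.0 / params.tau + Gamma * act.derivative(mu)
    A2 = act(mu) ** 2
    s0, s1, s2 = params.sigma[0] ** 2, params.sigma[1] ** 2, params.sigma[2] ** 2
    p0 = np.real(phi_primitive(2 * lt0, t))
    pa = np.real(phi_primitive(lt0, t))
    num = s0 * params.C0 * p0 + s1 * params.C1 * np.exp(2 * lt0 * t) + s2 * params.C2 * A2 * pa**2
    den = (
        s0
        * (
            params.C0 * p0
            - 0.5 * params.tau * (1.0 - params.C0) * np.expm1(-2.0 * t / params.tau)
        )
        + s1
        * (
            params.C1 * np.exp(2 * lt0 * t)
            + (1.0 - params.C1) * np.exp(-2.0 * t / params.tau)
        )
        + s2 * params.C2 * A2 * pa**2
    )
    return float(num / den)
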