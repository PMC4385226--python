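"""Core domain types of the stochastic firing-rate network.

The network obeys, for ``i = 0..N-1``,

    dV_i = [ -V_i/tau + (1/M_i) sum_j J_ij(t) A(V_j) + I_i(t) ] dt
           + sigma0 dB_i,        V_i(0) = mu_i + sigma1 N_i,

with three correlated Gaussian randomness sources: the Brownian motions
(pairwise correlation ``C0``), the initial conditions (``C1``) and the
quenched synaptic weights (``C2``), plus two small deterministic
time-varying modulations of the weights (``sigma3``) and of the input
current (``sigma4``).  ``T`` is the binary adjacency matrix (``T[i, j] = 1``
means an edge from presynaptic ``j`` to postsynaptic ``i``) and ``M_i`` its
incoming vertex degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize

from .activation import ActivationSpec

__all__ = [
    "Topology",
    "NetworkParams",
    "EquilibriumState",
    "JacobianSpec",
    "NoiseAdmissibility",
    "solve_equilibrium",
    "build_jacobian",
    "validate_noise_model",
    "equicorrelated_covariance",
    "read_adjacency",
    "write_adjacency",
    "read_edge_list",
    "write_edge_list",
]


# ---------------------------------------------------------------------------
# topology


@dataclass(frozen=True)
class Topology:
    """Binary adjacency matrix with zero diagonal; ``T[i, j] = 1`` means a
    synapse from neuron ``j`` onto neuron ``i`` (rows index the receiver)."""

    T: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.T)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if not np.isin(T, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.diagonal(T).any():
            raise ValueError("self-connections (nonzero diagonal) not allowed")
        T = T.astype(np.int64)
        if (T.sum(axis=1) < 1).any():
            raise ValueError(
                "every neuron needs at least one incoming connection "
                "(the coupling term divides by the incoming degree)"
            )
        object.__setattr__(self, "T", T)

    @property
    def N(self) -> int:
        return self.T.shape[0]

    @property
    def M(self) -> np.ndarray:
        """Incoming vertex degrees ``M_i = sum_j T_ij``."""
        return self.T.sum(axis=1)

    @property
    def Z(self) -> int:
        """Number of absent connections (zeros of ``T``, diagonal included)."""
        return int(self.N**2 - self.T.sum())

    @property
    def regular(self) -> bool:
        M = self.M
        return bool((M == M[0]).all())


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class NetworkParams:
    """All scalar/vector parameters of the network equation.

    ``Jbar_c`` may be a scalar coupling ``Gamma`` (broadcast over present
    edges) or a full ``N x N`` matrix; ``I_c`` a scalar or length-``N``
    vector.  ``Jv`` and ``Iv`` are optional callables ``t -> (N, N)`` and
    ``t -> (N,)`` giving the bounded (``|.| <= 1``) modulations scaled by
    ``sigma3`` and ``sigma4``.
    """

    tau: float = 1.0
    Jbar_c: float | np.ndarray = 1.0
    I_c: float | np.ndarray = 0.0
    sigma: Sequence[float] = (0.0, 0.0, 0.0, 0.0, 0.0)
    C0: float = 0.0
    C1: float = 0.0
    C2: float = 0.0
    Jv: Optional[Callable[[float], np.ndarray]] = None
    Iv: Optional[Callable[[float], np.ndarray]] = None

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        sigma = np.asarray(self.sigma, dtype=float)
        if sigma.shape != (5,):
            raise ValueError("sigma must have five entries (sigma0..sigma4)")
        if (sigma < 0).any():
            raise ValueError("sigma entries must be non-negative")
        object.__setattr__(self, "sigma", sigma)

    # broadcasting -----------------------------------------------------------

    def Jc_matrix(self, top: Topology) -> np.ndarray:
        """Static mean weights as an ``N x N`` array (scalar Gamma broadcast)."""
        J = np.asarray(self.Jbar_c, dtype=float)
        if J.ndim == 0:
            return np.full((top.N, top.N), float(J))
        if J.shape != (top.N, top.N):
            raise ValueError("Jbar_c matrix shape does not match topology")
        return J

    def Ic_vector(self, N: int) -> np.ndarray:
        I = np.asarray(self.I_c, dtype=float)
        if I.ndim == 0:
            return np.full(N, float(I))
        if I.shape != (N,):
            raise ValueError("I_c vector length does not match topology")
        return I

    def is_uniform(self, top: Topology) -> bool:
        """True when the equilibrium reduces to one scalar equation:
        uniform weights on present edges, uniform input and regular incoming
        degree."""
        J = np.asarray(self.Jbar_c, dtype=float)
        I = np.asarray(self.I_c, dtype=float)
        if J.ndim != 0:
            edge = J[top.T.astype(bool)]
            if edge.size and not np.allclose(edge, edge.flat[0]):
                return False
        if I.ndim != 0 and not np.allclose(I, I.flat[0]):
            return False
        return top.regular

    def with_sigma(self, sigma) -> "NetworkParams":
        return replace(self, sigma=np.asarray(sigma, dtype=float))


# ---------------------------------------------------------------------------
# noise admissibility


def equicorrelated_covariance(N: int, C: float) -> np.ndarray:
    """Equicorrelated covariance ``delta_ij + C (1 - delta_ij)``."""
    return (1.0 - C) * np.eye(N) + C * np.ones((N, N))


@dataclass(frozen=True)
class NoiseAdmissibility:
    """Admissible ranges of the three noise-correlation parameters and the
    predicted eigenvalues of the corresponding covariance matrices."""

    N: int
    Z: int
    C0_interval: tuple
    C1_interval: tuple
    C2_interval: tuple
    C0_ok: bool
    C1_ok: bool
    C2_ok: bool
    brownian_eigenvalues: dict
    initial_eigenvalues: dict
    theta_eigenvalues: dict

    @property
    def ok(self) -> bool:
        return self.C0_ok and self.C1_ok and self.C2_ok


def validate_noise_model(top: Topology, params: NetworkParams) -> NoiseAdmissibility:
    """Check that the equicorrelated covariances are positive-semidefinite.

    The ``N x N`` Brownian/initial-condition covariances are circulant with
    eigenvalues ``1 + C (N-1)`` (multiplicity 1) and ``1 - C`` (multiplicity
    ``N - 1``); admissibility is ``1/(1-N) <= C <= 1``.  The ``N^2 x N^2``
    weight covariance ``Theta`` has eigenvalues ``0`` (multiplicity ``Z``),
    ``1 + C2 (N^2 - Z - 1)`` (multiplicity 1) and ``1 - C2`` (multiplicity
    ``N^2 - Z - 1``); admissibility is ``1/(1 + Z - N^2) <= C2 <= 1``.
    """
    N, Z = top.N, top.Z
    lo = 1.0 / (1.0 - N)
    lo2 = 1.0 / (1.0 + Z - N**2)
    C0, C1, C2 = params.C0, params.C1, params.C2
    return NoiseAdmissibility(
        N=N,
        Z=Z,
        C0_interval=(lo, 1.0),
        C1_interval=(lo, 1.0),
        C2_interval=(lo2, 1.0),
        C0_ok=lo <= C0 <= 1.0,
        C1_ok=lo <= C1 <= 1.0,
        C2_ok=lo2 <= C2 <= 1.0,
        brownian_eigenvalues={1.0 + C0 * (N - 1): 1, 1.0 - C0: N - 1},
        initial_eigenvalues={1.0 + C1 * (N - 1): 1, 1.0 - C1: N - 1},
        theta_eigenvalues={0.0: Z, 1.0 + C2 * (N**2 - Z - 1): 1, 1.0 - C2: N**2 - Z - 1},
    )


# ---------------------------------------------------------------------------
# equilibrium


@dataclass(frozen=True)
class EquilibriumState:
    """Stationary mean potentials ``mu`` with the rates and gains there."""

    mu: np.ndarray
    A_mu: np.ndarray
    A_prime_mu: np.ndarray
    residual: float
    roots: Optional[np.ndarray] = None  # all scalar roots (uniform networks)
    multistable: bool = False


class EquilibriumError(RuntimeError):
    pass


def _equilibrium_rhs(mu, top, params, act):
    Jc = params.Jc_matrix(top)
    Ic = params.Ic_vector(top.N)
    coupling = (top.T * Jc) @ act(np.asarray(mu, dtype=float)) / top.M
    return params.tau * (coupling + Ic)


def _uniform_roots(Gamma, Ic, tau, act, bracket, grid):
    """All roots of mu = tau * (Gamma * A(mu) + Ic) on a bracketing grid."""

    def h(mu):
        return mu - tau * (Gamma * act(mu) + Ic)

    xs = np.linspace(bracket[0], bracket[1], grid)
    hs = h(xs)
    roots = []
    for a, b, ha, hb in zip(xs[:-1], xs[1:], hs[:-1], hs[1:]):
        if ha == 0.0:
            roots.append(a)
        elif ha * hb < 0:
            roots.append(optimize.brentq(h, a, b, xtol=1e-14, rtol=8.9e-16))
    if hs[-1] == 0.0:
        roots.append(xs[-1])
    # deduplicate (tangencies can produce near-identical roots)
    roots = sorted(roots)
    out = []
    for r in roots:
        if not out or abs(r - out[-1]) > 1e-9:
            out.append(r)
    return np.array(out)


def solve_equilibrium(
    top: Topology,
    params: NetworkParams,
    act: ActivationSpec,
    *,
    bracket: tuple = (-50.0, 50.0),
    grid: int = 2001,
    select: str | float = "nearest-zero",
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> EquilibriumState:
    """Solve the stationary equation ``mu_i = tau [ (1/M_i) sum_j T_ij
    Jc_ij A(mu_j) + Ic_i ]``.

    Uniform networks reduce to one scalar equation which is solved on a
    bracketing grid; every root found is reported and ``multistable`` is set
    when there is more than one (``select`` picks the returned root: a float
    target, or ``"nearest-zero"``/``"smallest"``/``"largest"``).  General
    networks use damped fixed-point iteration with a root-finder fallback.
    """
    N = top.N
    Jc = params.Jc_matrix(top)

    if not (top.T * Jc).any():  # decoupled network
        mu = params.tau * params.Ic_vector(N)
        return EquilibriumState(mu, act(mu), act.derivative(mu), 0.0)

    if params.is_uniform(top):
        Gamma = float(Jc[np.unravel_index(np.argmax(top.T), top.T.shape)])
        Ic = float(np.asarray(params.I_c, dtype=float).flat[0])
        roots = _uniform_roots(Gamma, Ic, params.tau, act, bracket, grid)
        if roots.size == 0:
            raise EquilibriumError(
                f"no equilibrium found in bracket {bracket}; the map "
                f"mu -> tau*(Gamma*A(mu)+Ic) has no fixed point there"
            )
        if isinstance(select, (int, float)) and not isinstance(select, bool):
            mu0 = roots[np.argmin(np.abs(roots - select))]
        elif select == "smallest":
            mu0 = roots[0]
        elif select == "largest":
            mu0 = roots[-1]
        else:
            mu0 = roots[np.argmin(np.abs(roots))]
        mu = np.full(N, mu0)
        res = float(np.max(np.abs(mu - _equilibrium_rhs(mu, top, params, act))))
        return EquilibriumState(
            mu, act(mu), act.derivative(mu), res, roots=roots, multistable=roots.size > 1
        )

    # general case: damped fixed point, then hybrid root finder if needed
    mu = params.tau * params.Ic_vector(N)
    alpha = 0.5
    for _ in range(max_iter):
        nxt = _equilibrium_rhs(mu, top, params, act)
        new = (1.0 - alpha) * mu + alpha * nxt
        if np.max(np.abs(new - mu)) < 0.1 * tol:
            mu = new
            break
        mu = new
    res = np.max(np.abs(mu - _equilibrium_rhs(mu, top, params, act)))
    if res > tol:
        sol = optimize.root(
            lambda m: m - _equilibrium_rhs(m, top, params, act), mu, tol=1e-14
        )
        mu = sol.x
        res = np.max(np.abs(mu - _equilibrium_rhs(mu, top, params, act)))
        if res > tol:
            raise EquilibriumError(
                f"equilibrium solver did not converge (residual {res:.3e})"
            )
    return EquilibriumState(mu, act(mu), act.derivative(mu), float(res))


# ---------------------------------------------------------------------------
# Jacobian


@dataclass(frozen=True)
class JacobianSpec:
    """Jacobian of the linearized dynamics and its eigendecomposition.

    ``Jac[i, i] = -1/tau`` and ``Jac[i, j] = J_eff[i, j] / M_i`` off the
    diagonal, with the effective connectivity
    ``J_eff[i, j] = T_ij Jc_ij A'(mu_j)``.
    """

    Jac: np.ndarray
    J_eff: np.ndarray
    eigenvalues: np.ndarray
    P: np.ndarray
    P_inv: np.ndarray
    diagonalizable: bool
    tau: float


def build_jacobian(
    top: Topology,
    params: NetworkParams,
    eq: EquilibriumState,
    *,
    cond_threshold: float = 1e8,
) -> JacobianSpec:
    N = top.N
    Jc = params.Jc_matrix(top)
    J_eff = top.T * Jc * eq.A_prime_mu[np.newaxis, :]
    Jac = J_eff / top.M[:, np.newaxis]
    np.fill_diagonal(Jac, -1.0 / params.tau)

    if np.allclose(Jac, Jac.T, atol=1e-13):
        lam, P = np.linalg.eigh(Jac)
        P_inv = P.T.copy()
        lam = lam.astype(complex)
        diagonalizable = True
    else:
        lam, P = np.linalg.eig(Jac)
        cond = np.linalg.cond(P)
        diagonalizable = bool(np.isfinite(cond) and cond < cond_threshold)
        P_inv = np.linalg.inv(P) if diagonalizable else np.full_like(P, np.nan)
    return JacobianSpec(Jac, J_eff, lam, P, P_inv, diagonalizable, params.tau)


# ---------------------------------------------------------------------------
# adjacency I/O (dense whitespace text and edge-list CSV, j -> i convention)


def read_adjacency(path) -> Topology:
    return Topology(np.loadtxt(path, dtype=np.int64, ndmin=2))


def write_adjacency(path, top: Topology) -> None:
    np.savetxt(path, top.T, fmt="%d")


def read_edge_list(path, N: Optional[int] = None) -> Topology:
    """Edge-list CSV with header ``target,source`` (edge source -> target)."""
    edges = np.loadtxt(path, dtype=np.int64, delimiter=",", skiprows=1, ndmin=2)
    n = int(edges.max()) + 1 if N is None else N
    T = np.zeros((n, n), dtype=np.int64)
    T[edges[:, 0], edges[:, 1]] = 1
    return Topology(T)


def write_edge_list(path, top: Topology) -> None:
    tgt, src = np.nonzero(top.T)
    with open(path, "w") as fh:
        fh.write("target,source\n")
        for i, j in zip(tgt, src):
            fh.write(f"{i},{j}\n")
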