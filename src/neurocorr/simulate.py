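"""Monte Carlo simulation of the full nonlinear network.

Euler-Maruyama integration of

    dV_i = [ -V_i/tau + (1/M_i) sum_j J_ij(t) A(V_j) + I_i(t) ] dt
           + sigma0 dB_i

over an ensemble of independent trials.  Each trial draws its own
equicorrelated initial conditions, Brownian increments and quenched weight
matrix; drift terms are evaluated at the left endpoint of each step.  The
resulting ensemble statistics are the ground truth against which the
analytic first-order covariance is benchmarked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .activation import ActivationSpec
from .model import NetworkParams, Topology

__all__ = [
    "SimulationConfig",
    "TrialEnsemble",
    "EnsembleStats",
    "equicorrelated_normals",
    "sample_initial_conditions",
    "sample_weight_matrices",
    "integrate_trials",
    "ensemble_statistics",
    "sample_higher_order",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings: step size, horizon, ensemble size, seed and
    which steps to store (every ``store_stride``-th, plus first and last)."""

    dt: float = 1e-3
    t_end: float = 1.0
    n_trials: int = 1000
    seed: int = 0
    store_stride: int = 0  # 0: store only t=0 and t_end

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.t_end >= 0:
            raise ValueError("t_end must be non-negative")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must satisfy 0 <= seed < 2**31")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    def stored_steps(self) -> np.ndarray:
        n = self.n_steps
        if self.store_stride <= 0:
            return np.unique(np.array([0, n]))
        return np.unique(np.r_[np.arange(0, n + 1, self.store_stride), n])


@dataclass(frozen=True)
class TrialEnsemble:
    """Stored trajectories ``V[trial, time, neuron]`` at ``times``."""

    times: np.ndarray
    V: np.ndarray
    seed: int


def equicorrelated_normals(
    rng: np.random.Generator, shape: tuple, C: float
) -> np.ndarray:
    """Standard-normal samples whose last axis is equicorrelated with
    coefficient ``C``.

    Decomposes each vector into its mean component (variance ``1 + C(n-1)``)
    and the orthogonal remainder (variance ``1 - C``), which factorizes the
    equicorrelated covariance exactly for any admissible ``C``, including
    negative values down to ``1/(1-n)`` (the boundary eigenvalue is clipped
    at zero against floating-point round-off).
    """
    n = shape[-1]
    if n == 1:
        return rng.standard_normal(shape)
    lo = 1.0 / (1.0 - n)
    if not lo - 1e-12 <= C <= 1.0 + 1e-12:
        raise ValueError(f"equicorrelation {C} outside admissible [{lo}, 1]")
    z = rng.standard_normal(shape)
    zbar = z.mean(axis=-1, keepdims=True)
    a = np.sqrt(max(1.0 - C, 0.0))
    b = np.sqrt(max(1.0 + C * (n - 1), 0.0))
    return a * (z - zbar) + b * zbar


def sample_initial_conditions(
    rng: np.random.Generator,
    mu: np.ndarray,
    sigma1: float,
    C1: float,
    n_trials: int,
) -> np.ndarray:
    return mu + sigma1 * equicorrelated_normals(rng, (n_trials, mu.size), C1)


def sample_weight_matrices(
    rng: np.random.Generator, top: Topology, C2: float, n_trials: int
) -> np.ndarray:
    """Quenched weight-perturbation matrices ``W`` (one per trial): standard
    normal on present edges, equicorrelated across all edges with ``C2``,
    zero where the topology has no connection."""
    tgt, src = np.nonzero(top.T)
    n_edges = tgt.size
    vals = equicorrelated_normals(rng, (n_trials, n_edges), C2)
    W = np.zeros((n_trials, top.N, top.N))
    W[:, tgt, src] = vals
    return W


def integrate_trials(
    top: Topology,
    params: NetworkParams,
    act: ActivationSpec,
    mu: np.ndarray,
    config: SimulationConfig,
    *,
    rng: Optional[np.random.Generator] = None,
) -> TrialEnsemble:
    """Integrate ``config.n_trials`` independent trials from the Gaussian
    initial condition ``mu + sigma1 N`` and return the stored snapshots."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N = top.N
    s = params.sigma
    Minv = (1.0 / top.M.astype(float))[:, np.newaxis]
    Jc = params.Jc_matrix(top) * top.T
    Ic = params.Ic_vector(N)
    dt = config.dt
    n_steps = config.n_steps
    stored = config.stored_steps()
    store_at = {int(k): idx for idx, k in enumerate(stored)}

    V = sample_initial_conditions(rng, np.asarray(mu, float), s[1], params.C1, config.n_trials)
    out = np.empty((config.n_trials, stored.size, N))
    if 0 in store_at:
        out[:, store_at[0], :] = V

    if s[2] > 0:
        Wq = sample_weight_matrices(rng, top, params.C2, config.n_trials)
        Wq *= s[2] * Minv  # pre-scale the quenched part by sigma2 / M_i
    else:
        Wq = None
    noise_amp = s[0] * np.sqrt(dt)
    Tf = top.T.astype(float)

    for k in range(n_steps):
        t = k * dt
        D = Jc.astype(float)
        if params.Jv is not None and s[3] > 0:
            D = D + s[3] * Tf * np.asarray(params.Jv(t), dtype=float)
        D = D * Minv
        A = act(V)
        drift = -V / params.tau + A @ D.T + Ic
        if Wq is not None:
            drift += np.einsum("tij,tj->ti", Wq, A)
        if params.Iv is not None and s[4] > 0:
            drift = drift + s[4] * np.asarray(params.Iv(t), dtype=float)
        V = V + dt * drift
        if noise_amp > 0:
            V = V + noise_amp * equicorrelated_normals(
                rng, (config.n_trials, N), params.C0
            )
        if k + 1 in store_at:
            if not np.isfinite(V).all():
                raise FloatingPointError(
                    f"non-finite state at step {k + 1} (t = {(k + 1) * dt:g}); "
                    "reduce dt or check stability"
                )
            out[:, store_at[k + 1], :] = V

    return TrialEnsemble(stored * dt, out, config.seed)


# ---------------------------------------------------------------------------
# ensemble statistics


@dataclass(frozen=True)
class EnsembleStats:
    """Per-stored-time sample statistics over trials."""

    times: np.ndarray
    mean_V: np.ndarray  # (T, N)
    cov_V: np.ndarray  # (T, N, N)
    corr_V: np.ndarray  # (T, N, N)
    mean_nu: np.ndarray
    corr_nu: np.ndarray
    n_trials: int


def _corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diagonal(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        c = cov / np.outer(d, d)
    return np.clip(c, -1.0, 1.0)


def ensemble_statistics(ens: TrialEnsemble, act: ActivationSpec) -> EnsembleStats:
    n_trials, n_times, N = ens.V.shape
    mean_V = ens.V.mean(axis=0)
    cov_V = np.empty((n_times, N, N))
    corr_V = np.empty((n_times, N, N))
    mean_nu = np.empty((n_times, N))
    corr_nu = np.empty((n_times, N, N))
    for k in range(n_times):
        cov_V[k] = np.cov(ens.V[:, k, :], rowvar=False)
        corr_V[k] = _corr(cov_V[k])
        rates = act(ens.V[:, k, :])
        mean_nu[k] = rates.mean(axis=0)
        corr_nu[k] = _corr(np.cov(rates, rowvar=False))
    return EnsembleStats(ens.times, mean_V, cov_V, corr_V, mean_nu, corr_nu, n_trials)


def sample_higher_order(
    ens: TrialEnsemble, time_index: int, indices: Sequence[int]
) -> float:
    """Sample estimate of the normalized n-th order central correlation:
    ``E[prod dV_i] / ((n-1)!! prod std_i)``, the quantity whose Gaussian
    prediction is the Isserlis pairing sum."""
    idx = list(indices)
    n = len(idx)
    if n < 2:
        raise ValueError("need at least two neuron indices")
    if n % 2 == 1:
        # the Gaussian prediction is zero; return the raw normalized moment
        pass
    X = ens.V[:, time_index, idx]
    dX = X - X.mean(axis=0)
    num = np.prod(dX, axis=1).mean()
    stds = dX.std(axis=0, ddof=1)
    double_fact = float(np.prod(np.arange(n - 1, 0, -2))) if n % 2 == 0 else 1.0
    return float(num / (double_fact * np.prod(stds)))
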