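"""Generators for regular graph families with closed-form spectra.

The covariance formulas of the analytic engine need the eigendecomposition
of the adjacency matrix.  For block-circulant matrices with circulant
blocks (``F`` populations of ``G`` neurons each) the eigenvector matrix is
the Kronecker product of two Fourier matrices and the eigenvalues are
two-dimensional DFT coefficients of the first row; the hypercube ``Q_n`` is
diagonalized by the Sylvester Hadamard matrix.  Graph products (Cartesian,
tensor, strong, lexicographic) compose spectra by simple rules on the
factor eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import Topology

__all__ = [
    "SpectralDecomposition",
    "Graph",
    "WeightedGraph",
    "make_block_circulant",
    "make_circulant",
    "make_cyclic",
    "make_complete",
    "make_hypercube",
    "hadamard_matrix",
    "band_eigenvalues",
    "numeric_spectrum",
    "graph_product",
    "complement",
    "make_ring_model",
    "f_coefficients",
    "parse_graph_spec",
]


@dataclass(frozen=True)
class SpectralDecomposition:
    """Eigenvalues and eigenvector matrix (columns are eigenvectors)."""

    eigenvalues: np.ndarray
    P: np.ndarray
    P_inv: np.ndarray
    source: str = "closed_form"  # or "numeric"


@dataclass(frozen=True)
class Graph:
    """A topology bundled with its spectral decomposition."""

    topology: Topology
    spectrum: Optional[SpectralDecomposition]
    degree: Optional[int]  # uniform incoming degree, None if irregular
    name: str = ""

    @property
    def N(self) -> int:
        return self.topology.N


@dataclass(frozen=True)
class WeightedGraph:
    """Topology together with static weights ``T o Jbar_c``."""

    topology: Topology
    weights: np.ndarray
    spectrum: Optional[SpectralDecomposition]
    regular_topology: bool
    uniform_weights: bool
    name: str = ""


def _heaviside(x) -> int:
    """H(x) = 0 for x <= 0, 1 for x > 0 (the convention used throughout)."""
    return int(x > 0)


# ---------------------------------------------------------------------------
# Fourier / Hadamard eigenvector matrices


def fourier_matrix(K: int) -> np.ndarray:
    """Symmetric unitary DFT-type matrix ``R_K[i, j] = exp(2 pi i i j / K) / sqrt(K)``."""
    idx = np.arange(K)
    return np.exp(2j * np.pi * np.outer(idx, idx) / K) / np.sqrt(K)


def hadamard_matrix(N: int) -> np.ndarray:
    """Sylvester Hadamard matrix ``H_N`` for ``N = 2**n`` (``H_{2n} = H_2 (x) H_n``)."""
    if N < 1 or N & (N - 1):
        raise ValueError("Hadamard matrix defined here only for N a power of two")
    H = np.array([[1.0]])
    H2 = np.array([[1.0, 1.0], [1.0, -1.0]])
    while H.shape[0] < N:
        H = np.kron(H2, H)
    return H


def _block_circulant_P(F: int, G: int) -> tuple[np.ndarray, np.ndarray]:
    P = np.kron(fourier_matrix(F), fourier_matrix(G))
    return P, P.conj().T  # unitary


def block_circulant_eigenvalues(first_row: np.ndarray, F: int, G: int) -> np.ndarray:
    """Eigenvalues of a block-circulant matrix with circulant blocks, given
    its first row, ordered ``k = m G + n`` (``m`` over populations, ``n``
    within a population).  These are 2-D DFT coefficients of the first row
    reshaped to ``(F, G)``."""
    blocks = np.asarray(first_row, dtype=complex).reshape(F, G)
    m = np.arange(F)
    n = np.arange(G)
    wF = np.exp(2j * np.pi * np.outer(m, m) / F)
    wG = np.exp(2j * np.pi * np.outer(n, n) / G)
    return (wF @ blocks @ wG.T).reshape(F * G)


def _assemble_block_circulant(first_row: np.ndarray, F: int, G: int) -> np.ndarray:
    """Full matrix with block ``(p, q) = B^((q - p) mod F)`` and each block
    circulant with entries ``b[(j - i) mod G]``."""
    blocks = np.asarray(first_row).reshape(F, G)
    N = F * G
    out = np.empty((N, N), dtype=blocks.dtype)
    gi = np.arange(G)
    shift = (gi[np.newaxis, :] - gi[:, np.newaxis]) % G  # (j - i) mod G
    for p in range(F):
        for q in range(F):
            out[p * G : (p + 1) * G, q * G : (q + 1) * G] = blocks[(q - p) % F][shift]
    return out


# ---------------------------------------------------------------------------
# block-circulant banded family


def _band_first_rows(F: int, G: int, xi: Sequence[int]) -> np.ndarray:
    """First rows of the banded circulant blocks B^(0) .. B^(F-1)."""
    if G < 3:
        raise ValueError("block-circulant band graphs need G >= 3")
    xi = list(xi)
    if len(xi) != F:
        raise ValueError("need one half-bandwidth xi per population (length F)")
    half = G // 2
    rows = np.zeros((F, G), dtype=np.int64)
    for i, x in enumerate(xi):
        if not 1 <= x <= half:
            raise ValueError(f"xi must satisfy 1 <= xi <= floor(G/2); got {x}")
        rho = G - x + _heaviside(x - half + (-1) ** G)
        j = np.arange(G)
        rows[i] = ((1 <= j) & (j <= x)) | ((rho <= j) & (j <= G - 1))
        rows[i, 0] = 0 if i == 0 else 1
    return rows


def band_eigenvalues(F: int, G: int, xi: Sequence[int]) -> np.ndarray:
    """Closed-form eigenvalues of the banded block-circulant family,
    ordered ``k = m G + n``.

    ``g(n, xi, G)`` is the circulant-band eigenvalue: ``2 xi - H(...)`` at
    ``n = 0``, ``-1`` for a full band, and the Dirichlet kernel ratio
    ``sin(pi n (2 xi + 1)/G)/sin(pi n / G) - 1`` otherwise.
    """
    half = G // 2

    def g(n: int, x: int) -> float:
        if n == 0:
            return 2 * x - _heaviside(x - half + (-1) ** G)
        if x == half:
            return -1.0
        return np.sin(np.pi * n * (2 * x + 1) / G) / np.sin(np.pi * n / G) - 1.0

    lam = np.empty(F * G, dtype=complex)
    for m in range(F):
        for n in range(G):
            if m == 0:
                lam[n] = F - 1 + sum(g(n, x) for x in xi)
            else:
                lam[m * G + n] = -1 + sum(
                    np.exp(2j * np.pi * m * k / F) * g(n, x)
                    for k, x in enumerate(xi)
                )
    return lam


def make_block_circulant(F: int, G: int, xi: Sequence[int]) -> Graph:
    """Banded block-circulant graph ``BC_{F,G}(M_0, ..., M_{F-1})``.

    ``xi[i]`` is the half-bandwidth of block ``B^(i)`` (bandwidth
    ``2 xi + 1``); every neuron receives ``M_0 = 2 xi_0 - H(.)`` connections
    from its own population and ``M_i = 2 xi_i + 1 - H(.)`` from the
    population ``i`` steps away, for a uniform incoming degree
    ``M = F - 1 + sum_i (2 xi_i - H(.))``.
    """
    rows = _band_first_rows(F, G, xi)
    T = _assemble_block_circulant(rows.reshape(-1), F, G)
    top = Topology(T)
    P, P_inv = _block_circulant_P(F, G)
    lam = band_eigenvalues(F, G, xi)
    half = G // 2
    M = F - 1 + sum(2 * x - _heaviside(x - half + (-1) ** G) for x in xi)
    blockM = [2 * xi[0] - _heaviside(xi[0] - half + (-1) ** G)] + [
        2 * x + 1 - _heaviside(x - half + (-1) ** G) for x in xi[1:]
    ]
    name = f"BC_{{{F},{G}}}({','.join(str(m) for m in blockM)})"
    return Graph(top, SpectralDecomposition(lam, P, P_inv), int(M), name)


def make_circulant(N: int, xi: int) -> Graph:
    """Circulant graph ``Ci_N(1, ..., xi)``; ``xi = 1`` is the cycle ``C_N``
    and ``xi = floor(N/2)`` the complete graph ``K_N``."""
    g = make_block_circulant(1, N, [xi])
    half = N // 2
    if xi == half and g.degree == N - 1:
        name = f"K_{N}"
    elif xi == 1:
        name = f"C_{N}"
    else:
        name = f"Ci_{N}(1..{xi})"
    return Graph(g.topology, g.spectrum, g.degree, name)


def make_cyclic(N: int) -> Graph:
    return make_circulant(N, 1)


def make_complete(N: int) -> Graph:
    return make_circulant(N, N // 2)


# ---------------------------------------------------------------------------
# hypercube


def make_hypercube(n: int) -> Graph:
    """Hypercube ``Q_n`` (``N = 2**n``, regular with ``M = n``) built by the
    recursion ``T_{Q_n} = [[T_{Q_{n-1}}, Id], [Id, T_{Q_{n-1}}]]``; its
    eigenvalues are ``n - 2 m`` with multiplicity ``C(n, m)`` and its
    eigenvectors the columns of the Hadamard matrix."""
    if n < 1:
        raise ValueError("hypercube dimension must be >= 1")
    T = np.array([[0, 1], [1, 0]], dtype=np.int64)
    for _ in range(n - 1):
        size = T.shape[0]
        eye = np.eye(size, dtype=np.int64)
        T = np.block([[T, eye], [eye, T]])
    N = 2**n
    H = hadamard_matrix(N)
    P = H / np.sqrt(N)
    k = np.arange(N)
    popcount = np.array([bin(x).count("1") for x in k])
    lam = (n - 2 * popcount).astype(complex)
    return Graph(Topology(T), SpectralDecomposition(lam, P, P.T.copy()), n, f"Q_{n}")


# ---------------------------------------------------------------------------
# generic / numeric


def numeric_spectrum(top: Topology) -> SpectralDecomposition:
    T = top.T.astype(float)
    if np.array_equal(T, T.T):
        lam, P = np.linalg.eigh(T)
        return SpectralDecomposition(lam.astype(complex), P, P.T.copy(), "numeric")
    lam, P = np.linalg.eig(T)
    return SpectralDecomposition(lam, P, np.linalg.inv(P), "numeric")


def from_topology(top: Topology, name: str = "custom") -> Graph:
    M = top.M
    degree = int(M[0]) if top.regular else None
    return Graph(top, numeric_spectrum(top), degree, name)


def complement(g: Graph) -> Graph:
    """Graph complement (spectrum computed numerically)."""
    N = g.N
    T = 1 - g.topology.T - np.eye(N, dtype=np.int64)
    top = Topology(T)
    degree = N - 1 - g.degree if g.degree is not None else None
    return Graph(top, numeric_spectrum(top), degree, f"complement({g.name})")


# ---------------------------------------------------------------------------
# graph products

_PRODUCT_KINDS = ("cartesian", "tensor", "strong", "lexicographic")
_PRODUCT_SYMBOL = {
    "cartesian": "box",
    "tensor": "x",
    "strong": "strong",
    "lexicographic": "lex",
}


def graph_product(kind: str, g: Graph, h: Graph) -> Graph:
    """Binary graph product with spectrum composed from the factor spectra.

    Eigenvalue rules for factor pairs ``(lam_g, lam_h)``: sum (Cartesian),
    product (tensor), ``(lam_g + 1)(lam_h + 1) - 1`` (strong); for the
    lexicographic product (which needs a regular second factor) the
    eigenvalues are ``lam_g N_h + M_h`` paired with the all-ones eigenvector
    of ``h`` and ``lam_h`` for the remaining eigenvectors.  Composed
    eigenvectors are Kronecker products, ordered ``k = i N_h + j``.
    """
    if kind not in _PRODUCT_KINDS:
        raise ValueError(f"unknown product kind {kind!r}; choose from {_PRODUCT_KINDS}")
    Tg, Th = g.topology.T, h.topology.T
    Ng, Nh = g.N, h.N
    if kind == "cartesian":
        T = np.kron(Tg, np.eye(Nh, dtype=np.int64)) + np.kron(np.eye(Ng, dtype=np.int64), Th)
        rule = lambda a, b: a + b
        deg = None if g.degree is None or h.degree is None else g.degree + h.degree
    elif kind == "tensor":
        T = np.kron(Tg, Th)
        rule = lambda a, b: a * b
        deg = None if g.degree is None or h.degree is None else g.degree * h.degree
    elif kind == "strong":
        T = (
            np.kron(Tg + np.eye(Ng, dtype=np.int64), Th + np.eye(Nh, dtype=np.int64))
            - np.eye(Ng * Nh, dtype=np.int64)
        )
        rule = lambda a, b: (a + 1) * (b + 1) - 1
        deg = (
            None
            if g.degree is None or h.degree is None
            else (g.degree + 1) * (h.degree + 1) - 1
        )
    else:  # lexicographic
        T = np.kron(Tg, np.ones((Nh, Nh), dtype=np.int64)) + np.kron(
            np.eye(Ng, dtype=np.int64), Th
        )
        rule = None
        deg = None if g.degree is None or h.degree is None else g.degree * Nh + h.degree
    top = Topology(T)
    name = f"{g.name} {_PRODUCT_SYMBOL[kind]} {h.name}"

    sg, sh = g.spectrum, h.spectrum
    if sg is None or sh is None:
        return Graph(top, numeric_spectrum(top), deg, name)

    if kind == "lexicographic":
        col0 = sh.P[:, 0]
        ones_like = np.allclose(col0, col0[0]) and abs(col0[0]) > 0
        if h.degree is None or not ones_like:
            # spectrum-composition rule needs a regular second factor with the
            # all-ones eigenvector in the leading column
            return Graph(top, None, deg, name)
        lam = np.empty(Ng * Nh, dtype=complex)
        for i in range(Ng):
            lam[i * Nh] = sg.eigenvalues[i] * Nh + h.degree
            lam[i * Nh + 1 : (i + 1) * Nh] = sh.eigenvalues[1:]
    else:
        lam = rule(
            np.repeat(sg.eigenvalues, Nh), np.tile(sh.eigenvalues, Ng)
        ).astype(complex)
    P = np.kron(sg.P, sh.P)
    P_inv = np.kron(sg.P_inv, sh.P_inv)
    source = (
        "closed_form" if sg.source == sh.source == "closed_form" else "numeric"
    )
    return Graph(top, SpectralDecomposition(lam, P, P_inv, source), deg, name)


# ---------------------------------------------------------------------------
# ring model (orientation hypercolumn)


def make_ring_model(
    F: int, G: int, Gamma: float, Delta: float, theta0: float = 0.0
) -> WeightedGraph:
    """Ring-model hypercolumn: ``F`` minicolumns of ``G`` neurons with
    orientation-tuned all-to-all weights
    ``Gamma + Delta cos(2 (theta_p(i) - theta_p(j)))`` where
    ``theta_p(i) = theta0 + (pi/F) floor(i/G)``.

    The topology is complete (``M = N - 1``); the weight matrix is
    block-circulant with in-block weight ``Gamma + Delta`` and ``k``-th
    off-block weight ``Gamma + Delta cos(2 pi k / F)``, so every row sums to
    ``(N - 1) Gamma - Delta`` and the spectrum follows from the same Fourier
    eigenvectors as the unweighted block-circulant family.  ``Delta = 0``
    recovers the uniform complete graph.
    """
    N = F * G
    theta = theta0 + (np.pi / F) * (np.arange(N) // G)
    W = Gamma + Delta * np.cos(2.0 * (theta[:, np.newaxis] - theta[np.newaxis, :]))
    np.fill_diagonal(W, 0.0)
    T = np.ones((N, N), dtype=np.int64) - np.eye(N, dtype=np.int64)
    top = Topology(T)
    P, P_inv = _block_circulant_P(F, G)
    lam = block_circulant_eigenvalues(W[0], F, G)
    spec = SpectralDecomposition(lam, P, P_inv)
    return WeightedGraph(
        top, W, spec, True, Delta == 0.0, f"ring_{{{F},{G}}}(G={Gamma},D={Delta})"
    )


# ---------------------------------------------------------------------------
# f coefficients (regular-family covariance reductions)


def f_coefficients(g: Graph, i: int, j: int) -> np.ndarray:
    """Vector ``f_ijk = N P_ik conj(P_jk)`` over ``k`` for the closed-form
    families; satisfies ``sum_j f_ijk = N delta_0k``."""
    if g.spectrum is None:
        raise ValueError("graph carries no spectral decomposition")
    P = g.spectrum.P
    return g.N * P[i, :] * np.conj(P[j, :])


# ---------------------------------------------------------------------------
# graph specification mini-grammar


def parse_graph_spec(spec: str) -> Graph:
    """Parse a graph specification string.

    Grammar: ``complete:N``, ``cyclic:N``, ``circulant:N:xi``,
    ``blockcirculant:F:G:xi0,xi1,...``, ``hypercube:n``,
    ``product:kind:specA:specB``, ``ring:F:G:Gamma:Delta`` (unweighted
    topology; use :func:`make_ring_model` for the weights), ``file:path``.
    """
    tokens = spec.strip().split(":")
    graph, rest = _parse_tokens(tokens)
    if rest:
        raise ValueError(f"trailing tokens in graph spec: {':'.join(rest)}")
    return graph


def _parse_tokens(tokens):
    if not tokens:
        raise ValueError("empty graph specification")
    head, rest = tokens[0], tokens[1:]
    if head == "complete":
        return make_complete(int(rest[0])), rest[1:]
    if head == "cyclic":
        return make_cyclic(int(rest[0])), rest[1:]
    if head == "circulant":
        return make_circulant(int(rest[0]), int(rest[1])), rest[2:]
    if head == "blockcirculant":
        F, G = int(rest[0]), int(rest[1])
        xi = [int(x) for x in rest[2].split(",")]
        return make_block_circulant(F, G, xi), rest[3:]
    if head == "hypercube":
        return make_hypercube(int(rest[0])), rest[1:]
    if head == "product":
        kind = rest[0]
        a, rem = _parse_tokens(rest[1:])
        b, rem = _parse_tokens(rem)
        return graph_product(kind, a, b), rem
    if head == "ring":
        wg = make_ring_model(int(rest[0]), int(rest[1]), float(rest[2]), float(rest[3]))
        return (
            Graph(wg.topology, numeric_spectrum(wg.topology), wg.topology.N - 1, wg.name),
            rest[4:],
        )
    if head == "file":
        from .model import read_adjacency

        path = ":".join(rest)  # paths may contain colons
        top = read_adjacency(path)
        return from_topology(top, f"file:{path}"), []
    raise ValueError(f"unknown graph family {head!r}")
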