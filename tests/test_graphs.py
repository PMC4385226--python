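import numpy as np
import pytest

from neurocorr import (
    graph_product,
    make_block_circulant,
    make_circulant,
    make_complete,
    make_cyclic,
    make_hypercube,
    make_ring_model,
    parse_graph_spec,
)
from neurocorr.graphs import (
    band_eigenvalues,
    complement,
    f_coefficients,
    from_topology,
    hadamard_matrix,
)


def _check_spectrum(g, atol=1e-12):
    """Closed-form decomposition must diagonalize the adjacency exactly."""
    T = g.topology.T.astype(float)
    s = g.spectrum
    rec = s.P @ np.diag(s.eigenvalues) @ s.P_inv
    assert np.max(np.abs(rec - T)) < 1e-10
    lam_n = np.sort(np.linalg.eigvals(T).real)
    assert np.allclose(np.sort(s.eigenvalues.real), lam_n, atol=1e-8)
    assert np.allclose(s.P @ s.P_inv, np.eye(g.N), atol=1e-10)


@pytest.mark.parametrize(
    "g",
    [
        make_cyclic(10),
        make_cyclic(7),
        make_complete(10),
        make_complete(5),
        make_circulant(11, 3),
        make_block_circulant(3, 10, [2, 2, 2]),
        make_block_circulant(2, 7, [1, 3]),
        make_hypercube(4),
        make_hypercube(1),
    ],
)
def test_closed_form_spectra(g):
    _check_spectrum(g)
    assert (g.topology.M == g.degree).all()
    # leading eigenvalue of a regular graph is the degree, eigenvector all-ones
    assert g.spectrum.eigenvalues[0].real == pytest.approx(g.degree)
    col0 = g.spectrum.P[:, 0]
    assert np.allclose(col0, col0[0])


def test_complete_graph_spectrum_values():
    lam = np.sort(make_complete(10).spectrum.eigenvalues.real)
    assert np.allclose(lam, np.r_[np.full(9, -1.0), 9.0], atol=1e-12)


def test_cyclic_spectrum_values():
    g = make_cyclic(12)
    lam = g.spectrum.eigenvalues
    expect = 2.0 * np.cos(2.0 * np.pi * np.arange(12) / 12)
    assert np.allclose(lam.real, expect, atol=1e-12)
    assert np.max(lam.real) == pytest.approx(2.0)


def test_block_circulant_naming_and_degree():
    g = make_block_circulant(3, 10, [2, 2, 2])
    assert g.name == "BC_{3,10}(4,5,5)"
    assert g.degree == 14
    assert g.N == 30


def test_band_eigenvalues_match_assembled_matrix():
    for F, G, xi in [(3, 10, [2, 2, 2]), (1, 9, [4]), (2, 8, [1, 4]), (4, 5, [2, 1, 2, 1])]:
        g = make_block_circulant(F, G, xi)
        lam_c = np.sort(band_eigenvalues(F, G, xi).real)
        lam_n = np.sort(np.linalg.eigvals(g.topology.T.astype(float)).real)
        assert np.allclose(lam_c, lam_n, atol=1e-8)


def test_band_parameter_validation():
    with pytest.raises(ValueError):
        make_block_circulant(2, 2, [1, 1])  # G too small
    with pytest.raises(ValueError):
        make_block_circulant(2, 8, [5, 1])  # xi > G/2
    with pytest.raises(ValueError):
        make_block_circulant(2, 8, [1])  # wrong length


def test_circulant_extremes_match_named_graphs():
    assert np.array_equal(
        make_circulant(9, 1).topology.T, make_cyclic(9).topology.T
    )
    assert np.array_equal(
        make_circulant(9, 4).topology.T, make_complete(9).topology.T
    )


def test_hypercube_structure():
    g = make_hypercube(4)
    T = g.topology.T
    assert g.N == 16 and g.degree == 4
    # neighbors differ in exactly one bit
    for i in range(16):
        nbrs = np.nonzero(T[i])[0]
        assert all(bin(i ^ j).count("1") == 1 for j in nbrs)
    lam = np.sort(g.spectrum.eigenvalues.real)
    mult = {v: int(np.sum(np.isclose(lam, v))) for v in (-4, -2, 0, 2, 4)}
    assert mult == {-4: 1, -2: 4, 0: 6, 2: 4, 4: 1}


def test_hadamard_matrix_orthogonality():
    H = hadamard_matrix(8)
    assert np.allclose(H @ H.T, 8 * np.eye(8))
    with pytest.raises(ValueError):
        hadamard_matrix(6)


@pytest.mark.parametrize("kind,deg", [
    ("cartesian", 5), ("tensor", 6), ("strong", 11), ("lexicographic", 26),
])
def test_graph_products_spectrum_and_degree(kind, deg):
    g = graph_product(kind, make_complete(4), make_cyclic(8))
    assert g.degree == deg
    assert (g.topology.M == deg).all()
    _check_spectrum(g)


def test_lexicographic_needs_regular_second_factor():
    # irregular second factor: path-like custom graph
    from neurocorr.model import Topology

    T = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    h = from_topology(Topology(T), "path3")
    g = graph_product("lexicographic", make_complete(3), h)
    # topology is still built, spectrum composition is declined
    assert g.spectrum is None
    assert (g.topology.M == g.topology.M[0]).all() is not None


def test_complement_of_cycle():
    g = complement(make_cyclic(7))
    assert g.degree == 4
    assert (g.topology.M == 4).all()
    lam = np.sort(g.spectrum.eigenvalues.real)
    lam_n = np.sort(np.linalg.eigvalsh(g.topology.T.astype(float)))
    assert np.allclose(lam, lam_n, atol=1e-10)


def test_ring_model_weights_and_spectrum():
    wg = make_ring_model(3, 10, Gamma=1.0, Delta=0.5)
    N = 30
    assert np.allclose(np.diagonal(wg.weights), 0.0)
    # row sums (N-1) Gamma - Delta
    assert np.allclose(wg.weights.sum(axis=1), (N - 1) * 1.0 - 0.5)
    lam_c = np.sort(wg.spectrum.eigenvalues.real)
    lam_n = np.sort(np.linalg.eigvalsh(wg.weights))
    assert np.allclose(lam_c, lam_n, atol=1e-8)
    # Delta = 0 reduces to the uniform complete graph
    uni = make_ring_model(3, 10, Gamma=1.0, Delta=0.0)
    assert uni.uniform_weights
    assert np.max(np.abs(uni.weights - (1.0 - np.eye(N)))) < 1e-12


def test_f_coefficients_sum_rule():
    for g in (make_cyclic(8), make_hypercube(3), make_block_circulant(2, 6, [2, 1])):
        N = g.N
        total = np.zeros(N, dtype=complex)
        for j in range(N):
            total += f_coefficients(g, 2 % N, j)
        expect = np.zeros(N)
        expect[0] = N
        assert np.allclose(total, expect, atol=1e-9)


@pytest.mark.parametrize(
    "spec,N,deg",
    [
        ("complete:10", 10, 9),
        ("cyclic:12", 12, 2),
        ("circulant:11:3", 11, 6),
        ("blockcirculant:3:10:2,2,2", 30, 14),
        ("hypercube:4", 16, 4),
        ("product:cartesian:complete:4:cyclic:8", 32, 5),
        ("ring:3:10:1.0:0.5", 30, 29),
    ],
)
def test_parse_graph_spec(spec, N, deg):
    g = parse_graph_spec(spec)
    assert g.N == N and g.degree == deg


def test_parse_graph_spec_errors():
    with pytest.raises(ValueError):
        parse_graph_spec("nope:5")
    with pytest.raises(ValueError):
        parse_graph_spec("complete:10:extra")


def test_parse_graph_spec_file(tmp_path):
    from neurocorr.model import write_adjacency

    g = make_cyclic(6)
    p = tmp_path / "adj.txt"
    write_adjacency(p, g.topology)
    loaded = parse_graph_spec(f"file:{p}")
    assert np.array_equal(loaded.topology.T, g.topology.T)
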