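import numpy as np
import pytest

from neurocorr import (
    build_jacobian,
    make_complete,
    solve_equilibrium,
)
from neurocorr.experiments import reference_activation, reference_params


@pytest.fixture(scope="session")
def ref_act():
    return reference_activation()


@pytest.fixture(scope="session")
def ref_params():
    return reference_params().with_sigma(np.full(5, 0.1))


@pytest.fixture(scope="session")
def k10(ref_act, ref_params):
    """Complete graph K_10 with equilibrium and Jacobian (reference setup)."""
    g = make_complete(10)
    eq = solve_equilibrium(g.topology, ref_params, ref_act)
    jac = build_jacobian(g.topology, ref_params, eq)
    return g, eq, jac
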