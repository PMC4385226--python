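# neurocorr

Analytic cross-correlation structure of finite-size stochastic firing-rate
networks.

## The problem

A network of `N` rate neurons obeys the stochastic differential equation

```
dV_i = [ -V_i/tau + (1/M_i) * sum_j J_ij(t) A(V_j) + I_i(t) ] dt + sigma0 dB_i
V_i(0) = mu_i + sigma1 * N_i
```

where `A` is a sigmoidal activation, `T` a binary adjacency matrix with
incoming degrees `M_i`, and three Gaussian randomness sources perturb the
system: Brownian noise (pairwise correlation `C0`), random initial
conditions (`C1`) and quenched random synaptic weights (`C2`), plus two
small deterministic modulations of the weights and the input current.

Simulating such a network to estimate correlations between neurons is
expensive and noisy.  This package instead linearizes the dynamics around
the deterministic equilibrium and evaluates the correlation structure *in
closed form*: the covariance splits into one term per randomness source,
each reducible in the Jacobian eigenbasis to the scalar primitive
`(exp(z t) - 1)/z`.  For regular graph families (circulant,
block-circulant, hypercube, and their graph products) the adjacency
spectrum itself is known in closed form, so the entire correlation matrix
costs a few matrix multiplications — or O(1) scalars for the complete
graph, at any size.

On top of the covariance engine the package provides:

- pairwise Pearson correlations, higher-order Gaussian correlations
  (Isserlis pairings), Gaussian mutual information;
- the joint Gaussian state of potentials and rates, and the quasi-Monte
  Carlo probability that the state stays inside the Taylor-convergence box
  of the activation (validity of the expansion);
- an Euler–Maruyama Monte Carlo simulator with correlated noise sources,
  used to validate the analytics (relative errors of a few percent up to
  perturbation strengths of order one);
- finite-size diagnostics: correlated randomness prevents propagation of
  chaos (the infinite-size correlation limit is nonzero whenever any `C`
  is), and marginally stable networks synchronize stochastically
  (correlation tends to 1 despite independent noise).

## Worked example

```python
import numpy as np
from neurocorr import (
    ActivationSpec, NetworkParams, make_complete,
    solve_equilibrium, build_jacobian, covariance_terms,
    pairwise_correlation, gaussian_state, validity_probability,
)

act = ActivationSpec("logistic", nu_max=1.0, Lambda=1.0, V_T=0.0)
params = NetworkParams(tau=1.0, Jbar_c=1.0, I_c=1.0,
                       sigma=np.full(5, 0.1), C0=0.4, C1=0.5, C2=0.6)
g = make_complete(10)

eq  = solve_equilibrium(g.topology, params, act)   # mu ~ 1.86599
jac = build_jacobian(g.topology, params, eq)
cov = covariance_terms(jac, g.topology, eq, params, t=1.0)
corr = pairwise_correlation(cov, params)
print(corr[0, 1])                                   # 0.58595...

state = gaussian_state(jac, g.topology, eq, params, act, t=1.0)
radii = np.asarray(act.radius_of_convergence(eq.mu))
print(validity_probability(state, radii).value)     # 1.0
```

Running this prints an equilibrium potential of about `1.866`, a pairwise
correlation of about `0.586` for every neuron pair of the complete graph at
`t = 1`, and a Taylor-validity probability of `1.0`.

## Command line

```bash
neurocorr spectrum blockcirculant:3:10:2,2,2     # closed-form eigenvalues
neurocorr analytic  --config run.yaml --out-dir results
neurocorr simulate  --config run.yaml --seed 7 --out-dir results
neurocorr compare   --config run.yaml --out-dir results
neurocorr sweep-ic  --config run.yaml --ic-min -5 --ic-max 5
neurocorr chaos     --sizes 8,64,512
neurocorr sync      --graph complete:8 --ic -1.0
neurocorr benchmark --trials 10000                # full validation (slow)
```

Every command writes CSV/JSON results plus a `provenance.json` (package
version, resolved config, seed).  See `neurocorr <cmd> --help` and the
config schema in `src/neurocorr/config.py`.

## Reproduction

- `python -m pytest -q tests/` runs the full suite, including one
  acceptance test per validation criterion (`tests/test_acceptance.py`).
  The strict all-pairs form of the Monte Carlo error bound is expected to
  fail for statistical reasons quantified in `docs/methods.md`; all other
  criteria pass.
- `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  recomputes the validity-probability target from scratch (~1 s).
- `neurocorr benchmark` reruns the analytic-vs-Monte-Carlo accuracy table
  (four topologies x four perturbation strengths, 10^4 trials; ~3 min).

Details of the numerical methods, parameter conventions and known
limitations are in `docs/methods.md`.
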