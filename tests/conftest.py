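import numpy as np
import pytest

from activegel.spring_network import (ActivationGeometry, activate, build_grid,
                                      solve_equilibrium)


@pytest.fixture(scope="session")
def circle_equilibrium():
    """Solved circular activation (radius 10, cell 120 = 6 diameters, K=0.13).

    Shared by shape-metric and property tests; solving it once keeps the
    suite fast.
    """
    net = build_grid(120, 120, 1.0)
    geo = ActivationGeometry("circle", radius=10.0)
    problem = solve_equilibrium(activate(net, geo, 0.13))
    return problem, geo


def dense_energy_minimum(network):
    """Independent oracle: minimize the total spring energy densely.

    Uses BFGS-family minimization over all node coordinates with the
    analytic gradient (the negative net force), then removes the mean
    displacement — a completely separate path from the sparse linear solve.
    """
    from scipy.optimize import minimize

    i, j = network.edges[:, 0], network.edges[:, 1]
    k = network.coefficients
    off = network.offsets
    n = network.n_nodes

    def energy_grad(flat):
        pos = flat.reshape(n, 2)
        vec = pos[j] + off - pos[i]
        e = 0.5 * np.sum(k * np.einsum("ij,ij->i", vec, vec))
        f = np.zeros_like(pos)
        np.add.at(f, i, k[:, None] * vec)
        np.add.at(f, j, -k[:, None] * vec)
        return e, -f.ravel()

    def hess(flat):
        h = np.zeros((2 * n, 2 * n))
        for e_idx in range(len(k)):
            a, b = i[e_idx], j[e_idx]
            for c in (0, 1):
                ia, ib = 2 * a + c, 2 * b + c
                h[ia, ia] += k[e_idx]
                h[ib, ib] += k[e_idx]
                h[ia, ib] -= k[e_idx]
                h[ib, ia] -= k[e_idx]
        return h

    res = minimize(energy_grad, network.positions.ravel(), jac=True,
                   method="trust-exact", hess=hess,
                   options={"gtol": 1e-13, "maxiter": 5000})
    pos = res.x.reshape(n, 2)
    u = pos - network.positions
    return network.positions + (u - u.mean(axis=0))
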