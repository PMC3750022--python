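"""Independent oracles used by the test suite.

These deliberately avoid the package's bracketing/polishing machinery:
roots are found by a brute-force dense-grid sign scan refined by plain
bisection, and stability by forward integration from small perturbations.
"""

import numpy as np

from tcswitch.steady import pstar_upper_bound, scalar_residual
from tcswitch.models import integrate, pstar_index, rhs_for


def dense_grid_roots(model, params, n_points=200_000):
    """Brute-force root scan of the scalar balance equation.

    Log-spaced grid of >= n_points across the full admissible Pstar range,
    sign-change detection, and 80 rounds of interval bisection per root.
    """
    g, _ = scalar_residual(model, params)
    hi = pstar_upper_bound(params)
    grid = np.concatenate([[0.0], np.logspace(-12, np.log10(hi), n_points)])
    vals = np.asarray(g(grid))
    roots = []
    if vals[0] == 0.0:
        roots.append(0.0)
    idx = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    for i in idx:
        a, b = grid[i], grid[i + 1]
        fa = vals[i]
        if fa == 0.0:
            roots.append(a)
            continue
        for _ in range(80):
            m = 0.5 * (a + b)
            fm = float(g(m))
            if fm == 0.0:
                a = b = m
                break
            if (fm > 0) == (fa > 0):
                a, fa = m, fm
            else:
                b = m
        roots.append(0.5 * (a + b))
    return np.array(sorted(roots))


def stability_by_integration(model, params, state, eps=1e-3, horizon_gens=400):
    """Classify a steady state by where perturbed trajectories settle.

    Returns "stable" if +/-eps perturbations of the PhoP-P component return
    to the state, "unstable" if either diverges to a different attractor.
    """
    idx = pstar_index(model)
    state = np.asarray(state, dtype=float)
    ps0 = state[idx]
    t_final = horizon_gens * np.log(2) / params.lam
    for sgn in (+1, -1):
        y0 = state.copy()
        y0[idx] = max(ps0 * (1 + sgn * eps) + sgn * eps * 1e-9, 0.0)
        fin = integrate(model, params, y0, t_final).y[idx, -1]
        if abs(fin - ps0) > 0.05 * max(ps0, 1e-8) + 1e-8:
            return "unstable"
    return "stable"
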