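"""Steady states, stability, regimes, bifurcation sweeps and bistability maps.

For every model variant the steady-state condition reduces to a scalar
balance equation in the PhoP-P concentration ``Pstar``:

* reduced: the operon balance gives the total protein scale
  ``T = F(Pstar)/lam`` with ``Q = T`` and ``P = T - Pstar``, leaving the
  phospho-balance ``g(Pstar) = k_k (T - Pstar) T - k_p Pstar T - lam Pstar``.
* detailed: the complex and PhoQ-P balances are linear in free PhoQ once the
  free-PhoP concentration ``P`` is fixed, and the remaining 1-D equation for
  ``P`` is strictly monotone, so the inner solve is unique and ``g(Pstar)``
  is single-valued.
* decoupled: same structure with the PhoQ family clamped to ``Q_tot``.

Roots are bracketed by sign changes on a log-spaced grid (the OFF root can
sit many orders of magnitude below the ON root) and polished by Brent's
method; stability comes from the eigenvalues of the numerical Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .models import pstar_index, rhs_for, state_dim
from .params import DecoupledParams, DetailedParams, Params, ReducedParams

__all__ = [
    "SteadyStateSet", "BranchTable", "RegimeMap",
    "find_steady_states", "jacobian_stability", "classify_regime",
    "bifurcation_sweep", "bistability_scan", "clamp_for_display",
    "scalar_residual",
]

DISPLAY_FLOOR = 1e-4
#: eigenvalue real parts within this of zero are flagged marginal
STABILITY_TIE_TOL = 1e-9


def clamp_for_display(value):
    """Floor steady-state values at 1e-4 for log-scale display."""
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError("display values must be nonnegative")
    out = np.maximum(value, DISPLAY_FLOOR)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# scalar balance residuals
# ---------------------------------------------------------------------------

def _reduced_residual(p: ReducedParams):
    def g(ps):
        ps = np.asarray(ps, dtype=float)
        T = p.promoter(ps) / p.lam
        return p.k_k * (T - ps) * T - p.k_p * ps * T - p.lam * ps

    def reconstruct(ps):
        T = p.promoter(ps) / p.lam
        return np.array([max(T - ps, 0.0), T, ps])

    return g, reconstruct


def _decoupled_reduced_residual(p: DecoupledParams):
    def g(ps):
        ps = np.asarray(ps, dtype=float)
        T = p.promoter(ps) / p.lam
        return p.k_k * (T - ps) * p.Q_tot - p.k_p * ps * p.Q_tot - p.lam * ps

    def reconstruct(ps):
        T = p.promoter(ps) / p.lam
        return np.array([max(T - ps, 0.0), ps])

    return g, reconstruct


def _bisect_monotone(f, lo, hi, iters=200):
    """Vectorized bisection for elementwise-monotone increasing f."""
    lo = np.array(lo, dtype=float)
    hi = np.array(hi, dtype=float)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        pos = f(mid) > 0
        hi = np.where(pos, mid, hi)
        lo = np.where(pos, lo, mid)
    return 0.5 * (lo + hi)


def _decoupled_seq_residual(p: DecoupledParams):
    """Balance residual for the sequestration-cycle decoupled model.

    Inner unknown is free PhoP ``P``; free PhoQ follows from the clamp
    ``Q (1 + a)(1 + k_a/(k_t P + lam)) = Q_tot`` with complex occupancy
    ``a = k_on_p Pstar / (k_off_p + k_a + lam)``, and the PhoP-family
    balance ``P + a Q(P) = F/lam - Pstar`` is strictly increasing in ``P``.
    Outer residual: ``g = k_t P Qstar - lam (Pstar + C_p)``.
    """
    esc = p.k_off_p + p.k_a + p.lam

    def solve_inner(ps):
        ps = np.atleast_1d(np.asarray(ps, dtype=float))
        f = p.promoter(ps)
        S = f / p.lam - ps
        a = p.k_on_p * ps / esc

        def qofp(P):
            return p.Q_tot / ((1 + a) * (1 + p.k_a / (p.k_t * P + p.lam)))

        def hres(P):
            return P + a * qofp(P) - S

        feasible = S > 0
        Smax = np.where(feasible, S, 1.0)
        no_sol = hres(np.zeros_like(S)) > 0
        P = _bisect_monotone(hres, np.zeros_like(S), Smax)
        Q = qofp(P)
        Qs = p.k_a * Q * (1 + a) / (p.k_t * P + p.lam)
        Cp = a * Q
        ok = feasible & ~no_sol
        return P, Q, Qs, Cp, ok

    def g(ps):
        ps_arr = np.atleast_1d(np.asarray(ps, dtype=float))
        P, Q, Qs, Cp, ok = solve_inner(ps_arr)
        out = np.where(ok, p.k_t * P * Qs - p.lam * (ps_arr + Cp), -p.lam * ps_arr - 1e-30)
        return out[0] if np.isscalar(ps) or np.ndim(ps) == 0 else out

    def reconstruct(ps):
        P, Q, Qs, Cp, ok = solve_inner(ps)
        return np.array([P[0], float(np.atleast_1d(ps)[0]), Qs[0], Cp[0]])

    return g, reconstruct


def _detailed_residual(p: DetailedParams):
    """Balance residual for the six-species autoregulated model."""
    a_den = p.k_off_p + p.k_cat_p + p.lam
    t_den = p.k_off_t + p.k_cat_t + p.lam
    b = p.k_on_t / t_den
    c1 = p.k_on_t * (p.k_cat_t + p.lam) / t_den

    def solve_inner(ps):
        ps = np.atleast_1d(np.asarray(ps, dtype=float))
        f = p.promoter(ps)
        T = f / p.lam
        S = T - ps
        a = p.k_on_p * ps / a_den

        def qofp(P):
            return T / (1 + a + p.k_a * (1 + b * P) / (c1 * P + p.lam))

        def hres(P):
            Q = qofp(P)
            Qs = p.k_a * Q / (c1 * P + p.lam)
            return P + b * P * Qs + a * Q - S

        feasible = S > 0
        Smax = np.where(feasible, S, 1.0)
        no_sol = hres(np.zeros_like(S)) > 0
        P = _bisect_monotone(hres, np.zeros_like(S), Smax)
        Q = qofp(P)
        Qs = p.k_a * Q / (c1 * P + p.lam)
        Ct = b * P * Qs
        Cp = a * Q
        ok = feasible & ~no_sol
        return P, Q, Qs, Ct, Cp, ok

    def g(ps):
        ps_arr = np.atleast_1d(np.asarray(ps, dtype=float))
        P, Q, Qs, Ct, Cp, ok = solve_inner(ps_arr)
        drain = p.k_on_p * ps_arr * Q * (p.k_cat_p + p.lam) / a_den
        out = np.where(ok, p.k_cat_t * Ct - drain - p.lam * ps_arr,
                       -p.lam * ps_arr - 1e-30)
        return out[0] if np.isscalar(ps) or np.ndim(ps) == 0 else out

    def reconstruct(ps):
        P, Q, Qs, Ct, Cp, ok = solve_inner(ps)
        return np.array([P[0], float(np.atleast_1d(ps)[0]), Q[0], Qs[0], Ct[0], Cp[0]])

    return g, reconstruct


def scalar_residual(model: str, params: Params):
    """Return ``(g, reconstruct)`` for the 1-D balance equation of ``model``.

    ``g(Pstar)`` is vectorized; its sign changes locate steady states.
    ``reconstruct(Pstar)`` rebuilds the full state vector at a root.
    """
    if model == "reduced":
        return _reduced_residual(params)
    if model == "detailed":
        if not isinstance(params, DetailedParams):
            raise TypeError("detailed model requires DetailedParams")
        return _detailed_residual(params)
    if model == "decoupled":
        if not isinstance(params, DecoupledParams):
            raise TypeError("decoupled model requires DecoupledParams")
        if params.has_sequestration:
            return _decoupled_seq_residual(params)
        return _decoupled_reduced_residual(params)
    raise ValueError(f"unknown model {model!r}")


def pstar_upper_bound(params: Params) -> float:
    """Production cap (V_0 + V_f)/lam, with 5% headroom."""
    return 1.05 * (params.V_0 + params.V_f) / params.lam


# ---------------------------------------------------------------------------
# steady-state sets
# ---------------------------------------------------------------------------

@dataclass
class SteadyStateSet:
    """Steady states of one model/parameter combination.

    ``states`` is ordered by increasing ``Pstar``; ``stabilities`` holds
    ``"stable"``/``"unstable"``/``"marginal"`` labels; ``regime`` is filled
    by :func:`classify_regime`.
    """

    model: str
    states: list = field(default_factory=list)       # full state vectors
    stabilities: list = field(default_factory=list)  # parallel labels
    regime: str | None = None

    @property
    def pstars(self) -> np.ndarray:
        i = pstar_index(self.model)
        return np.array([s[i] for s in self.states])

    @property
    def stable_pstars(self) -> np.ndarray:
        i = pstar_index(self.model)
        return np.array([s[i] for s, lab in zip(self.states, self.stabilities)
                         if lab == "stable"])

    @property
    def n_stable(self) -> int:
        return sum(lab == "stable" for lab in self.stabilities)

    def __len__(self):
        return len(self.states)


def find_steady_states(model: str, params: Params, window=None, *,
                       n_grid: int = 4000, tol: float = 1e-9) -> SteadyStateSet:
    """Locate all steady states of ``model`` within ``window``.

    ``window`` defaults to ``[0, 1.05 (V_0 + V_f)/lam]``, which contains
    every steady state because production is bounded.  Sign changes of the
    scalar balance residual on a log-spaced grid are polished by Brent's
    method; every root is verified against the full right-hand side.
    """
    g, reconstruct = scalar_residual(model, params)
    lo, hi = window if window is not None else (0.0, pstar_upper_bound(params))
    if hi <= lo:
        raise ValueError("empty search window")
    grid = np.concatenate([[max(lo, 0.0)],
                           np.logspace(np.log10(max(lo, 1e-13)), np.log10(hi), n_grid)])
    vals = np.asarray(g(grid))

    roots = []
    if abs(vals[0]) == 0.0 and grid[0] == 0.0:
        roots.append(0.0)
    sgn = np.sign(vals)
    for i in np.nonzero(np.diff(sgn) != 0)[0]:
        if vals[i] == 0.0:
            roots.append(grid[i])
            continue
        try:
            roots.append(brentq(lambda x: float(g(x)), grid[i], grid[i + 1],
                                xtol=1e-300, rtol=8.9e-16, maxiter=200))
        except ValueError as exc:  # pragma: no cover
            raise RuntimeError(
                f"root polishing failed in [{grid[i]:g}, {grid[i+1]:g}]") from exc

    # dedupe near-identical roots
    roots = sorted(roots)
    dedup: list[float] = []
    for r in roots:
        if not dedup or abs(r - dedup[-1]) > 1e-8 * max(1.0, abs(r)):
            dedup.append(r)

    rhs = rhs_for(model, params)
    sset = SteadyStateSet(model=model)
    scale = max(params.V_0 + params.V_f, params.lam)
    for r in dedup:
        state = reconstruct(r)
        resid = np.max(np.abs(rhs(state)))
        if resid > max(tol, 1e-7 * scale):
            raise RuntimeError(
                f"steady-state candidate Pstar={r:g} fails residual check "
                f"(|rhs|={resid:g}); solver diagnostics: window=({lo:g},{hi:g})")
        sset.states.append(state)
        sset.stabilities.append(jacobian_stability(model, params, state))
    return sset


def jacobian_stability(model: str, params: Params, state, *,
                       steady_tol: float = 1e-6) -> str:
    """Linear stability of a steady state: sign of the leading eigenvalue.

    Raises if ``state`` is not a steady state; eigenvalue real parts within
    ``±1e-9`` of zero are flagged ``"marginal"``.
    """
    rhs = rhs_for(model, params)
    state = np.asarray(state, dtype=float)
    scale = max(params.V_0 + params.V_f, params.lam)
    if np.max(np.abs(rhs(state))) > max(steady_tol, 1e-6 * scale):
        raise ValueError("jacobian_stability called on a non-steady state")
    n = state.size
    J = np.empty((n, n))
    for j in range(n):
        h = 1e-7 * max(abs(state[j]), 1e-6)
        up = state.copy()
        dn = state.copy()
        up[j] += h
        dn[j] = max(dn[j] - h, 0.0)
        J[:, j] = (rhs(up) - rhs(dn)) / (up[j] - dn[j])
    lead = np.max(np.real(np.linalg.eigvals(J)))
    if abs(lead) < STABILITY_TIE_TOL:
        return "marginal"
    return "stable" if lead < 0 else "unstable"


def classify_regime(sset: SteadyStateSet, reference_scale: float) -> str:
    """Label a steady-state set as monostable_off / bistable / monostable_on.

    Two stable states mean bistable; a single stable state is OFF or ON
    according to whether its ``Pstar`` lies below or above
    ``reference_scale``.  Marginal states are excluded.
    """
    if len(sset) == 0:
        raise ValueError("empty steady-state set")
    stable = sset.stable_pstars
    if stable.size > 2:
        raise ValueError(f"{stable.size} stable states: model violation")
    if stable.size == 2:
        return "bistable"
    if stable.size == 0:
        raise ValueError("no stable states (all marginal or unstable)")
    return "monostable_off" if stable[0] < reference_scale else "monostable_on"


# ---------------------------------------------------------------------------
# sweeps and scans
# ---------------------------------------------------------------------------

def _with_param(params: Params, name: str, value: float) -> Params:
    if not hasattr(params, name):
        raise ValueError(f"unknown sweep parameter {name!r}")
    return replace(params, **{name: value})


@dataclass
class BranchTable:
    """1-D bifurcation sweep: steady-state branches along one parameter."""

    model: str
    param: str
    grid: np.ndarray
    sets: list          # SteadyStateSet per grid point
    regimes: list       # regime label per grid point
    folds: list         # parameter values where the stable-branch count changes
    reference_scale: float = np.nan

    def to_dataframe(self):
        import pandas as pd
        rows = []
        for x, ss, reg in zip(self.grid, self.sets, self.regimes):
            rows.append({
                "param": self.param, "value": x, "n_roots": len(ss),
                "n_stable": ss.n_stable, "regime": reg,
                "pstars": ";".join(f"{v:.8g}" for v in ss.pstars),
                "stabilities": ";".join(ss.stabilities),
            })
        return pd.DataFrame(rows)

    @property
    def regime_sequence(self) -> list:
        seq = []
        for r in self.regimes:
            if not seq or seq[-1] != r:
                seq.append(r)
        return seq


def _reference_scale_for(sets: Sequence[SteadyStateSet], K_f: float) -> float:
    """Geometric mean of OFF/ON branches at a bistable point, else K_f."""
    for ss in sets:
        if ss.n_stable == 2:
            lo, hi = np.sort(ss.stable_pstars)
            if lo > 0:
                return float(np.sqrt(lo * hi))
    return K_f


def bifurcation_sweep(model: str, params: Params, param_name: str,
                      grid, *, fold_rtol: float = 1e-6) -> BranchTable:
    """Sweep one parameter, collecting branches, regimes and fold points.

    Fold (saddle-node) points are localized by bisection on the swept
    parameter between grid cells where the root count changes.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or not (np.all(np.diff(grid) > 0) or np.all(np.diff(grid) < 0)):
        raise ValueError("sweep grid must be strictly monotone")
    sets = []
    for x in grid:
        try:
            sets.append(find_steady_states(model, _with_param(params, param_name, x)))
        except RuntimeError as exc:
            raise RuntimeError(f"sweep failed at {param_name}={x:g}: {exc}") from exc

    ref = _reference_scale_for(sets, params.K_f)
    regimes = [classify_regime(ss, ref) for ss in sets]

    folds = []
    counts = [len(ss) for ss in sets]
    for i in range(len(grid) - 1):
        if counts[i] != counts[i + 1]:
            a, b = grid[i], grid[i + 1]
            na = counts[i]
            while abs(b - a) > fold_rtol * max(abs(a), abs(b)):
                mid = 0.5 * (a + b)
                nm = len(find_steady_states(model, _with_param(params, param_name, mid)))
                if nm == na:
                    a = mid
                else:
                    b = mid
            folds.append(0.5 * (a + b))
    return BranchTable(model=model, param=param_name, grid=grid, sets=sets,
                       regimes=regimes, folds=folds, reference_scale=ref)


@dataclass
class RegimeMap:
    """2-D bistability scan over two parameters."""

    model: str
    x_param: str
    y_param: str
    x_grid: np.ndarray
    y_grid: np.ndarray
    regimes: np.ndarray       # (ny, nx) object array of labels
    display: np.ndarray       # (ny, nx) clamped steady value; NaN where bistable
    n_roots: np.ndarray

    def to_dataframe(self):
        import pandas as pd
        rows = []
        for iy, y in enumerate(self.y_grid):
            for ix, x in enumerate(self.x_grid):
                rows.append({self.x_param: x, self.y_param: y,
                             "n_roots": int(self.n_roots[iy, ix]),
                             "regime": self.regimes[iy, ix],
                             "display": self.display[iy, ix]})
        return pd.DataFrame(rows)

    @property
    def n_bistable(self) -> int:
        return int(np.sum(self.regimes == "bistable"))


def bistability_scan(model: str, params: Params, x_param: str, x_grid,
                     y_param: str, y_grid) -> RegimeMap:
    """Classify the regime on a 2-D parameter grid.

    Monostable cells carry their steady ``Pstar`` clamped at the display
    floor (1e-4); bistable cells carry NaN (plotted black in the source
    figures this mirrors).
    """
    x_grid = np.asarray(x_grid, dtype=float)
    y_grid = np.asarray(y_grid, dtype=float)
    for g in (x_grid, y_grid):
        if not np.all(np.diff(g) > 0):
            raise ValueError("scan grids must be strictly increasing")
    regimes = np.empty((y_grid.size, x_grid.size), dtype=object)
    display = np.full((y_grid.size, x_grid.size), np.nan)
    n_roots = np.zeros((y_grid.size, x_grid.size), dtype=int)
    for iy, y in enumerate(y_grid):
        py = _with_param(params, y_param, y)
        for ix, x in enumerate(x_grid):
            ss = find_steady_states(model, _with_param(py, x_param, x))
            n_roots[iy, ix] = len(ss)
            reg = classify_regime(ss, params.K_f)
            regimes[iy, ix] = reg
            if reg != "bistable":
                display[iy, ix] = clamp_for_display(float(ss.stable_pstars[0]))
    return RegimeMap(model=model, x_param=x_param, y_param=y_param,
                     x_grid=x_grid, y_grid=y_grid, regimes=regimes,
                     display=display, n_roots=n_roots)
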