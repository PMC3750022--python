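"""Deterministic rate equations for the circuit variants.

State conventions (concentrations, all nonnegative):

* reduced:    ``(P, Q, Pstar)``
* detailed:   ``(P, Pstar, Q, Qstar, C_t, C_p)``
* decoupled:  ``(P, Pstar)`` with ``Q = Q_tot`` fixed, or
              ``(P, Pstar, Qstar, C_p)`` with the PhoQ family clamped so
              that ``Q + Qstar + C_p = Q_tot``.

Every species is diluted at the growth rate ``lam``; PhoP and PhoQ are
co-produced from the single autoregulated operon at rate
``promoter_activity(Pstar)``.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .params import DecoupledParams, DetailedParams, Params, ReducedParams

__all__ = ["reduced_rhs", "detailed_rhs", "decoupled_rhs", "rhs_for", "integrate"]


def reduced_rhs(state, params: ReducedParams) -> np.ndarray:
    """Time derivatives of ``(P, Q, Pstar)`` for the three-species model.

    Kinase flux ``k_k P Q`` and phosphatase flux ``k_p Pstar Q`` each depend
    on the product of two concentrations; dilution ``-lam X`` acts on every
    species.  The phospho-fluxes cancel in ``d(P + Pstar)/dt``.
    """
    P, Q, Ps = state
    f = params.promoter(Ps)
    kin = params.k_k * P * Q
    pho = params.k_p * Ps * Q
    return np.array([
        f - kin + pho - params.lam * P,
        f - params.lam * Q,
        kin - pho - params.lam * Ps,
    ])


def detailed_rhs(state, params: DetailedParams) -> np.ndarray:
    """Time derivatives of ``(P, Pstar, Q, Qstar, C_t, C_p)``.

    Reaction scheme::

        operon:       0 -> P + Q        at promoter_activity(Pstar)
        autophos:     Q -> Qstar        (k_a)
        transfer:     P + Qstar <-> C_t (k_on_t / k_off_t); C_t -> Pstar + Q (k_cat_t)
        phosphatase:  Pstar + Q <-> C_p (k_on_p / k_off_p); C_p -> P + Q (k_cat_p)
        dilution:     -lam on every species, complexes included
    """
    P, Ps, Q, Qs, Ct, Cp = state
    p = params
    f = p.promoter(Ps)
    bind_t = p.k_on_t * P * Qs
    bind_p = p.k_on_p * Ps * Q
    return np.array([
        f - bind_t + p.k_off_t * Ct + p.k_cat_p * Cp - p.lam * P,
        p.k_cat_t * Ct - bind_p + p.k_off_p * Cp - p.lam * Ps,
        f - p.k_a * Q + p.k_cat_t * Ct - bind_p + (p.k_off_p + p.k_cat_p) * Cp - p.lam * Q,
        p.k_a * Q - bind_t + p.k_off_t * Ct - p.lam * Qs,
        bind_t - (p.k_off_t + p.k_cat_t + p.lam) * Ct,
        bind_p - (p.k_off_p + p.k_cat_p + p.lam) * Cp,
    ])


def decoupled_rhs(state, params: DecoupledParams) -> np.ndarray:
    """Derivatives for the constitutive-kinase variant.

    Two-species form ``(P, Pstar)``: kinase flux ``k_k P Q_tot`` (and
    phosphatase flux ``k_p Pstar Q_tot`` if the phosphatase is active).

    Five-species form ``(P, Pstar, Qstar, C_p)`` (sequestration cycle):
    free ``Q = Q_tot - Qstar - C_p``; phosphotransfer is a single step
    ``P + Qstar -> Pstar + Q`` at ``k_t``; the phosphatase complex is a
    dead end for catalysis but its PhoQ moiety still autophosphorylates,
    releasing ``Pstar + Qstar`` at ``k_a``.
    """
    if params.Q_tot < 0:
        raise ValueError("Q_tot must be nonnegative")
    p = params
    state = np.asarray(state, dtype=float)
    if state.shape[-1] == 2:
        P, Ps = state
        f = p.promoter(Ps)
        kin = p.k_k * P * p.Q_tot
        pho = p.k_p * Ps * p.Q_tot
        return np.array([f - kin + pho - p.lam * P, kin - pho - p.lam * Ps])
    P, Ps, Qs, Cp = state
    Q = max(p.Q_tot - Qs - Cp, 0.0)
    f = p.promoter(Ps)
    kin = p.k_t * P * Qs
    bind = p.k_on_p * Ps * Q
    return np.array([
        f - kin - p.lam * P,
        kin + (p.k_off_p + p.k_a) * Cp - bind - p.lam * Ps,
        p.k_a * Q + p.k_a * Cp - kin - p.lam * Qs,
        bind - (p.k_off_p + p.k_a + p.lam) * Cp,
    ])


def rhs_for(model: str, params: Params):
    """Return ``f(state) -> derivatives`` for a model name.

    ``model`` is one of ``reduced``, ``detailed``, ``decoupled``.  For the
    decoupled model the state dimension follows
    ``params.has_sequestration`` (2 without binding, 4 with).
    """
    if model == "reduced":
        return lambda y: reduced_rhs(y, params)
    if model == "detailed":
        if not isinstance(params, DetailedParams):
            raise TypeError("detailed model requires DetailedParams")
        return lambda y: detailed_rhs(y, params)
    if model == "decoupled":
        if not isinstance(params, DecoupledParams):
            raise TypeError("decoupled model requires DecoupledParams")
        return lambda y: decoupled_rhs(y, params)
    raise ValueError(f"unknown model {model!r}")


def state_dim(model: str, params: Params) -> int:
    if model == "reduced":
        return 3
    if model == "detailed":
        return 6
    if model == "decoupled":
        return 4 if params.has_sequestration else 2
    raise ValueError(f"unknown model {model!r}")


def pstar_index(model: str) -> int:
    """Index of the PhoP-P component in the state vector of ``model``."""
    return {"reduced": 2, "detailed": 1, "decoupled": 1}[model]


def integrate(model: str, params: Params, y0, t_final: float, *,
              rtol: float = 1e-8, atol: float = 1e-12, dense: bool = False):
    """Integrate a model to ``t_final`` with a stiff solver.

    Returns the ``solve_ivp`` result (``.y[:, -1]`` is the final state).
    """
    f = rhs_for(model, params)
    sol = solve_ivp(lambda t, y: f(np.maximum(y, 0.0)), (0.0, t_final),
                    np.asarray(y0, dtype=float), method="LSODA",
                    rtol=rtol, atol=atol, dense_output=dense)
    if not sol.success:  # pragma: no cover - solver failure is exceptional
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol
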