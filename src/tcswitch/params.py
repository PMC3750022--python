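"""Parameter sets for the two-component switch models and their variant transforms.

The circuit is a bifunctional sensor-kinase / response-regulator pair
(PhoQ/PhoP-type) whose operon is transcriptionally activated by the
phosphorylated regulator (PhoP-P, written ``Pstar``).  Three model levels are
parameterised here:

* :class:`ReducedParams` -- three species (PhoP, PhoQ, PhoP-P) with lumped
  bilinear kinase and phosphatase fluxes.
* :class:`DetailedParams` -- six species, adding PhoQ-P and the two
  intermediate complexes (phosphotransfer complex ``C_t`` and phosphatase
  complex ``C_p``) with explicit binding/unbinding/catalysis rates.
* :class:`DecoupledParams` -- the regulator side stays autoregulated while
  the kinase is expressed constitutively at total concentration ``Q_tot``
  (the engineered strain whose induction response probes the role of
  kinase autoregulation).

All parameters are dimensionless; concentrations are measured in units of
the feedback half-saturation scale and time in units where the default
growth rate is ``lam = 0.02``.  Growth-mediated dilution is the only loss
term for these stable proteins.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields, replace
from typing import Union

import numpy as np

__all__ = [
    "VariantTag",
    "ReducedParams",
    "DetailedParams",
    "DecoupledParams",
    "Params",
    "promoter_activity",
    "make_variant",
    "rescale_time",
]


class VariantTag(str, enum.Enum):
    """Closed set of circuit variants.

    ``wild_type``   intact kinase and phosphatase.
    ``T281R``       phosphatase-dead, kinase-impaired point mutant.
    ``T281R_dP2``   the mutant with the constitutive operon promoter deleted
                    (basal transcription reduced, not abolished).
    ``decoupled``   mutant kinase expressed from a feedback-insensitive
                    promoter; only the regulator side stays autoregulated.
    """

    wild_type = "wild_type"
    T281R = "T281R"
    T281R_dP2 = "T281R_dP2"
    decoupled = "decoupled"


def promoter_activity(Pstar, V_0, V_f, K_f, h):
    """Operon production rate as a function of PhoP-P concentration.

    A saturating (Hill) activation on top of a constitutive floor::

        F(P*) = V_0 + V_f * P*^h / (K_f^h + P*^h)

    Bounded in ``[V_0, V_0 + V_f]`` and monotone nondecreasing in ``Pstar``.
    The default Hill coefficient used throughout the package is ``h = 1``:
    cooperativity is not required for bistability in this circuit, which
    instead relies on the bilinearity of the kinase/phosphatase fluxes and
    on feedback saturation.

    Accepts scalars or arrays for ``Pstar``.
    """
    Pstar = np.asarray(Pstar, dtype=float)
    if np.any(Pstar < 0):
        raise ValueError("Pstar must be nonnegative")
    for name, val in (("V_0", V_0), ("V_f", V_f), ("h", h)):
        if val < 0:
            raise ValueError(f"{name} must be nonnegative")
    if K_f <= 0:
        raise ValueError("K_f must be positive")
    x = Pstar**h
    out = V_0 + V_f * x / (K_f**h + x)
    return float(out) if out.ndim == 0 else out


def _check_nonneg(obj, names):
    for n in names:
        v = getattr(obj, n)
        if v is None:
            continue
        if v < 0:
            raise ValueError(f"{n} must be nonnegative (got {v})")


@dataclass(frozen=True)
class ReducedParams:
    """Rate constants of the three-species model.

    k_k   kinase rate constant, flux ``k_k * P * Q``  [1/(conc time)]
    k_p   phosphatase rate constant, flux ``k_p * Pstar * Q``
    V_0   constitutive production rate  [conc/time]
    V_f   maximal feedback production rate  [conc/time]
    K_f   feedback half-saturation concentration
    h     Hill coefficient of the feedback (>= 1)
    lam   growth/dilution rate  [1/time]
    """

    k_k: float = 1.0
    k_p: float = 50.0
    V_0: float = 5e-5
    V_f: float = 0.2
    K_f: float = 1.0
    h: float = 1.0
    lam: float = 0.02

    _rate_fields = ("k_k", "k_p", "V_0", "V_f", "lam")

    def __post_init__(self):
        _check_nonneg(self, ("k_k", "k_p", "V_0", "V_f", "K_f"))
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.h < 1:
            raise ValueError("h must be >= 1")

    def promoter(self, Pstar):
        return promoter_activity(Pstar, self.V_0, self.V_f, self.K_f, self.h)


@dataclass(frozen=True)
class DetailedParams(ReducedParams):
    """Six-species model: explicit autophosphorylation and complexes.

    Adds to :class:`ReducedParams`:

    k_a                      PhoQ autophosphorylation rate  [1/time]
    k_on_t, k_off_t, k_cat_t phosphotransfer complex ``P + Q* <-> C_t -> P* + Q``
    k_on_p, k_off_p, k_cat_p phosphatase complex ``P* + Q <-> C_p -> P + Q``

    ``K_d = k_off_p / k_on_p`` is the dissociation constant of the
    phosphatase complex.  In the fast-autophosphorylation, fast-binding
    limit with ``k_on_t * k_cat_t / (k_off_t + k_cat_t)`` matched to ``k_k``
    (and analogously for the phosphatase side) the model collapses onto the
    reduced one.
    """

    k_a: float = 50.0
    k_on_t: float = 2.0
    k_off_t: float = 1.0
    k_cat_t: float = 1.0
    k_on_p: float = 100.0
    k_off_p: float = 1.0
    k_cat_p: float = 1.0

    _rate_fields = ReducedParams._rate_fields + (
        "k_a", "k_on_t", "k_off_t", "k_cat_t", "k_on_p", "k_off_p", "k_cat_p")

    def __post_init__(self):
        super().__post_init__()
        _check_nonneg(self, ("k_a", "k_on_t", "k_off_t", "k_cat_t",
                             "k_on_p", "k_off_p", "k_cat_p"))

    @property
    def K_d(self) -> float:
        if self.k_on_p == 0:
            return np.inf
        return self.k_off_p / self.k_on_p


@dataclass(frozen=True)
class DecoupledParams(ReducedParams):
    """Autoregulated phoP side with constitutively expressed kinase.

    Q_tot   total PhoQ concentration held by constitutive expression
    k_cons  constitutive phoQ production scale (Q_tot = k_cons * induction / lam
            when the kinase is produced rather than clamped)

    The optional sequestration cycle (used to probe the role of the
    phosphatase-complex dissociation constant ``K_d = k_off_p / k_on_p``):

    k_t     direct phosphotransfer rate ``P + Q* -> P* + Q``
    k_a     autophosphorylation ``Q -> Q*`` and in-complex release
            ``C_p -> P* + Q*``
    k_on_p, k_off_p   binding/unbinding of the dead-end phosphatase complex

    With ``k_on_p = 0`` the model is the two-species reduced decoupled
    circuit with kinase flux ``k_k * P * Q_tot``.
    """

    Q_tot: float = 1.0
    k_cons: float = 1.0
    k_t: float = 0.5
    k_a: float = 0.1
    k_on_p: float = 0.0
    k_off_p: float = 0.0

    _rate_fields = ReducedParams._rate_fields + (
        "k_cons", "k_t", "k_a", "k_on_p", "k_off_p")

    def __post_init__(self):
        super().__post_init__()
        _check_nonneg(self, ("Q_tot", "k_cons", "k_t", "k_a", "k_on_p", "k_off_p"))

    @property
    def K_d(self) -> float:
        if self.k_on_p == 0:
            return np.inf
        return self.k_off_p / self.k_on_p

    @property
    def has_sequestration(self) -> bool:
        return self.k_on_p > 0


Params = Union[ReducedParams, DetailedParams, DecoupledParams]

#: default kinase deficit of the point mutant relative to wild type
DEFAULT_KAPPA = 0.1
#: default residual basal transcription after deleting the constitutive promoter
DEFAULT_DELTA = 0.1


def make_variant(base: Params, tag: VariantTag | str, *, kappa: float = DEFAULT_KAPPA,
                 delta: float = DEFAULT_DELTA, Q_tot: float | None = None) -> Params:
    """Apply a variant transformation to a base parameter set.

    ``T281R`` zeroes the phosphatase (rate constant and, for the detailed
    model, the catalytic step of the phosphatase complex) and scales the
    kinase rate by ``kappa < 1`` -- the mutant is a poorer kinase and has no
    detectable phosphatase activity.  ``T281R_dP2`` additionally scales the
    constitutive production ``V_0`` by ``delta`` (residual basal
    transcription, not zero).  ``decoupled`` removes feedback from kinase
    production only, returning :class:`DecoupledParams` with the phoP side
    inherited from ``base``.
    """
    tag = VariantTag(tag)
    if tag is VariantTag.wild_type:
        return base
    if tag is VariantTag.decoupled:
        kw = {f.name: getattr(base, f.name)
              for f in fields(ReducedParams) if hasattr(base, f.name)}
        kw["k_k"] = kappa * base.k_k
        kw["k_p"] = 0.0
        if Q_tot is not None:
            kw["Q_tot"] = Q_tot
        return DecoupledParams(**kw)

    # T281R family
    updates: dict = {"k_p": 0.0, "k_k": kappa * base.k_k}
    if isinstance(base, DetailedParams):
        updates["k_cat_p"] = 0.0
        updates["k_a"] = kappa * base.k_a
        updates["k_on_t"] = kappa * base.k_on_t
    if tag is VariantTag.T281R_dP2:
        updates["V_0"] = delta * base.V_0
    return replace(base, **updates)


def rescale_time(params: Params, c: float) -> Params:
    """Multiply every rate-dimension field by ``c``.

    A reduction in growth rate is equivalent to an upscaling of all kinetic
    parameters: the steady-state set of the rescaled system is identical,
    only time scales change.
    """
    if c <= 0:
        raise ValueError("time-rescaling factor must be positive")
    return replace(params, **{n: c * getattr(params, n) for n in params._rate_fields})
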