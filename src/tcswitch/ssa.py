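"""Exact stochastic simulation of the switching circuit.

Molecule counts are concentrations times the system size ``Omega``; the
promoter propensity is the Hill production rate evaluated on the PhoP-P
*count* with half-saturation ``K_f * Omega`` (the ``C_P1``/``C_P2``
analogues of ``V_f``/``V_0`` scale with ``Omega``).

Growth is handled by the simulation policy rather than by reactions:

* ``"generations"`` (default): exact SSA for one deterministic doubling
  time ``ln 2 / lam``, then every molecule count is partitioned binomially
  (p = 1/2) into the followed daughter cell.
* ``"dilution"``: a continuous first-order loss propensity ``lam * n`` per
  species; this is the policy whose ensemble mean follows the rate
  equations exactly and is used for deterministic-limit checks.
* ``"none"``: pure reaction chemistry over the same time horizon (no loss,
  no division) -- useful for checking the reaction core in isolation.

The per-generation time-averaged copy numbers are recorded; the endpoint
statistic of a run is the mean PhoP-P count over its final generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .params import DecoupledParams, DetailedParams, Params, ReducedParams, VariantTag

__all__ = [
    "ReactionNetwork", "SSAResult", "build_network", "gillespie_run",
    "run_ensemble", "deterministic_limit", "priming_fraction",
    "detect_switch", "bimodality_report",
]

# propensity kinds
K_CONST, K_UNARY, K_BINARY, K_PROMOTER = 0, 1, 2, 3


@dataclass
class ReactionNetwork:
    """Species, stoichiometry and propensity specification.

    ``kinds[r]`` selects the propensity form of reaction ``r``:
    constant (``rpar[r,0]``), unary (``rpar[r,0] * n[i]``), binary
    (``rpar[r,0] * n[i] * n[j]``, the rate already divided by ``Omega``),
    or promoter (``rpar[r,0] + rpar[r,1] * n[j]^h / (rpar[r,2]^h + n[j]^h)``
    with ``h = rpar[r,3]``).
    """

    species: list
    stoich: np.ndarray       # (nr, ns) int64
    kinds: np.ndarray        # (nr,) int64
    ridx: np.ndarray         # (nr, 2) int64 reactant indices
    rpar: np.ndarray         # (nr, 4) float64
    omega: float
    lam: float
    labels: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def pstar_index(self) -> int:
        return self.species.index("Pstar")

    def propensities(self, counts) -> np.ndarray:
        """Reference (non-jitted) propensity evaluation, for tests."""
        n = np.asarray(counts, dtype=float)
        a = np.zeros(len(self.kinds))
        for r, k in enumerate(self.kinds):
            if k == K_CONST:
                a[r] = self.rpar[r, 0]
            elif k == K_UNARY:
                a[r] = self.rpar[r, 0] * n[self.ridx[r, 0]]
            elif k == K_BINARY:
                a[r] = self.rpar[r, 0] * n[self.ridx[r, 0]] * n[self.ridx[r, 1]]
            else:
                x = n[self.ridx[r, 0]] ** self.rpar[r, 3]
                a[r] = self.rpar[r, 0] + self.rpar[r, 1] * x / (self.rpar[r, 2] ** self.rpar[r, 3] + x)
        if np.any(a < 0):
            raise ValueError("negative propensity")
        return a


def _net(species, rows, omega, lam, meta):
    labels = [r[0] for r in rows]
    stoich = np.array([r[1] for r in rows], dtype=np.int64)
    kinds = np.array([r[2] for r in rows], dtype=np.int64)
    ridx = np.array([r[3] for r in rows], dtype=np.int64)
    rpar = np.array([r[4] for r in rows], dtype=np.float64)
    return ReactionNetwork(species=list(species), stoich=stoich, kinds=kinds,
                           ridx=ridx, rpar=rpar, omega=float(omega), lam=lam,
                           labels=labels, meta=meta)


def build_network(variant: VariantTag | str, params: Params, omega: float,
                  scheme: str = "reduced") -> ReactionNetwork:
    """Build the stochastic reaction network for a circuit variant.

    ``variant`` selects the wiring: autoregulated operon
    (``wild_type``/``T281R``/``T281R_dP2``) or constitutive kinase
    expression (``decoupled``).  ``params`` should already carry the
    variant's rate values (see :func:`tcswitch.params.make_variant`);
    reactions with zero rate (e.g. the phosphatase catalysis of the
    mutant) are omitted from the reaction list.
    """
    variant = VariantTag(variant)
    if omega < 1:
        raise ValueError("omega must be >= 1")
    p = params
    meta = {"variant": variant.value, "scheme": scheme, "lam": p.lam}
    C_P2, C_P1, Kc = omega * p.V_0, omega * p.V_f, omega * p.K_f

    if scheme == "reduced":
        species = ["P", "Q", "Pstar"]
        rows = []
        if variant is VariantTag.decoupled:
            if not isinstance(p, DecoupledParams):
                raise TypeError("decoupled network requires DecoupledParams")
            rows.append(("phoP_production", (1, 0, 0), K_PROMOTER, (2, 0),
                         (C_P2, C_P1, Kc, p.h)))
            rows.append(("phoQ_production", (0, 1, 0), K_CONST,
                         (0, 0), (omega * p.lam * p.k_cons * p.Q_tot, 0, 0, 0)))
        else:
            rows.append(("operon_production", (1, 1, 0), K_PROMOTER, (2, 0),
                         (C_P2, C_P1, Kc, p.h)))
        rows.append(("kinase", (-1, 0, 1), K_BINARY, (0, 1), (p.k_k / omega, 0, 0, 0)))
        if p.k_p > 0:
            rows.append(("phosphatase", (1, 0, -1), K_BINARY, (2, 1),
                         (p.k_p / omega, 0, 0, 0)))
        return _net(species, rows, omega, p.lam, meta)

    if scheme == "detailed":
        if not isinstance(p, DetailedParams):
            raise TypeError("detailed scheme requires DetailedParams")
        if variant is VariantTag.decoupled:
            raise ValueError("decoupled networks use the reduced scheme")
        species = ["P", "Pstar", "Q", "Qstar", "C_t", "C_p"]
        rows = [
            ("operon_production", (1, 0, 1, 0, 0, 0), K_PROMOTER, (1, 0),
             (C_P2, C_P1, Kc, p.h)),
            ("autophosphorylation", (0, 0, -1, 1, 0, 0), K_UNARY, (2, 0),
             (p.k_a, 0, 0, 0)),
            ("transfer_bind", (-1, 0, 0, -1, 1, 0), K_BINARY, (0, 3),
             (p.k_on_t / omega, 0, 0, 0)),
            ("transfer_unbind", (1, 0, 0, 1, -1, 0), K_UNARY, (4, 0),
             (p.k_off_t, 0, 0, 0)),
            ("transfer_cat", (0, 1, 1, 0, -1, 0), K_UNARY, (4, 0),
             (p.k_cat_t, 0, 0, 0)),
        ]
        if p.k_on_p > 0:
            rows.append(("phosphatase_bind", (0, -1, -1, 0, 0, 1), K_BINARY,
                         (1, 2), (p.k_on_p / omega, 0, 0, 0)))
            rows.append(("phosphatase_unbind", (0, 1, 1, 0, 0, -1), K_UNARY,
                         (5, 0), (p.k_off_p, 0, 0, 0)))
        if p.k_cat_p > 0:
            rows.append(("phosphatase_cat", (1, 0, 1, 0, 0, -1), K_UNARY,
                         (5, 0), (p.k_cat_p, 0, 0, 0)))
        return _net(species, rows, omega, p.lam, meta)

    raise ValueError(f"unknown scheme {scheme!r}")


@njit(cache=True)
def _ssa_kernel(stoich, kinds, ridx, rpar, n0, n_gen, t_gen, lam, policy, seed):
    np.random.seed(seed)
    ns = n0.size
    nr = kinds.size
    n = n0.astype(np.float64)
    gen_means = np.zeros((n_gen, ns))
    a = np.zeros(nr)
    for g in range(n_gen):
        t = 0.0
        acc = np.zeros(ns)
        while True:
            A = 0.0
            for r in range(nr):
                k = kinds[r]
                if k == 0:
                    ar = rpar[r, 0]
                elif k == 1:
                    ar = rpar[r, 0] * n[ridx[r, 0]]
                elif k == 2:
                    ar = rpar[r, 0] * n[ridx[r, 0]] * n[ridx[r, 1]]
                else:
                    x = n[ridx[r, 0]] ** rpar[r, 3]
                    ar = rpar[r, 0] + rpar[r, 1] * x / (rpar[r, 2] ** rpar[r, 3] + x)
                if ar < 0.0:
                    raise ValueError("negative propensity (stoichiometry bug?)")
                a[r] = ar
                A += ar
            dil = 0.0
            if policy == 1:
                for i in range(ns):
                    dil += n[i]
                dil *= lam
                A += dil
            if A <= 0.0:
                for i in range(ns):
                    acc[i] += n[i] * (t_gen - t)
                break
            dt = -np.log(np.random.random()) / A
            if t + dt >= t_gen:
                for i in range(ns):
                    acc[i] += n[i] * (t_gen - t)
                break
            t += dt
            for i in range(ns):
                acc[i] += n[i] * dt
            u = np.random.random() * A
            if policy == 1 and u < dil:
                # remove one molecule, species chosen proportional to count
                v = u / lam
                csum = 0.0
                for i in range(ns):
                    csum += n[i]
                    if v < csum:
                        n[i] -= 1.0
                        break
            else:
                if policy == 1:
                    u -= dil
                picked = nr - 1
                csum = 0.0
                for r in range(nr):
                    csum += a[r]
                    if u < csum:
                        picked = r
                        break
                for i in range(ns):
                    n[i] += stoich[picked, i]
                    if n[i] < 0.0:
                        raise ValueError("negative count (stoichiometry bug?)")
        for i in range(ns):
            gen_means[g, i] = acc[i] / t_gen
        if policy == 0:
            for i in range(ns):
                n[i] = float(np.random.binomial(np.int64(n[i]), 0.5))
    return n, gen_means


@dataclass
class SSAResult:
    """One stochastic run: final counts and per-generation mean copy numbers."""

    species: list
    final_counts: np.ndarray
    gen_means: np.ndarray      # (n_generations, n_species) time-averaged counts
    seed: int
    n_generations: int
    omega: float
    policy: str

    @property
    def endpoint(self) -> float:
        """Mean PhoP-P count over the final generation."""
        return float(self.gen_means[-1, self.species.index("Pstar")])

    def pstar_trajectory(self) -> np.ndarray:
        return self.gen_means[:, self.species.index("Pstar")]


def gillespie_run(network: ReactionNetwork, init_counts, n_generations: int,
                  seed: int, division_policy: str = "generations") -> SSAResult:
    """Exact SSA for ``n_generations`` doubling times.

    ``init_counts`` are molecule counts (nonnegative integers).  The run is
    reproducible given ``(network, init, seed, policy)``.
    """
    init = np.asarray(init_counts, dtype=np.int64)
    if np.any(init < 0):
        raise ValueError("initial counts must be nonnegative")
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    # "none": pure chemistry over the same horizon (no dilution, no division)
    policy = {"generations": 0, "dilution": 1, "none": 2}[division_policy]
    t_gen = np.log(2.0) / network.lam
    if n_generations == 0:
        return SSAResult(network.species, init.astype(float),
                         np.zeros((0, len(network.species))), seed, 0,
                         network.omega, division_policy)
    fin, means = _ssa_kernel(network.stoich, network.kinds, network.ridx,
                             network.rpar, init, n_generations, t_gen,
                             network.lam, policy, seed % 2**31)
    return SSAResult(network.species, fin, means, seed, n_generations,
                     network.omega, division_policy)


def run_ensemble(network: ReactionNetwork, init_counts, n_runs: int,
                 base_seed: int, n_generations: int = 35,
                 division_policy: str = "generations") -> pd.DataFrame:
    """Independent runs with seeds derived from ``base_seed``.

    Returns one row per run: seed, final counts, and the endpoint statistic
    (mean PhoP-P count over the last generation).  Deterministic given
    ``base_seed``.
    """
    if n_runs < 0:
        raise ValueError("n_runs must be >= 0")
    rows = []
    for k in range(n_runs):
        seed = (base_seed * 1000003 + k * 7919 + 1) % 2**31
        res = gillespie_run(network, init_counts, n_generations, seed,
                            division_policy)
        row = {"run": k, "seed": seed, "generations": n_generations,
               "endpoint": res.endpoint}
        for s, v in zip(network.species, res.final_counts):
            row[f"final_{s}"] = v
        rows.append(row)
    cols = (["run", "seed", "generations", "endpoint"]
            + [f"final_{s}" for s in network.species])
    return pd.DataFrame(rows, columns=cols)


def deterministic_limit(network: ReactionNetwork):
    """Rate equations of the network in the large-``Omega`` limit.

    Returns ``f(conc_state) -> d(conc)/dt`` including the first-order
    dilution term ``-lam x``; the steady states of this system are the
    large-``Omega`` limit of the SSA.
    """
    om = network.omega

    def rhs(x):
        x = np.asarray(x, dtype=float)
        a = network.propensities(om * x) / om
        return network.stoich.T @ a - network.lam * x

    return rhs


def priming_fraction(endpoints, threshold: float) -> float:
    """Percentage of runs whose final-generation mean PhoP-P exceeds ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(endpoints, pd.DataFrame):
        endpoints = endpoints["endpoint"].to_numpy()
    endpoints = np.asarray(endpoints, dtype=float)
    if endpoints.size == 0:
        raise ValueError("empty endpoint table")
    return 100.0 * float(np.mean(endpoints > threshold))


def detect_switch(trajectory, off_threshold: float, on_threshold: float):
    """Full-band state switches along a per-generation trajectory.

    A switch is recorded only when the trajectory crosses the entire
    hysteresis band ``[off_threshold, on_threshold]``; excursions that stay
    inside the band produce no events.  Returns a list of
    ``(direction, generation)`` with direction ``"ON->OFF"`` or ``"OFF->ON"``.
    """
    if not off_threshold < on_threshold:
        raise ValueError("off_threshold must be below on_threshold")
    traj = np.asarray(trajectory, dtype=float)
    events = []
    state = None
    for g, v in enumerate(traj):
        if v >= on_threshold:
            if state == "OFF":
                events.append(("OFF->ON", g))
            state = "ON"
        elif v <= off_threshold:
            if state == "ON":
                events.append(("ON->OFF", g))
            state = "OFF"
    return events


def bimodality_report(endpoints, off_ref: float, on_ref: float,
                      log_tol: float | None = None) -> dict:
    """Partition endpoints into near-OFF / near-ON / intermediate fractions.

    ``off_ref``/``on_ref`` are reference copy numbers (deterministic-limit
    steady states).  "Near" means within ``log_tol`` decades of the
    reference; the default tolerance is a third of the OFF-ON separation.
    A set is flagged bimodal when both modes hold at least 5% of the runs.
    """
    if isinstance(endpoints, pd.DataFrame):
        endpoints = endpoints["endpoint"].to_numpy()
    e = np.asarray(endpoints, dtype=float)
    if e.size == 0:
        raise ValueError("empty endpoint table")
    if not 0 <= off_ref < on_ref:
        raise ValueError("need 0 <= off_ref < on_ref")
    floor = 0.25
    lo = np.log10(max(off_ref, floor))
    hi = np.log10(max(on_ref, floor))
    if log_tol is None:
        log_tol = (hi - lo) / 3.0
    le = np.log10(np.maximum(e, floor))
    near_off = np.abs(le - lo) <= log_tol
    near_on = np.abs(le - hi) <= log_tol
    inter = ~(near_off | near_on)
    f_off = float(np.mean(near_off))
    f_on = float(np.mean(near_on & ~near_off))
    f_int = float(np.mean(inter))
    return {
        "fraction_off": f_off,
        "fraction_on": f_on,
        "fraction_intermediate": f_int,
        "is_bimodal": f_off >= 0.05 and f_on >= 0.05,
    }
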