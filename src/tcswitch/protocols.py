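"""In-silico culture protocols.

Three experiment emulations:

* :func:`priming_assay` -- drive a model through a schedule of growth
  phases (exponential maintenance, stationary passage, altered signaling)
  and classify the endpoint against OFF/ON references.  Mg2+ or other
  stimuli are represented purely as phase-level parameter multipliers
  (e.g. a kinase-rate factor); the model carries no explicit ligand.
* :func:`induction_hysteresis` -- the decoupled strain grown ~15
  generations from uninduced and fully induced starting populations across
  an induction grid; convergence of the two endpoint distributions is the
  signature of a monostable (hysteresis-free) circuit.
* :func:`lineage_simulation` -- the multi-day serial-dilution experiment:
  a binomial bottleneck of founders each day, per-generation stochastic
  state switching during regrowth, and differential stationary-phase
  survival of ON cells.  This is a two-state population process, not a
  per-cell chemical simulation: the day-scale experiment operates on
  ~1e9 cells where only state fractions matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import ssa as _ssa
from .models import integrate, pstar_index, state_dim
from .params import DecoupledParams, Params
from .steady import find_steady_states

__all__ = [
    "Phase", "PhaseSchedule", "LineageConfig",
    "priming_assay", "induction_hysteresis", "lineage_simulation",
]


@dataclass(frozen=True)
class Phase:
    """One culture phase: duration in generations, growth rate, overrides.

    ``overrides`` maps parameter names to multiplicative factors applied
    for the duration of the phase (a kinase-rate multiplier is the stand-in
    for a change in Mg2+).  ``dilution`` marks a serial-dilution event at
    the end of the phase (a bookkeeping flag; concentrations are intensive).
    """

    duration_gen: float
    lam: float
    overrides: dict = field(default_factory=dict)
    dilution: float | None = None

    def __post_init__(self):
        if self.duration_gen <= 0:
            raise ValueError("phase duration must be positive")
        if self.lam <= 0:
            raise ValueError("phase growth rate must be positive")


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered culture phases."""

    phases: tuple

    def __init__(self, phases):
        object.__setattr__(self, "phases", tuple(phases))
        if not self.phases:
            raise ValueError("schedule needs at least one phase")

    def __iter__(self):
        return iter(self.phases)


def _apply_phase(params: Params, phase: Phase) -> Params:
    p = replace(params, lam=phase.lam)
    for name, factor in phase.overrides.items():
        if not hasattr(p, name):
            raise ValueError(f"schedule references unknown parameter {name!r}")
        p = replace(p, **{name: factor * getattr(p, name)})
    return p


def _references(model: str, params: Params):
    """OFF/ON Pstar references and the geometric-mean threshold."""
    ss = find_steady_states(model, params)
    stable = np.sort(ss.stable_pstars)
    if stable.size == 2:
        off_ref, on_ref = float(stable[0]), float(stable[1])
        thr = float(np.sqrt(max(off_ref, 1e-300) * on_ref))
    else:
        off_ref = on_ref = float(stable[0])
        thr = params.K_f
    return ss, off_ref, on_ref, thr


def priming_assay(model: str, params: Params, schedule: PhaseSchedule,
                  start="off") -> dict:
    """Integrate the deterministic model through a culture schedule.

    ``start`` is ``"off"``, ``"on"`` or an explicit state vector; OFF/ON
    references are the stable states of the *baseline* parameters (the
    bistable condition the lineages are assayed in).  Returns the final
    state, its OFF/ON label, and the references used.
    """
    ss, off_ref, on_ref, thr = _references(model, params)
    idx = pstar_index(model)
    if isinstance(start, str):
        target = {"off": off_ref, "on": on_ref}[start]
        state = None
        for s in ss.states:
            if abs(s[idx] - target) <= 1e-9 * max(1.0, target):
                state = np.array(s, dtype=float)
        if state is None:  # pragma: no cover
            raise RuntimeError("reference state not found")
    else:
        state = np.asarray(start, dtype=float)
        if state.size != state_dim(model, params):
            raise ValueError("start state has wrong dimension")

    for phase in schedule:
        p = _apply_phase(params, phase)
        t_final = phase.duration_gen * np.log(2.0) / phase.lam
        state = integrate(model, p, state, t_final).y[:, -1]

    final_ps = float(state[idx])
    return {
        "final_state": state,
        "final_pstar": final_ps,
        "label": "ON" if final_ps > thr else "OFF",
        "off_ref": off_ref,
        "on_ref": on_ref,
        "threshold": thr,
    }


def induction_hysteresis(params: DecoupledParams, induction_grid,
                         n_generations: int = 15, *, n_runs: int = 60,
                         omega: float = 100.0, base_seed: int = 0) -> pd.DataFrame:
    """Endpoint summaries of the decoupled strain from both initial states.

    For every induction level (target total PhoQ) an SSA ensemble is run
    starting from the uninduced steady state and from the fully induced
    one.  Returns a tidy frame with per-(induction, start) median endpoint
    and its standard error (1.2533 * sd / sqrt(n), the large-sample SE of
    a median under approximate normality).
    """
    grid = np.asarray(induction_grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("induction grid must be strictly increasing")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")

    def start_counts(q):
        p = replace(params, Q_tot=float(q))
        ss = find_steady_states("decoupled", p)
        st = ss.states[int(np.argmax(ss.stable_pstars))] if ss.n_stable else ss.states[0]
        P, Ps = float(st[0]), float(st[1])
        return np.array([round(P * omega), round(q * omega), round(Ps * omega)],
                        dtype=np.int64)

    inits = {"uninduced": start_counts(grid[0]), "induced": start_counts(grid[-1])}

    rows = []
    for gi, q in enumerate(grid):
        p = replace(params, Q_tot=float(q))
        net = _ssa.build_network("decoupled", p, omega)
        for si, (start, init) in enumerate(inits.items()):
            ens = _ssa.run_ensemble(net, init, n_runs,
                                    base_seed + 1000 * gi + 500 * si,
                                    n_generations=n_generations)
            e = ens["endpoint"].to_numpy()
            rows.append({
                "induction": q, "start": start, "n": len(e),
                "median": float(np.median(e)), "mean": float(np.mean(e)),
                "sd": float(np.std(e, ddof=1)),
                "se_median": 1.2533 * float(np.std(e, ddof=1)) / np.sqrt(len(e)),
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LineageConfig:
    """Serial-dilution lineage experiment settings.

    Defaults mirror the long-term culture protocol: ~20 generations of
    regrowth after a million-fold dilution, >14 h of stationary phase per
    day, and a bottleneck of ~2000 transferred founder cells.
    ``s_on`` is the relative stationary-phase survival of ON cells per day;
    switching probabilities are per generation of exponential growth.
    """

    n_days: int = 5
    dilution: float = 1e6
    n_b: int = 2000
    generations_per_day: int = 20
    stationary_hours: float = 14.0
    p_on_to_off: float = 1e-4
    p_off_to_on: float = 0.0
    s_on: float = 0.5
    replicates: int = 7
    seed: int = 0
    start: str = "on"

    def __post_init__(self):
        for name in ("p_on_to_off", "p_off_to_on"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.s_on <= 1:
            raise ValueError("s_on must be in (0, 1]")
        if self.n_b < 1:
            raise ValueError("n_b must be >= 1")
        if self.start not in ("on", "off"):
            raise ValueError("start must be 'on' or 'off'")


def lineage_simulation(config: LineageConfig) -> pd.DataFrame:
    """Simulate replicate serial-dilution lineages.

    Each day: a binomial draw of ``n_b`` founders from the previous day's
    state fractions, doubling growth with per-generation binomial switching
    in both directions, then binomial stationary-phase survival (``s_on``
    on ON cells).  Fractions are recorded at the end of each day (the
    overnight culture that is plated).  Deterministic given ``seed``.

    Returns columns: replicate, day, off_fraction, on_fraction, population,
    extinct.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for rep in range(config.replicates):
        n_on = config.n_b if config.start == "on" else 0
        n_off = config.n_b - n_on
        extinct = False
        for day in range(1, config.n_days + 1):
            if day > 1:
                # bottleneck: founders drawn binomially from yesterday's fractions
                total = n_on + n_off
                f_on = n_on / total
                n_on = int(rng.binomial(config.n_b, f_on))
                n_off = config.n_b - n_on
            for _ in range(config.generations_per_day):
                n_on *= 2
                n_off *= 2
                to_off = int(rng.binomial(n_on, config.p_on_to_off)) if n_on else 0
                to_on = int(rng.binomial(n_off, config.p_off_to_on)) if n_off else 0
                n_on += to_on - to_off
                n_off += to_off - to_on
            n_on = int(rng.binomial(n_on, config.s_on)) if n_on else 0
            total = n_on + n_off
            if total == 0:
                extinct = True
                rows.append({"replicate": rep, "day": day, "off_fraction": np.nan,
                             "on_fraction": np.nan, "population": 0, "extinct": True})
                break
            rows.append({"replicate": rep, "day": day,
                         "off_fraction": n_off / total, "on_fraction": n_on / total,
                         "population": total, "extinct": False})
    return pd.DataFrame(rows)
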