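"""Synthetic data generators.

These stand in for the wet-lab measurements with the statistical structure
the quantification assumes: a two-state (OFF/ON) log-scale mixture of
reporter ratios with ~60-fold separation, a constitutive normalizer
channel, state-dependent cell widths, competition plate counts with known
ground-truth fitness, and piecewise-constant switching trajectories.
Every generator is deterministic given its seed and records the ground
truth it drew from, so downstream estimators can be checked for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .quantify import CompetitionCounts

__all__ = [
    "CellGenParams", "simulate_cells", "simulate_competition",
    "simulate_switch_trajectory",
]


@dataclass(frozen=True)
class CellGenParams:
    """Settings for the per-cell measurement generator.

    ``fold`` is the ON/OFF separation of the median YFP/CFP ratio (default
    60); ``cv`` the log-scale spread per channel (multiplicative microscopy
    noise).  ON cells are narrower than OFF cells (state-dependent width,
    in micrometres).  ``saturation`` optionally caps YFP, mimicking a
    reporter promoter near saturation in the ON state.
    """

    n: int = 1000
    fraction_on: float = 0.5
    off_ratio_median: float = 1.0
    fold: float = 60.0
    cv: float = 0.3
    cfp_median: float = 100.0
    width_off: float = 1.05
    width_on: float = 0.85
    width_sd: float = 0.08
    saturation: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if not 0 <= self.fraction_on <= 1:
            raise ValueError("fraction_on must be in [0, 1]")
        if self.fold <= 1:
            raise ValueError("fold separation must exceed 1")
        for name in ("off_ratio_median", "cv", "cfp_median",
                     "width_off", "width_on", "width_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def simulate_cells(params: CellGenParams) -> pd.DataFrame:
    """Draw a synthetic single-cell measurement table.

    YFP/CFP is lognormal per latent state with medians separated by
    ``fold``; CFP is lognormal and state-independent; width is normal
    truncated at zero with a state-dependent mean.  Columns: cell_id, yfp,
    cfp, width, label.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    on = rng.random(p.n) < p.fraction_on
    cfp = p.cfp_median * np.exp(p.cv * rng.standard_normal(p.n))
    ratio_median = np.where(on, p.off_ratio_median * p.fold, p.off_ratio_median)
    ratio = ratio_median * np.exp(p.cv * rng.standard_normal(p.n))
    yfp = cfp * ratio
    if p.saturation is not None:
        yfp = np.minimum(yfp, p.saturation)
    mean_w = np.where(on, p.width_on, p.width_off)
    width = truncnorm.rvs(-mean_w / p.width_sd, np.inf, loc=mean_w,
                          scale=p.width_sd, random_state=rng)
    return pd.DataFrame({
        "cell_id": np.arange(p.n),
        "yfp": yfp,
        "cfp": cfp,
        "width": width,
        "label": np.where(on, "ON", "OFF"),
    })


def simulate_competition(true_cr: float, base_counts=(200, 400), noise: float = 0.0,
                         seed: int = 0) -> CompetitionCounts:
    """Plate counts consistent with a requested competitive ratio.

    The initial culture is mixed ``C0/L0 = base_counts[0]/base_counts[1]``;
    the relative survival of the sensitive strain is chosen so the
    noise-free counts give exactly ``true_cr``.  With ``noise > 0`` each
    plated subpopulation is Poisson-resampled (``noise`` rescales the
    effective number of colonies counted; 1.0 is plain Poisson).
    """
    if true_cr <= 0:
        raise ValueError("true CR must be positive")
    C0, L0 = float(base_counts[0]), float(base_counts[1])
    if C0 <= 0 or L0 <= C0:
        raise ValueError("need 0 < C0 < L0")
    rho = C0 / L0
    sr = (1.0 / true_cr - rho) / (1.0 - rho)   # sensitive:resistant survival
    if sr < 0:
        raise ValueError(f"CR={true_cr} not reachable from C0/L0={rho}")
    res10 = C0            # resistant survival normalized to 1
    sen10 = sr * (L0 - C0)
    if noise == 0:
        return CompetitionCounts(C0=C0, L0=L0, C10=res10, L10=res10 + sen10)
    rng = np.random.default_rng(seed)

    def plate(mean):
        return noise * rng.poisson(mean / noise)

    c0 = plate(C0)
    s0 = plate(L0 - C0)
    c10 = plate(res10)
    s10 = plate(sen10) if sen10 > 0 else 0.0
    return CompetitionCounts(C0=c0, L0=c0 + s0, C10=c10, L10=c10 + s10)


def simulate_switch_trajectory(levels, change_points, noise: float = 0.0,
                               n_generations: int | None = None, seed: int = 0):
    """Piecewise-constant latent trajectory plus observation noise.

    ``levels`` are the latent values of successive segments and
    ``change_points`` the generations at which each new segment begins
    (len(levels) == len(change_points) + 1).  Returns ``(trajectory,
    events)`` where events is the ground-truth list of
    ``(direction, generation)`` transitions.
    """
    levels = list(levels)
    change_points = list(change_points)
    if len(levels) != len(change_points) + 1:
        raise ValueError("need one more level than change points")
    if sorted(change_points) != change_points:
        raise ValueError("change points must be increasing")
    if n_generations is None:
        n_generations = (change_points[-1] + 10) if change_points else 20
    rng = np.random.default_rng(seed)
    traj = np.empty(n_generations)
    bounds = [0] + change_points + [n_generations]
    events = []
    for i, lev in enumerate(levels):
        traj[bounds[i]:bounds[i + 1]] = lev
        if i > 0:
            direction = "ON->OFF" if lev < levels[i - 1] else "OFF->ON"
            events.append((direction, bounds[i]))
    if noise > 0:
        traj = traj + noise * rng.standard_normal(n_generations)
    return traj, events
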