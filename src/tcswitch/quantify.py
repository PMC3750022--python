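"""Measurement statistics: single-cell classification, competition assays,
and serial-dilution arithmetic.

Cells are measured through a PhoP-P-responsive YFP reporter normalized by a
constitutive CFP channel; the per-cell YFP/CFP ratio is the activity proxy.
Competition outcomes are quantified from colony counts on selective
(chloramphenicol) and plain plates at the start and end of a 10 h
stationary-phase co-culture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CompetitionCounts", "classify_cells", "estimate_ratio_threshold",
    "summarize_ratios", "competitive_ratio", "competitive_index",
    "inoculum_presence_probability", "generations_from_dilution",
]

_ROUND_TOL = 1e-6


@dataclass(frozen=True)
class CompetitionCounts:
    """Colony counts: C = selective plates (resistant), L = plain plates (total).

    Counts may be floats (plate counts back-scaled by dilution); the
    resistant subset cannot exceed the total at either time.
    """

    C0: float
    L0: float
    C10: float
    L10: float

    def __post_init__(self):
        for n in ("C0", "L0", "C10", "L10"):
            if getattr(self, n) < 0:
                raise ValueError(f"{n} must be nonnegative")
        if self.C0 > self.L0 * (1 + _ROUND_TOL):
            raise ValueError("C0 cannot exceed L0")
        if self.C10 > self.L10 * (1 + _ROUND_TOL):
            raise ValueError("C10 cannot exceed L10")


def competitive_ratio(counts: CompetitionCounts) -> float:
    """CR = (C(10) L(0)) / (C(0) L(10)).

    Neutral competition gives CR = 1.  In a 1:1 design the statistic is
    bounded: complete elimination of the sensitive strain gives CR = 2.
    """
    if counts.C0 <= 0 or counts.L10 <= 0:
        raise ZeroDivisionError("CR undefined: C0 and L10 must be positive")
    return (counts.C10 * counts.L0) / (counts.C0 * counts.L10)


def competitive_index(counts: CompetitionCounts) -> float:
    """CI: quotient of final and initial resistant:sensitive ratios.

    Unbounded, unlike CR; undefined when the sensitive population falls
    below detection (L = C).
    """
    s0 = counts.L0 - counts.C0
    s10 = counts.L10 - counts.C10
    if s10 <= _ROUND_TOL * counts.L10:
        raise ValueError("sensitive below detection: CI cannot be computed")
    if s0 <= 0 or counts.C0 <= 0:
        raise ValueError("CI undefined for empty initial subpopulation")
    return (counts.C10 / s10) / (counts.C0 / s0)


def _check_cells(cells: pd.DataFrame):
    if len(cells) == 0:
        raise ValueError("empty cell table")
    if np.any(cells["cfp"].to_numpy() <= 0):
        raise ValueError("CFP values must be positive")
    if np.any(cells["yfp"].to_numpy() <= 0):
        raise ValueError("YFP values must be positive")


def estimate_ratio_threshold(cells: pd.DataFrame) -> float:
    """OFF/ON threshold on YFP/CFP: geometric midpoint of a two-component
    log-scale split (Gaussian mixture on log ratios, deterministic init)."""
    from sklearn.mixture import GaussianMixture

    _check_cells(cells)
    logr = np.log(cells["yfp"].to_numpy() / cells["cfp"].to_numpy()).reshape(-1, 1)
    init = np.percentile(logr, [25, 75]).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, means_init=init, n_init=1,
                         random_state=0, max_iter=500)
    gm.fit(logr)
    return float(np.exp(np.mean(gm.means_.ravel())))


def classify_cells(cells: pd.DataFrame, threshold: float | None = None):
    """Label each cell OFF/ON by its YFP/CFP ratio and report percent ON.

    With ``threshold=None`` the cutoff is estimated from the ratio
    distribution itself (two-component log-scale split).  Returns
    ``(labels, percent_on, threshold)``; the classification is invariant
    under a common rescaling of both channels.
    """
    _check_cells(cells)
    ratio = cells["yfp"].to_numpy() / cells["cfp"].to_numpy()
    if threshold is None:
        threshold = estimate_ratio_threshold(cells)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    labels = pd.Series(np.where(ratio > threshold, "ON", "OFF"),
                       index=cells.index, name="label")
    percent_on = 100.0 * float(np.mean(labels.to_numpy() == "ON"))
    return labels, percent_on, float(threshold)


def summarize_ratios(cells: pd.DataFrame) -> dict:
    """Median and geometric mean of the per-cell YFP/CFP ratio."""
    _check_cells(cells)
    ratio = cells["yfp"].to_numpy() / cells["cfp"].to_numpy()
    return {
        "median": float(np.median(ratio)),
        "geometric_mean": float(np.exp(np.mean(np.log(ratio)))),
        "n": int(ratio.size),
    }


def inoculum_presence_probability(n: int, f: float) -> float:
    """Probability that at least one minority cell is present among ``n``
    transferred cells when the minority fraction is ``f``: 1 - (1-f)^n."""
    if n < 0 or int(n) != n:
        raise ValueError("n must be a nonnegative integer")
    if not 0 <= f <= 1:
        raise ValueError("f must be in [0, 1]")
    return 1.0 - (1.0 - f) ** int(n)


def generations_from_dilution(d: float) -> float:
    """Doublings needed to regrow a d-fold dilution back to saturation: log2(d)."""
    if d < 1:
        raise ValueError("dilution factor must be >= 1")
    return float(np.log2(d))
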