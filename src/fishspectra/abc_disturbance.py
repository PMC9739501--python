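"""Abundance-biomass comparison (ABC) curves and Clarke's W statistic.

An ABC plot overlays two rank-ordered cumulative-percentage dominance
curves for the same community: one ranking species by abundance, one by
biomass (each curve sorted by its own quantity).  Their relative position
diagnoses disturbance: an undisturbed community is dominated by a few
large-bodied, slow-growing species so the biomass curve sits above the
abundance curve; under severe disturbance small fast-growing species
dominate numerically and the abundance curve lies on top; crossing curves
indicate moderate disturbance.

The W statistic summarizes the signed area between the curves:

    W = sum_i (B_i - A_i) / (50 (S - 1))

which lies in [-1, 1]; positive when biomass dominates.
"""

from __future__ import annotations

import enum
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from fishspectra.errors import DegenerateInputError, EmptyCommunityError


class DisturbanceState(str, enum.Enum):
    UNDISTURBED = "undisturbed"
    MODERATE = "moderate"
    SEVERE = "severe"


@dataclass(frozen=True)
class ABCCurves:
    """Paired cumulative-percentage curves for one community.

    ``A`` cumulates abundance, ``B`` biomass, each over its own descending
    sort; both end at 100.
    """

    A: np.ndarray
    B: np.ndarray

    @property
    def S(self) -> int:
        return len(self.A)

    @property
    def W(self) -> float:
        return w_statistic(self)


def dominance_curve(values: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    """Cumulative percentage of a quantity over its descending rank order.

    Ties are broken by species identifier (when a mapping is given) so the
    sort is reproducible; the curve ends at exactly 100.
    """
    if isinstance(values, Mapping):
        ordered = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
        vec = np.array([v for _, v in ordered], dtype=float)
    else:
        vec = np.sort(np.asarray(values, dtype=float))[::-1]
    if (vec < 0).any():
        raise ValueError("dominance values must be non-negative")
    total = vec.sum()
    if total <= 0:
        raise EmptyCommunityError("all dominance values are zero")
    return 100.0 * np.cumsum(vec) / total


def abc_curves(
    abundance: Mapping[str, float], biomass: Mapping[str, float]
) -> ABCCurves:
    """Build the paired ABC curves from per-species abundance and biomass.

    The two curves are independent sorts: ranks do not match species
    across curves (standard ABC methodology).
    """
    if set(abundance) != set(biomass):
        raise ValueError("abundance and biomass must cover the same species")
    if len(abundance) < 2:
        raise DegenerateInputError("ABC curves need at least 2 species")
    return ABCCurves(A=dominance_curve(abundance), B=dominance_curve(biomass))


def w_statistic(curves: ABCCurves) -> float:
    """Clarke's W = sum(B_i - A_i) / (50 (S - 1)), in [-1, 1]."""
    S = curves.S
    if S < 2:
        raise DegenerateInputError("W is undefined for a single species")
    return float((curves.B - curves.A).sum() / (50.0 * (S - 1)))


def classify_disturbance(curves: ABCCurves) -> DisturbanceState:
    """Three-tier disturbance state from the curves' relative position.

    undisturbed: abundance curve never above biomass (A <= B everywhere,
    strictly below somewhere); severe: the mirror case; moderate: the
    curves cross, or coincide at every rank (tie-break: neither curve is
    above the other).
    """
    diff = curves.B - curves.A
    if (diff >= 0).all() and (diff > 0).any():
        return DisturbanceState.UNDISTURBED
    if (diff <= 0).all() and (diff < 0).any():
        return DisturbanceState.SEVERE
    return DisturbanceState.MODERATE
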