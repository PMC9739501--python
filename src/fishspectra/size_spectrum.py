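"""Normalized biomass size spectrum (NBSS) construction and fitting.

Fish are binned into doubling (octave) weight classes anchored at the
minimum body weight V: class k spans [V 2^(k-1), V 2^k).  For every
non-empty class the spectrum records

    x = log2(class upper limit, g)
    y = log2( (class biomass / area) / class width )

i.e. biomass density per unit area, normalized by class width, on log2
axes.  Under the Sheldon ideal (equal total biomass per octave) the
points fall on a line of slope exactly -1.  Disturbed communities bend
into a dome; an ordinary-least-squares parabola y = a x^2 + b x + c
summarizes it, with the quadratic coefficient a ("curvature", more
negative = steeper dome) and the apex at x = -b / 2a.

Curvatures of site groups are compared with a three-tier box-plot rule:
disjoint interquartile boxes mean a very significant difference, both
medians outside the other group's box a significant one, anything else
not significant.
"""

from __future__ import annotations

import enum
import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from fishspectra.core_data import CatchRecord
from fishspectra.errors import DegenerateInputError, EmptyCommunityError


@dataclass(frozen=True)
class SizeClassScheme:
    """Doubling weight classes anchored at minimum size V (grams).

    Class k (1-based) covers the half-open interval [V 2^(k-1), V 2^k);
    widths form a geometric sequence with ratio 2.
    """

    V: float

    def class_of(self, weight: float) -> int:
        if weight <= 0:
            raise ValueError("weight must be positive")
        if weight < self.V:
            raise ValueError(f"weight {weight} below scheme minimum V={self.V}")
        return int(math.floor(math.log2(weight / self.V))) + 1

    def bounds(self, k: int) -> tuple[float, float]:
        return self.V * 2.0 ** (k - 1), self.V * 2.0**k

    def width(self, k: int) -> float:
        lo, hi = self.bounds(k)
        return hi - lo


@dataclass(frozen=True)
class SizeSpectrum:
    """NBSS points: x = log2 class upper limit, y = log2 biomass density.

    One point per non-empty class; x strictly increasing.
    """

    x: np.ndarray
    y: np.ndarray
    area: float = 1.0
    scheme: SizeClassScheme | None = None

    @property
    def n_classes(self) -> int:
        return len(self.x)


class FitModel(str, enum.Enum):
    QUADRATIC = "quadratic"
    LINEAR = "linear"


@dataclass(frozen=True)
class SpectrumFit:
    """OLS fit of an NBSS: quadratic y = a x^2 + b x + c or linear.

    ``curvature`` is the quadratic coefficient a (0 for the linear model);
    ``apex_x`` = -b/2a is reported only for dome-shaped fits (a < 0).
    """

    model: FitModel
    coefficients: tuple[float, ...]
    r_squared: float

    @property
    def curvature(self) -> float:
        return self.coefficients[0] if self.model is FitModel.QUADRATIC else 0.0

    @property
    def slope(self) -> float:
        if self.model is not FitModel.LINEAR:
            raise AttributeError("slope is defined for the linear model only")
        return self.coefficients[0]

    @property
    def intercept(self) -> float:
        return self.coefficients[-1]

    @property
    def apex_x(self) -> float | None:
        if self.model is FitModel.QUADRATIC:
            a, b, _ = self.coefficients
            if a < 0:
                return -b / (2.0 * a)
        return None

    def equation(self) -> str:
        if self.model is FitModel.QUADRATIC:
            a, b, c = self.coefficients
            return f"y = {a:.4f}x^2 + {b:.4f}x + {c:.4f}"
        m, c = self.coefficients
        return f"y = {m:.4f}x + {c:.4f}"


def _weights(records: Sequence[CatchRecord] | Sequence[float]) -> np.ndarray:
    if len(records) == 0:
        raise EmptyCommunityError("no fish to bin")
    first = records[0]
    if isinstance(first, CatchRecord):
        w = np.array([r.body_weight for r in records], dtype=float)
    else:
        w = np.asarray(records, dtype=float)
    if (w <= 0).any():
        raise ValueError("all body weights must be positive")
    return w


def assign_size_classes(
    records: Sequence[CatchRecord] | Sequence[float],
    V_override: float | None = None,
) -> tuple[SizeClassScheme, np.ndarray]:
    """Bin fish into doubling weight classes.

    V defaults to the minimum observed weight; ``V_override`` (which must
    not exceed it) forces a shared scheme across communities so their
    spectra share a bin grid.  Returns the scheme and the 1-based class
    index of every fish, ``k = floor(log2(w / V)) + 1``.
    """
    w = _weights(records)
    V = float(w.min()) if V_override is None else float(V_override)
    if V <= 0:
        raise ValueError("V must be positive")
    if V > w.min():
        raise ValueError(f"V_override {V} exceeds minimum weight {w.min()}")
    scheme = SizeClassScheme(V=V)
    classes = np.array([scheme.class_of(x) for x in w], dtype=int)
    return scheme, classes


def build_nbss(
    records: Sequence[CatchRecord] | Sequence[float],
    area: float = 1.0,
    V_override: float | None = None,
) -> SizeSpectrum:
    """Construct the normalized biomass size spectrum of a community.

    ``area`` (m^2) is the effort/area normalization constant; it shifts
    every y by the same amount and leaves slope and curvature untouched.
    Empty classes are omitted (log2 of zero biomass is undefined).
    """
    if area <= 0:
        raise ValueError("area must be positive")
    w = _weights(records)
    scheme, classes = assign_size_classes(w, V_override=V_override)
    xs, ys = [], []
    for k in np.unique(classes):
        biomass = w[classes == k].sum()
        _, upper = scheme.bounds(int(k))
        xs.append(math.log2(upper))
        ys.append(math.log2((biomass / area) / scheme.width(int(k))))
    return SizeSpectrum(
        x=np.array(xs), y=np.array(ys), area=area, scheme=scheme
    )


def fit_spectrum(
    spectrum: SizeSpectrum, model: FitModel | str = FitModel.QUADRATIC
) -> SpectrumFit:
    """Ordinary least squares fit of the spectrum points.

    Quadratic needs >= 3 points, linear >= 2; R^2 = 1 - SS_res/SS_tot
    requires non-constant y.
    """
    model = FitModel(model)
    degree = 2 if model is FitModel.QUADRATIC else 1
    x, y = spectrum.x, spectrum.y
    if len(x) < degree + 1:
        raise DegenerateInputError(
            f"{model.value} fit needs >= {degree + 1} points, got {len(x)}"
        )
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise DegenerateInputError("y has zero variance; R^2 is undefined")
    coeffs = np.polyfit(x, y, degree)
    resid = y - np.polyval(coeffs, x)
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    return SpectrumFit(
        model=model, coefficients=tuple(float(c) for c in coeffs), r_squared=r2
    )


class CurvatureDifference(str, enum.Enum):
    VERY_SIGNIFICANT = "very_significant"
    SIGNIFICANT = "significant"
    NOT_SIGNIFICANT = "not_significant"


@dataclass(frozen=True)
class BoxSummary:
    """Five-number box summary; quartiles by linear interpolation."""

    q1: float
    median: float
    q3: float
    low: float
    high: float

    @classmethod
    def of(cls, values: Sequence[float]) -> "BoxSummary":
        v = np.asarray(values, dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return cls(q1=float(q1), median=float(med), q3=float(q3),
                   low=float(v.min()), high=float(v.max()))


def compare_curvatures(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[CurvatureDifference, BoxSummary, BoxSummary]:
    """Three-tier box-plot comparison of two curvature samples.

    very_significant: the [Q1, Q3] boxes do not overlap;
    significant: each median lies outside the other group's box;
    not_significant: otherwise (at least one median inside the other box).
    Each group needs >= 3 values.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise DegenerateInputError("each group needs at least 3 curvature values")
    box_a, box_b = BoxSummary.of(group_a), BoxSummary.of(group_b)
    disjoint = box_a.q3 < box_b.q1 or box_b.q3 < box_a.q1
    if disjoint:
        verdict = CurvatureDifference.VERY_SIGNIFICANT
    else:
        a_out = not (box_b.q1 <= box_a.median <= box_b.q3)
        b_out = not (box_a.q1 <= box_b.median <= box_a.q3)
        verdict = (
            CurvatureDifference.SIGNIFICANT
            if a_out and b_out
            else CurvatureDifference.NOT_SIGNIFICANT
        )
    return verdict, box_a, box_b
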