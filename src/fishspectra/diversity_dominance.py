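"""Shannon diversity, Pielou evenness and the index of relative importance.

Shannon diversity is computed in bits (log base 2):

    H = -sum_i p_i log2 p_i,   p_i = N_i / T

Pielou evenness scales H by its maximum for S species:

    J = H / log2 S            (undefined for S = 1)

The index of relative importance of Pinkas combines a species'
numerical share N% and weight share W% (each on the 0-100 scale, summing
to 100 across species) with its occurrence frequency F% across sampling
units:

    IRI = (N% + W%) * F%

with F% entered on the 0-100 scale, giving IRI in [0, 20000]; a species
is dominant when IRI >= 1000 (the threshold is inclusive).
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from fishspectra.core_data import CatchRecord
from fishspectra.errors import DegenerateInputError, EmptyCommunityError


def _clean_abundances(abundances: Mapping[str, float]) -> dict[str, float]:
    if any(v < 0 for v in abundances.values()):
        raise ValueError("abundances must be non-negative")
    cleaned = {k: float(v) for k, v in abundances.items() if v > 0}
    if not cleaned:
        raise EmptyCommunityError("all abundances are zero")
    return cleaned


def shannon_index(abundances: Mapping[str, float], base: float = 2.0) -> float:
    """Shannon diversity of an abundance vector.

    Zero-abundance species are dropped; the default base 2 yields bits.
    """
    cleaned = _clean_abundances(abundances)
    total = sum(cleaned.values())
    p = np.array([v / total for v in cleaned.values()])
    return float(-(p * np.log(p)).sum() / math.log(base))


def pielou_evenness(abundances: Mapping[str, float], base: float = 2.0) -> float:
    """Pielou evenness J = H / log S; requires at least two species."""
    cleaned = _clean_abundances(abundances)
    S = len(cleaned)
    if S < 2:
        raise DegenerateInputError("evenness is undefined for a single species")
    return shannon_index(cleaned, base=base) / (math.log(S) / math.log(base))


@dataclass(frozen=True)
class IRIRecord:
    """Per-species relative-importance decomposition.

    N_pct, W_pct and F_pct are all on the 0-100 scale; IRI in [0, 20000].
    """

    species: str
    N_pct: float
    W_pct: float
    F_pct: float
    IRI: float
    dominant: bool


def relative_importance(
    records: Sequence[CatchRecord],
    sampling_units: Sequence[str] = ("site", "season"),
    threshold: float = 1000.0,
) -> list[IRIRecord]:
    """Index of relative importance per species, with dominance flags.

    ``sampling_units`` names the grouping fields that define one occurrence
    unit for F% (default site x season).  N% and W% are computed over the
    pooled records; F% is the percentage of units in which the species
    occurs.  Dominance is IRI >= ``threshold`` (inclusive).
    """
    if not records:
        raise EmptyCommunityError("no catch records")
    units: dict[tuple, set[str]] = {}
    for r in records:
        key = []
        for f in sampling_units:
            key.append(r.site_id if f == "site" else r.season.value)
        units.setdefault(tuple(key), set()).add(r.species)
    n_units = len(units)
    if n_units == 0:
        raise EmptyCommunityError("zero sampling units")

    count: dict[str, int] = {}
    weight: dict[str, float] = {}
    for r in records:
        count[r.species] = count.get(r.species, 0) + 1
        weight[r.species] = weight.get(r.species, 0.0) + r.body_weight
    T = sum(count.values())
    W = sum(weight.values())

    out = []
    for sp in sorted(count):
        n_pct = 100.0 * count[sp] / T
        w_pct = 100.0 * weight[sp] / W
        f_pct = 100.0 * sum(sp in seen for seen in units.values()) / n_units
        iri = (n_pct + w_pct) * f_pct
        out.append(
            IRIRecord(
                species=sp,
                N_pct=n_pct,
                W_pct=w_pct,
                F_pct=f_pct,
                IRI=iri,
                dominant=iri >= threshold,
            )
        )
    out.sort(key=lambda r: (-r.IRI, r.species))
    return out
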