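"""Synthetic multi-site, two-season fish-catch generator.

Emulates the structure of a river survey — a pool of species with
characteristic body sizes, per-site x season catches with skewed
abundance, individual weights, and a per-site environment table — so the
whole analysis chain (diversity, IRI, ABC curves, NBSS) is testable
without field data.

Disturbance regimes shape how numerical abundance pairs with body size:

* ``undisturbed``  — near-even abundances with biomass concentrated in a
  few large-bodied species, so the biomass dominance curve lies above
  the abundance curve (W > 0).
* ``severe``       — abundance concentrated in small-bodied species with
  per-species biomass roughly equal, so the abundance curve lies on top
  (W < 0).
* ``moderate``     — body size assigned independently of abundance rank;
  the curves typically cross.
* ``sheldon_ideal`` — a deterministic community with exactly equal total
  biomass in every doubling weight class, whose NBSS is a line of slope
  exactly -1.

Setting ``dome`` switches weight generation to a parabola-shaped NBSS
with a configurable curvature, apex and height (optionally coupled to
the site's dissolved-oxygen value so curvature-environment correlations
of known sign can be synthesized).

Everything is driven by a single integer seed; identical config + seed
reproduce the dataset exactly.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from fishspectra.core_data import (
    CatchRecord,
    Ecotype,
    Origin,
    Season,
    SiteEnvironment,
    SpeciesAttributes,
)
from fishspectra.errors import ConfigurationError
from fishspectra.size_spectrum import SizeSpectrum


class Regime(str, enum.Enum):
    UNDISTURBED = "undisturbed"
    MODERATE = "moderate"
    SEVERE = "severe"
    SHELDON_IDEAL = "sheldon_ideal"


class AbundanceModel(str, enum.Enum):
    GEOMETRIC_SERIES = "geometric_series"
    LOGNORMAL = "lognormal"


class DomeParams(BaseModel):
    """Target parabola for a dome-shaped NBSS.

    y = curvature * (x - apex)^2 + peak_y on the spectrum's log2 axes,
    over integer size classes 1..n_classes (V = 1 g).  ``site_sd`` jitters
    the curvature independently per site x season; ``do_coupling`` adds
    a term proportional to the site's centred dissolved-oxygen value so
    higher-DO sites get flatter (less negative) domes when positive.
    """

    model_config = ConfigDict(frozen=True)

    curvature: float = Field(lt=0.0)
    apex: float = 6.0
    peak_y: float = 8.0
    n_classes: int = Field(default=10, ge=3)
    site_sd: float = Field(default=0.02, ge=0.0)
    do_coupling: float = 0.0


# Default faunal template: family -> (order, species count for a pool of 28)
DEFAULT_FAMILIES: tuple[tuple[str, str, int], ...] = (
    ("Cyprinidae", "Cypriniformes", 14),
    ("Cobitidae", "Cypriniformes", 9),
    ("Sisoridae", "Siluriformes", 3),
    ("Balitoridae", "Cypriniformes", 1),
    ("Siluridae", "Siluriformes", 1),
)

# Shallow (tributary-like) and steep (main-stream-like) dome presets.
DOME_TRIBUTARY = DomeParams(curvature=-0.08)
DOME_MAIN_STREAM = DomeParams(curvature=-0.30)


class GeneratorConfig(BaseModel):
    """Full specification of one synthetic survey."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_sites: int = Field(default=21, ge=1)
    seasons: tuple[Season, ...] = (Season.WET, Season.DRY)
    n_species: int = Field(default=28, ge=1)
    abundance_model: AbundanceModel = AbundanceModel.GEOMETRIC_SERIES
    geometric_k: float = Field(default=0.4, gt=0.0, lt=1.0)
    lognormal_sigma: float = Field(default=1.0, gt=0.0)
    individuals_per_unit: int = Field(default=97, ge=1)
    weight_min_g: float = Field(default=0.5, gt=0.0)
    weight_max_g: float = Field(default=512.0, gt=0.0)
    weight_sigma: float = Field(default=0.4, gt=0.0)
    settled_fraction: float = Field(default=0.6, ge=0.0, le=1.0)
    exotic_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    regime: Regime = Regime.MODERATE
    sheldon_classes: int = Field(default=8, ge=3)
    dome: DomeParams | None = None

    @model_validator(mode="after")
    def _feasible(self) -> "GeneratorConfig":
        if self.regime in (Regime.SEVERE, Regime.UNDISTURBED) and self.n_species < 2:
            raise ValueError(f"{self.regime.value} regime needs >= 2 species")
        if self.weight_max_g <= self.weight_min_g:
            raise ValueError("weight_max_g must exceed weight_min_g")
        return self


@dataclass(frozen=True)
class GeneratedDataset:
    """Catch records plus the two side tables and a provenance log."""

    records: list[CatchRecord]
    attributes: dict[str, SpeciesAttributes]
    environment: dict[str, SiteEnvironment]
    provenance: dict


def _species_pool(config: GeneratorConfig) -> list[SpeciesAttributes]:
    """Deterministic species table: families allocated proportionally to
    the faunal template, ecotype/origin by configured fractions."""
    S = config.n_species
    total = sum(n for _, _, n in DEFAULT_FAMILIES)
    raw = [(fam, order, S * n / total) for fam, order, n in DEFAULT_FAMILIES]
    counts = [int(q) for _, _, q in raw]
    # largest-remainder rounding so family counts sum to S
    remainders = sorted(
        range(len(raw)), key=lambda i: (raw[i][2] - counts[i]), reverse=True
    )
    for i in remainders[: S - sum(counts)]:
        counts[i] += 1
    pool: list[SpeciesAttributes] = []
    idx = 0
    n_settled = round(config.settled_fraction * S)
    n_exotic = round(config.exotic_fraction * S)
    for (fam, order, _), n in zip(DEFAULT_FAMILIES, counts):
        for _ in range(n):
            idx += 1
            pool.append(
                SpeciesAttributes(
                    species=f"sp{idx:02d}",
                    order=order,
                    family=fam,
                    ecotype=(
                        Ecotype.SETTLED if idx <= n_settled
                        else Ecotype.SHORT_MIGRATORY
                    ),
                    origin=(
                        Origin.EXOTIC if idx > S - n_exotic else Origin.NATIVE
                    ),
                    protection=None,
                )
            )
    return pool


def _environment(config: GeneratorConfig, rng: np.random.Generator) -> dict[str, SiteEnvironment]:
    """Per-site table with a downstream altitude gradient and water-quality
    values in realistic upper-river ranges; DO rises as altitude falls."""
    n = config.n_sites
    alt = np.linspace(3400.0, 1800.0, n) if n > 1 else np.array([2600.0])
    alt = alt + rng.normal(0.0, 20.0, n)
    out: dict[str, SiteEnvironment] = {}
    for i in range(n):
        drop = 3400.0 - alt[i]
        env = SiteEnvironment(
            site_id=f"S{i + 1}",
            lat=float(31.8 - 0.25 * i + rng.normal(0, 0.05)),
            lon=float(98.5 + 0.07 * i + rng.normal(0, 0.03)),
            altitude=float(alt[i]),
            T=float(12.0 + 0.0025 * drop + rng.normal(0, 0.4)),
            DO=float(7.0 + 0.0008 * drop + rng.normal(0, 0.1)),
            V=float(rng.uniform(0.8, 2.3)),
            pH=float(rng.uniform(8.1, 8.5)),
            TDS=float(rng.uniform(110.0, 730.0)),
            TP=float(rng.uniform(0.2, 0.63)),
            TN=float(rng.uniform(0.45, 0.93)),
            CHL=float(rng.uniform(0.14, 0.66)),
            NH3N=float(rng.uniform(0.12, 0.32)),
            PO4=float(rng.uniform(0.0025, 0.025)),
        )
        out[env.site_id] = env
    return out


def _abundance_probs(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Descending species relative abundances from the configured model."""
    S = config.n_species
    if config.abundance_model is AbundanceModel.GEOMETRIC_SERIES:
        k = config.geometric_k
        p = k * (1.0 - k) ** np.arange(S)
    else:
        p = rng.lognormal(0.0, config.lognormal_sigma, S)
        p = np.sort(p)[::-1]
    return p / p.sum()


def _median_weights(config: GeneratorConfig, p: np.ndarray) -> np.ndarray:
    """Per-abundance-rank median body weight (g), regime-dependent.

    undisturbed: sizes ascend steeply with rank so rare large-bodied
    species carry the biomass; severe: size inversely proportional to
    abundance so expected per-species biomass is flat; moderate: the
    size ladder is shuffled against abundance rank by the caller.
    """
    S = config.n_species
    lo, hi = config.weight_min_g, config.weight_max_g
    ladder = np.logspace(math.log10(lo), math.log10(hi), S)
    if config.regime is Regime.SEVERE:
        w = lo * p[0] / p
        return np.clip(w, lo, hi)
    return ladder  # pairing decided by caller


def _round_weight(w: float) -> float:
    """Measurement precision: 0.1 g, truncated below at 0.1 g."""
    return max(0.1, round(w, 1))


def _length_from_weight(w: float) -> float:
    """Cubic length-weight allometry W = 0.01 L^3 (W g, L cm), 0.1 cm."""
    return max(0.1, round((w / 0.01) ** (1.0 / 3.0), 1))


def _sample_unit_regular(
    config: GeneratorConfig,
    p: np.ndarray,
    medians: np.ndarray,
    species: list[str],
    site: str,
    season: Season,
    rng: np.random.Generator,
) -> list[CatchRecord]:
    counts = rng.multinomial(config.individuals_per_unit, p)
    recs: list[CatchRecord] = []
    for i, n in enumerate(counts):
        if n == 0:
            continue
        weights = medians[i] * np.exp(rng.normal(0.0, config.weight_sigma, n))
        for w in weights:
            w = _round_weight(float(w))
            recs.append(
                CatchRecord(
                    site_id=site,
                    season=season,
                    species=species[i],
                    body_length=_length_from_weight(w),
                    body_weight=w,
                )
            )
    return recs


def _sheldon_unit(
    config: GeneratorConfig, species: list[str], site: str, season: Season
) -> list[CatchRecord]:
    """Exactly equal total biomass in every doubling class [2^(k-1), 2^k) g:
    2^(K-k+1) fish of weight 2^(k-1) g in class k, so each class holds
    2^K g and the NBSS is a line of slope exactly -1."""
    K = config.sheldon_classes
    recs: list[CatchRecord] = []
    for k in range(1, K + 1):
        w = 2.0 ** (k - 1)
        n = 2 ** (K - k + 1)
        sp = species[(k - 1) % len(species)]
        rec = CatchRecord(
            site_id=site,
            season=season,
            species=sp,
            body_length=_length_from_weight(w),
            body_weight=w,
        )
        recs.extend([rec] * n)
    return recs


def _dome_unit(
    dome: DomeParams,
    curvature: float,
    species: list[str],
    site: str,
    season: Season,
    rng: np.random.Generator,
) -> list[CatchRecord]:
    """Fish whose NBSS tracks y = a (x - apex)^2 + peak_y (V = 1 g).

    Class k gets ~(target biomass / mid-weight) fish near the geometric
    interior of [2^(k-1), 2^k), with a small within-class jitter that
    cannot cross a class boundary."""
    recs: list[CatchRecord] = []
    for k in range(1, dome.n_classes + 1):
        width = 2.0**k - 2.0 ** (k - 1)
        y = curvature * (k - dome.apex) ** 2 + dome.peak_y
        target_biomass = width * 2.0**y
        w0 = 1.5 * 2.0 ** (k - 1)
        n = int(round(target_biomass / w0))
        if n == 0:
            continue
        sp = species[(k - 1) % len(species)]
        jitter = 2.0 ** rng.uniform(-0.25, 0.25, n)
        for w in w0 * jitter:
            # jitter keeps w in [1.26, 1.78]*2^(k-1), so 0.1 g rounding
            # cannot push it across a class boundary
            w = _round_weight(float(w))
            recs.append(
                CatchRecord(
                    site_id=site,
                    season=season,
                    species=sp,
                    body_length=_length_from_weight(w),
                    body_weight=w,
                )
            )
    return recs


def generate_catch(config: GeneratorConfig) -> GeneratedDataset:
    """Generate a full synthetic survey dataset from one config + seed."""
    rng = np.random.default_rng(config.seed)
    pool = _species_pool(config)
    attributes = {a.species: a for a in pool}
    environment = _environment(config, rng)
    p = _abundance_probs(config, rng)
    names_by_size = [a.species for a in pool]  # pool order = size order

    medians = None
    shuffle = None
    if config.regime not in (Regime.SHELDON_IDEAL,) and config.dome is None:
        medians = _median_weights(config, p)
        if config.regime is Regime.UNDISTURBED:
            # flatten abundances toward uniform; biomass stays with the
            # large-bodied end of the ladder
            p = p**0.1
            p = p / p.sum()
        elif config.regime is Regime.MODERATE:
            shuffle = rng.permutation(config.n_species)
            medians = medians[shuffle]

    mean_do = float(np.mean([e.DO for e in environment.values()]))
    records: list[CatchRecord] = []
    site_curvatures: dict[str, float] = {}
    for i in range(config.n_sites):
        site = f"S{i + 1}"
        for season in config.seasons:
            if config.dome is not None:
                a = (
                    config.dome.curvature
                    + config.dome.do_coupling * (environment[site].DO - mean_do)
                    + rng.normal(0.0, config.dome.site_sd)
                )
                a = min(a, -1e-4)  # keep the dome a dome
                site_curvatures[f"{site}:{season.value}"] = a
                records.extend(
                    _dome_unit(config.dome, a, names_by_size, site, season, rng)
                )
            elif config.regime is Regime.SHELDON_IDEAL:
                records.extend(
                    _sheldon_unit(config, names_by_size, site, season)
                )
            else:
                records.extend(
                    _sample_unit_regular(
                        config, p, medians, names_by_size, site, season, rng
                    )
                )
    provenance = {
        "config": config.model_dump(mode="json"),
        "abundance_probs": [float(v) for v in p],
        "median_weights_g": (
            [float(v) for v in medians] if medians is not None else None
        ),
        "size_shuffle": (
            [int(v) for v in shuffle] if shuffle is not None else None
        ),
        "site_target_curvatures": site_curvatures or None,
        "n_records": len(records),
    }
    return GeneratedDataset(
        records=records,
        attributes=attributes,
        environment=environment,
        provenance=provenance,
    )


def generate_spectrum_points(
    a: float,
    b: float,
    c: float,
    n_points: int = 10,
    noise_sd: float = 0.0,
    seed: int | None = None,
    x_start: float = 1.0,
) -> SizeSpectrum:
    """Spectrum points y = a x^2 + b x + c + N(0, noise_sd) on an
    integer-spaced x grid, for fit-recovery experiments."""
    if n_points < 3:
        raise ConfigurationError("need at least 3 points")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    x = x_start + np.arange(n_points, dtype=float)
    y = a * x**2 + b * x + c
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, n_points)
    return SizeSpectrum(x=x, y=y)
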