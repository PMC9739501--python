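"""One-command pipeline: catch tables in, the full report bundle out.

Wires the modules together in the order a survey analysis runs them:
community summaries -> diversity -> IRI/dominants -> ABC curves with W
and the disturbance tier -> NBSS fits per group -> curvature comparison
between groups -> curvature-environment correlations.  All stages are
deterministic given the input data; randomness lives only in the
synthetic generator.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from fishspectra import abc_disturbance, core_data, diversity_dominance, size_spectrum
from fishspectra.core_data import CatchRecord, SiteEnvironment, SpeciesAttributes
from fishspectra.errors import FishspectraError
from fishspectra.size_spectrum import FitModel
from fishspectra.synthetic_data import GeneratorConfig, generate_catch
from fishspectra.transforms_stats import curvature_environment_correlations

log = logging.getLogger("fishspectra")


class StageError(FishspectraError):
    """Failure in one pipeline stage, tagged with stage and group."""

    def __init__(self, stage: str, group, cause: Exception):
        super().__init__(f"stage {stage!r}, group {group!r}: {cause}")
        self.stage = stage
        self.group = group
        self.cause = cause


class RunConfig(BaseModel):
    """Inputs and knobs for one pipeline run.

    Either the three table paths or a ``simulate`` generator config must
    be given.  ``group_by`` controls the per-group statistics; F% for the
    IRI always uses site x season occurrence units.
    """

    model_config = ConfigDict(frozen=True)

    catch_path: Optional[str] = None
    species_path: Optional[str] = None
    sites_path: Optional[str] = None
    simulate: Optional[GeneratorConfig] = None
    group_by: tuple[str, ...] = ("site", "season")
    iri_threshold: float = Field(default=1000.0, gt=0.0)
    nbss_area: float = Field(default=1.0, gt=0.0)
    shared_v: bool = False
    fit_model: FitModel = FitModel.QUADRATIC
    output_dir: Optional[str] = None


def _load(config: RunConfig):
    if config.simulate is not None:
        ds = generate_catch(config.simulate)
        return ds.records, ds.attributes, ds.environment
    if config.catch_path is None:
        raise FishspectraError("RunConfig needs either table paths or simulate")
    records = core_data.read_catch_table(config.catch_path)
    attributes = (
        core_data.read_species_table(config.species_path)
        if config.species_path
        else None
    )
    environment = (
        core_data.read_environment_table(config.sites_path)
        if config.sites_path
        else None
    )
    return records, attributes, environment


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every analysis stage; returns (and optionally writes) the bundle.

    Keys: ``diversity``, ``iri``, ``abc``, ``nbss_points``, ``nbss_fits``,
    ``curvature_comparison`` (when both seasons have >= 3 fitted groups),
    ``correlations`` (when a site table is available), ``composition``
    (when a species table is available).
    """
    records, attributes, environment = _load(config)
    summaries = _stage(
        "summarize", None, core_data.summarize_community,
        records, config.group_by, attributes,
    )

    report: dict[str, pd.DataFrame] = {}
    report["diversity"] = _diversity_table(summaries, config.group_by)
    report["iri"] = _iri_table(records, config.iri_threshold)
    report["abc"] = _abc_table(summaries, config.group_by)
    points, fits = _nbss_tables(records, summaries, config)
    report["nbss_points"] = points
    report["nbss_fits"] = fits
    comparison = _curvature_comparison(fits)
    if comparison is not None:
        report["curvature_comparison"] = comparison
    if environment is not None and len(fits):
        corr = _correlations(fits, environment)
        if corr is not None:
            report["correlations"] = corr
    if attributes is not None:
        report["composition"] = _stage(
            "composition", None, core_data.composition_tally, attributes, records
        )

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in report.items():
            df.to_csv(out / f"{name}.csv", index=False)
            log.info("wrote %s (%d rows)", out / f"{name}.csv", len(df))
    return report


def _stage(name, group, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except FishspectraError as exc:
        raise StageError(name, group, exc) from exc


def _group_cols(group_by) -> list[str]:
    return list(group_by)


def _diversity_table(summaries, group_by) -> pd.DataFrame:
    rows = []
    for key, summ in summaries.items():
        H = _stage("diversity", key, diversity_dominance.shannon_index, summ.abundance)
        J = (
            diversity_dominance.pielou_evenness(summ.abundance)
            if summ.S >= 2
            else np.nan
        )
        rows.append(
            dict(zip(_group_cols(group_by), key))
            | {"S": summ.S, "T": summ.T, "biomass_g": summ.total_biomass,
               "H": H, "J": J}
        )
    return pd.DataFrame(rows)


def _iri_table(records, threshold) -> pd.DataFrame:
    iri = _stage(
        "iri", None, diversity_dominance.relative_importance,
        records, ("site", "season"), threshold,
    )
    return pd.DataFrame(
        [
            {"species": r.species, "N_pct": r.N_pct, "W_pct": r.W_pct,
             "F_pct": r.F_pct, "IRI": r.IRI, "dominant": r.dominant}
            for r in iri
        ]
    )


def _abc_table(summaries, group_by) -> pd.DataFrame:
    rows = []
    for key, summ in summaries.items():
        if summ.S < 2:
            log.warning("ABC skipped for %s: single species", key)
            continue
        curves = _stage(
            "abc", key, abc_disturbance.abc_curves, summ.abundance, summ.biomass
        )
        rows.append(
            dict(zip(_group_cols(group_by), key))
            | {
                "S": curves.S,
                "W": abc_disturbance.w_statistic(curves),
                "disturbance": abc_disturbance.classify_disturbance(curves).value,
            }
        )
    return pd.DataFrame(rows)


def _nbss_tables(records, summaries, config) -> tuple[pd.DataFrame, pd.DataFrame]:
    v_override = None
    if config.shared_v:
        v_override = min(r.body_weight for r in records)
    by_group: dict[tuple, list[CatchRecord]] = {}
    for rec in records:
        key = core_data._group_key(rec, config.group_by)
        by_group.setdefault(key, []).append(rec)
    point_rows, fit_rows = [], []
    cols = _group_cols(config.group_by)
    min_points = 3 if config.fit_model is FitModel.QUADRATIC else 2
    for key in sorted(by_group):
        spectrum = _stage(
            "nbss", key, size_spectrum.build_nbss,
            by_group[key], config.nbss_area, v_override,
        )
        for x, y in zip(spectrum.x, spectrum.y):
            point_rows.append(dict(zip(cols, key)) | {"x": x, "y": y})
        if spectrum.n_classes < min_points:
            log.warning("NBSS fit skipped for %s: %d point(s)", key,
                        spectrum.n_classes)
            continue
        fit = _stage("nbss_fit", key, size_spectrum.fit_spectrum,
                     spectrum, config.fit_model)
        fit_rows.append(
            dict(zip(cols, key))
            | {
                "equation": fit.equation(),
                "curvature": fit.curvature,
                "slope": fit.slope if fit.model is FitModel.LINEAR else np.nan,
                "apex_x": fit.apex_x if fit.apex_x is not None else np.nan,
                "r_squared": fit.r_squared,
            }
        )
    return pd.DataFrame(point_rows), pd.DataFrame(fit_rows)


def _curvature_comparison(fits: pd.DataFrame) -> pd.DataFrame | None:
    if "season" not in fits.columns or fits.empty:
        return None
    groups = {s: g["curvature"].to_numpy() for s, g in fits.groupby("season")}
    if len(groups) != 2 or any(len(v) < 3 for v in groups.values()):
        return None
    (name_a, vals_a), (name_b, vals_b) = sorted(groups.items())
    verdict, box_a, box_b = size_spectrum.compare_curvatures(vals_a, vals_b)
    return pd.DataFrame(
        [
            {"group": name_a, "q1": box_a.q1, "median": box_a.median,
             "q3": box_a.q3, "verdict": verdict.value},
            {"group": name_b, "q1": box_b.q1, "median": box_b.median,
             "q3": box_b.q3, "verdict": verdict.value},
        ]
    )


_ENV_VARS = ("altitude", "T", "DO", "V", "pH", "TDS", "TP", "TN", "CHL",
             "NH3N", "PO4")


def _correlations(
    fits: pd.DataFrame, environment: dict[str, SiteEnvironment]
) -> pd.DataFrame | None:
    if "site" not in fits.columns:
        return None
    curv = fits.groupby("site")["curvature"].mean()
    if curv.nunique() < 2:
        return None
    env = pd.DataFrame(
        [{"site": s} | {v: getattr(e, v) for v in _ENV_VARS}
         for s, e in environment.items()]
    ).set_index("site")
    try:
        return curvature_environment_correlations(curv, env)
    except (ValueError, FishspectraError):
        return None
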