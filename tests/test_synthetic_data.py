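"""Synthetic survey generator: bookkeeping, determinism, regime fidelity."""

import numpy as np
import pydantic
import pytest

from fishspectra.abc_disturbance import abc_curves, w_statistic
from fishspectra.core_data import records_to_frame, summarize_community
from fishspectra.errors import ConfigurationError
from fishspectra.size_spectrum import FitModel, build_nbss, fit_spectrum
from fishspectra.synthetic_data import (
    DOME_MAIN_STREAM,
    DOME_TRIBUTARY,
    GeneratorConfig,
    Regime,
    generate_catch,
    generate_spectrum_points,
)


def _pooled_w(dataset) -> float:
    summ = summarize_community(dataset.records, ("all",))[("all",)]
    return w_statistic(abc_curves(summ.abundance, summ.biomass))


class TestBookkeeping:
    def test_default_survey_shape(self):
        ds = generate_catch(GeneratorConfig(seed=11))
        assert len(ds.attributes) == 28
        groups = summarize_community(ds.records, ("site", "season"))
        assert len(groups) == 42  # 21 sites x 2 seasons
        assert sum(s.T for s in groups.values()) == len(ds.records)
        assert ds.provenance["n_records"] == len(ds.records)

    def test_species_pool_matches_faunal_template(self):
        ds = generate_catch(GeneratorConfig(seed=0))
        families = {}
        for a in ds.attributes.values():
            families[a.family] = families.get(a.family, 0) + 1
        assert families == {
            "Cyprinidae": 14, "Cobitidae": 9, "Sisoridae": 3,
            "Balitoridae": 1, "Siluridae": 1,
        }
        orders = {}
        for a in ds.attributes.values():
            orders[a.order] = orders.get(a.order, 0) + 1
        assert orders == {"Cypriniformes": 24, "Siluriformes": 4}

    def test_every_record_has_attributes_and_site(self):
        ds = generate_catch(GeneratorConfig(seed=4, n_sites=3))
        for r in ds.records[:200]:
            assert r.species in ds.attributes
            assert r.site_id in ds.environment

    def test_weights_respect_measurement_precision(self):
        ds = generate_catch(GeneratorConfig(seed=9, n_sites=2))
        w = np.array([r.body_weight for r in ds.records])
        assert (w >= 0.1 - 1e-9).all()
        assert np.allclose(w, np.round(w, 1))


class TestDeterminism:
    def test_identical_seed_reproduces_tables_exactly(self):
        cfg = GeneratorConfig(seed=123, n_sites=4)
        a = generate_catch(cfg)
        b = generate_catch(cfg)
        assert records_to_frame(a.records).equals(records_to_frame(b.records))
        assert a.provenance == b.provenance
        assert a.environment == b.environment

    def test_different_seeds_differ(self):
        a = generate_catch(GeneratorConfig(seed=1, n_sites=2))
        b = generate_catch(GeneratorConfig(seed=2, n_sites=2))
        assert not records_to_frame(a.records).equals(records_to_frame(b.records))


class TestRegimes:
    def test_sheldon_ideal_nbss_is_exact_line(self):
        ds = generate_catch(
            GeneratorConfig(seed=5, regime=Regime.SHELDON_IDEAL, n_sites=1)
        )
        groups = summarize_community(ds.records, ("site", "season"))
        for key in groups:
            recs = [r for r in ds.records
                    if (r.site_id, r.season.value) == key]
            fit = fit_spectrum(build_nbss(recs), FitModel.LINEAR)
            assert fit.slope == pytest.approx(-1.0, abs=1e-12)
            assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("regime,sign", [
        (Regime.UNDISTURBED, 1), (Regime.SEVERE, -1),
    ])
    def test_regime_w_signs_across_seeds(self, regime, sign):
        for seed in range(10):
            ds = generate_catch(
                GeneratorConfig(seed=seed, regime=regime, n_sites=3)
            )
            assert sign * _pooled_w(ds) > 0

    def test_dome_presets_separate_very_significantly(self):
        """Shallow (tributary-like) and steep (main-stream-like) dome
        communities give clearly separated fitted curvatures."""
        from fishspectra.size_spectrum import (
            CurvatureDifference,
            compare_curvatures,
        )

        curvs = {}
        for name, dome in (("trib", DOME_TRIBUTARY), ("main", DOME_MAIN_STREAM)):
            ds = generate_catch(GeneratorConfig(seed=21, n_sites=4, dome=dome))
            by_unit: dict[tuple, list] = {}
            for r in ds.records:
                by_unit.setdefault((r.site_id, r.season.value), []).append(r)
            curvs[name] = [
                fit_spectrum(build_nbss(recs)).curvature
                for recs in by_unit.values()
            ]
        verdict, *_ = compare_curvatures(curvs["trib"], curvs["main"])
        assert verdict is CurvatureDifference.VERY_SIGNIFICANT

    def test_dome_curvature_tracks_target(self):
        ds = generate_catch(GeneratorConfig(seed=7, n_sites=3, dome=DOME_TRIBUTARY))
        by_unit: dict[tuple, list] = {}
        for r in ds.records:
            by_unit.setdefault((r.site_id, r.season.value), []).append(r)
        for (site, season), recs in by_unit.items():
            target = ds.provenance["site_target_curvatures"][f"{site}:{season}"]
            fitted = fit_spectrum(build_nbss(recs)).curvature
            assert fitted == pytest.approx(target, abs=0.05)

    def test_infeasible_config_rejected(self):
        with pytest.raises(pydantic.ValidationError):
            GeneratorConfig(seed=0, regime=Regime.SEVERE, n_species=1)


class TestSpectrumPoints:
    def test_noise_free_points_lie_on_the_parabola(self):
        s = generate_spectrum_points(-0.6241, 8.93, -24.06, n_points=10)
        fit = fit_spectrum(s)
        assert fit.coefficients == pytest.approx(
            (-0.6241, 8.93, -24.06), abs=1e-9
        )
        assert fit.apex_x == pytest.approx(7.154, abs=1e-3)

    def test_seeded_noise_is_reproducible(self):
        a = generate_spectrum_points(-0.1, 2.0, 0.0, noise_sd=0.1, seed=3)
        b = generate_spectrum_points(-0.1, 2.0, 0.0, noise_sd=0.1, seed=3)
        assert a.y == pytest.approx(b.y)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_spectrum_points(-0.1, 2.0, 0.0, noise_sd=-1.0)
        with pytest.raises(ConfigurationError):
            generate_spectrum_points(-0.1, 2.0, 0.0, n_points=2)
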