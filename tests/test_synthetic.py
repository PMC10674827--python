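"""Generator contracts: determinism, truth consistency at zero noise,
monotone stress encoding, and configuration validation."""

import numpy as np
import pandas as pd
import pytest

from fieldscale.errors import ConfigurationError, ValidationError
from fieldscale.pipeline import run_pipeline
from fieldscale.rgb import green_area, rgb_to_hsi
from fieldscale.spectral import ndvi
from fieldscale.synthetic import (SimConfig, TABLE1_YIELD_MEANS,
                                  render_multispectral_plot,
                                  render_rgb_canopy, simulate_field,
                                  simulate_meteo, simulate_yield)


def small_config(**kw):
    base = dict(raster_shape=(8, 8), rgb_shape=(12, 12), dates=(54, 58, 61),
                trace_days=10, trace_start_dat=52, sampling_interval_min=60)
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        a, b = (simulate_field(small_config(seed=42)) for _ in range(2))
        key = ("T40_P1", 58)
        assert np.array_equal(a.bands[key].stack(), b.bands[key].stack())
        assert np.array_equal(a.rgb[key], b.rgb[key])
        assert np.array_equal(a.traces[0].ids, b.traces[0].ids)
        pd.testing.assert_frame_equal(a.yields, b.yields)
        pd.testing.assert_frame_equal(a.meteo, b.meteo)

    def test_different_seed_same_structure_different_noise(self):
        a = simulate_field(small_config(seed=1))
        b = simulate_field(small_config(seed=2))
        assert [p.plot_id for p in a.plots] == [p.plot_id for p in b.plots]
        assert a.truth.stress_severity == b.truth.stress_severity
        key = ("T40_P1", 58)
        assert not np.array_equal(a.bands[key].stack(), b.bands[key].stack())


class TestTruthConsistency:
    def test_zero_noise_green_fraction_roundtrip(self, zero_noise_dataset):
        ds = zero_noise_dataset
        n = ds.config.rgb_shape[0] * ds.config.rgb_shape[1]
        for key, img in list(ds.rgb.items())[::7]:
            hue, _, _ = rgb_to_hsi(img)
            assert green_area(hue, 60, 180) == pytest.approx(
                100 * ds.truth.green_fraction[key], abs=100 / n)
            assert green_area(hue, 80, 180) == pytest.approx(
                100 * ds.truth.greener_fraction[key], abs=100 / n)

    def test_zero_noise_ndvi_matches_closed_form(self, zero_noise_dataset):
        ds = zero_noise_dataset
        v = ds.config.veg_reflectance
        expected = (v["nir"] - v["red"]) / (v["nir"] + v["red"])
        key = ("T100_P1", 56)
        grid = ndvi(ds.bands[key])
        assert np.allclose(grid[ds.truth.vegetation_masks[key]], expected)

    def test_greener_never_exceeds_green(self, zero_noise_dataset):
        t = zero_noise_dataset.truth
        assert all(t.greener_fraction[k] <= t.green_fraction[k] + 1e-12
                   for k in t.green_fraction)


class TestRenderers:
    def test_full_and_empty_vegetation_masks(self):
        _, _, mask1 = render_multispectral_plot(1.0, 0.2, 0.0)
        assert mask1.all()
        r0, _, mask0 = render_multispectral_plot(0.0, 0.2, 0.0)
        assert not mask0.any()
        assert np.nanmax(ndvi(r0)) < 0.5  # soil NDVI stays below vegetation

    def test_half_fraction_counts_exact(self):
        _, _, mask = render_multispectral_plot(0.5, 0.2, 0.0, shape=(10, 10))
        assert mask.sum() == 50

    def test_canopy_temperature_monotone_in_stress(self):
        tc = [render_multispectral_plot(1.0, s, 0.0)[1].tc.mean()
              for s in (0.0, 0.3, 0.7, 1.0)]
        assert all(a < b for a, b in zip(tc, tc[1:]))

    def test_rgb_extreme_fractions(self):
        img = render_rgb_canopy(1.0, 1.0, seed=0, shape=(12, 12))
        hue, _, _ = rgb_to_hsi(img)
        assert green_area(hue, 60, 180) == 100.0
        assert green_area(hue, 80, 180) == 100.0

    def test_rgb_fraction_precondition(self):
        with pytest.raises(ValidationError):
            render_rgb_canopy(0.5, 0.8)


class TestMeteoAndYield:
    def test_rh_clipped_over_many_hours(self):
        meteo = simulate_meteo(420, seed=0, noise_sd=5.0)  # > 10,000 hours
        assert meteo["rh"].between(0, 100).all()
        assert (meteo["rainfall"] >= 0).all()

    def test_diurnal_temperature_cycle(self):
        meteo = simulate_meteo(5, seed=0, noise_sd=0.0)
        ts = pd.to_datetime(meteo["timestamp"])
        assert meteo.loc[ts.dt.hour == 15, "ta"].mean() > \
            meteo.loc[ts.dt.hour == 3, "ta"].mean()

    def test_zero_noise_yield_equals_means(self):
        table = simulate_yield(TABLE1_YIELD_MEANS, 0.0, replicates=3, seed=0)
        for trt, means in TABLE1_YIELD_MEANS.items():
            sub = table[table["treatment"] == trt]
            assert np.allclose(sub["marketable"], means["marketable"])

    def test_total_is_component_sum(self):
        table = simulate_yield(TABLE1_YIELD_MEANS, 5.0, replicates=4, seed=1)
        assert np.allclose(table["total"],
                           table[["marketable", "unripen", "rotten"]].sum(axis=1))
        assert (table[["marketable", "unripen", "rotten"]] >= 0).all().all()


class TestStressEncoding:
    def test_deficit_treatment_declines_late(self, default_result):
        ds = default_result.dataset
        t = ds.truth
        late = ds.config.dates[-1]
        assert t.stress_severity[("T40_P1", late)] > t.stress_severity[("T100_P1", late)]
        assert t.green_fraction[("T40_P1", late)] < t.green_fraction[("T100_P1", late)]
        assert (t.yield_means[40]["total"] < t.yield_means[100]["total"])

    def test_smoothed_response_drops_in_deficit_plots(self, default_result):
        daily = default_result.bioristor_plot_daily
        d40 = daily[daily["treatment"] == 40].set_index("dat")["r"]
        assert d40.loc[85:].mean() < d40.loc[:60].mean()


class TestConfigValidation:
    @pytest.mark.parametrize("kw, field", [
        (dict(plots_per_treatment=1), "plots_per_treatment"),
        (dict(dates=(62, 56, 82)), "dates"),
        (dict(base_severity=1.5), "base_severity"),
        (dict(trace_noise_sd=-0.1), "trace_noise_sd"),
        (dict(monitored="some"), "monitored"),
        (dict(cross_corr_target=1.5), "cross_corr_target"),
    ])
    def test_invalid_config_names_offending_field(self, kw, field):
        with pytest.raises(ConfigurationError, match=field):
            small_config(**kw)


def test_pipeline_report_deterministic():
    import json
    reports = []
    for _ in range(2):
        res = run_pipeline(sim_config=small_config(seed=9))
        reports.append(json.dumps(res.report, sort_keys=True))
    assert reports[0] == reports[1]
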