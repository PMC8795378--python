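"""Synthetic generator: forward optics, datasets, reference growth law."""

import numpy as np
import pytest

from phycolight import synthgen
from phycolight.imaging import dark_area_fraction
from phycolight.synthgen import (
    Geometry,
    OpticalParams,
    TrueGrowthModel,
    generate_irradiance_field,
    generate_ldp,
    generate_ldp_dataset,
    irradiance_to_gsv,
    shading_penalty,
    simulate_true_growth,
)

SINGLE = Geometry(n_sources=1)
NOISE_FREE = OpticalParams(noise_sd=0.0)


class TestIrradianceField:
    def test_zero_concentration_gives_uniform_incident_field(self):
        field = generate_irradiance_field(100.0, 0.0, SINGLE, NOISE_FREE)
        assert np.allclose(field, 100.0)

    def test_half_attenuation_at_analytic_depth(self):
        """Where k*C*depth(row) = ln 2 the pre-blur field halves."""
        geom = Geometry(depth_m=0.05, n_sources=1)
        depth_r5 = geom.row_depths()[5]
        conc = np.log(2) / (NOISE_FREE.extinction_coeff * depth_r5)
        optics = OpticalParams(noise_sd=0.0, lateral_blur_sigma=0.0)
        field = generate_irradiance_field(100.0, conc, geom, optics)
        assert field[5, 0] == pytest.approx(50.0)

    def test_double_source_field_symmetric_under_row_reversal(self):
        geom = Geometry(n_sources=2)
        field = generate_irradiance_field(574.0, 1.5, geom, NOISE_FREE)
        assert np.allclose(field, field[::-1, :])

    def test_single_source_rows_non_increasing(self):
        field = generate_irradiance_field(700.0, 2.0, SINGLE, NOISE_FREE)
        assert np.all(np.diff(field, axis=0) <= 1e-12)

    @pytest.mark.parametrize("intensity, conc", [(-1.0, 1.0), (1.0, -0.1)])
    def test_negative_inputs_rejected(self, intensity, conc):
        with pytest.raises(ValueError):
            generate_irradiance_field(intensity, conc, SINGLE, NOISE_FREE)


class TestGsvConversion:
    def test_saturation_clips_to_gsv_max(self):
        optics = OpticalParams(gsv_slope=0.3, gsv_intercept=0.0, noise_sd=0.0)
        out = irradiance_to_gsv(np.full((18, 40), 1000.0), optics)
        assert np.all(out == 255)

    def test_unit_slope_maps_irradiance_to_gray(self):
        optics = OpticalParams(gsv_slope=1.0, gsv_intercept=0.0, noise_sd=0.0)
        out = irradiance_to_gsv(np.full((18, 40), 100.0), optics)
        assert np.all(out == 100)

    def test_inverse_regression_recovers_camera_line(self):
        """Regressing noise-free gray on irradiance returns the generator's
        slope/intercept (to rounding precision)."""
        optics = OpticalParams(gsv_slope=0.3, gsv_intercept=2.0, noise_sd=0.0)
        irr = np.linspace(20, 800, 50)
        gsv = irradiance_to_gsv(irr.reshape(1, -1), optics).ravel()
        ok = gsv < 255
        slope, intercept = np.polyfit(irr[ok], gsv[ok].astype(float), 1)
        assert slope == pytest.approx(0.3, abs=0.002)
        assert intercept == pytest.approx(2.0, abs=0.5)

    def test_gsv_bounds_and_integrality(self, rng):
        optics = OpticalParams(noise_sd=50.0)  # heavy noise exercises clipping
        field = rng.uniform(0, 2000, size=(18, 40))
        out = irradiance_to_gsv(field, optics, rng)
        assert out.dtype.kind == "i"
        assert out.min() >= 0 and out.max() <= 255


class TestDatasets:
    def test_cartesian_record_count(self):
        ds = generate_ldp_dataset(
            np.linspace(100, 700, 5), synthgen.REFERENCE_CONCENTRATIONS_G_L,
            SINGLE, NOISE_FREE, seed=0,
        )
        assert len(ds) == 5 * 23

    def test_regeneration_is_byte_identical(self):
        grids = (np.linspace(100, 700, 3), [0.2, 1.0, 3.0])
        a = generate_ldp_dataset(*grids, SINGLE, OpticalParams(), seed=11)
        b = generate_ldp_dataset(*grids, SINGLE, OpticalParams(), seed=11)
        for ra, rb in zip(a.records, b.records):
            assert ra.ldp.tobytes() == rb.ldp.tobytes()

    def test_empty_condition_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_ldp_dataset([], [1.0], SINGLE, NOISE_FREE)

    def test_dark_fraction_monotone_in_concentration_and_intensity(self):
        """More cells shade more; more light shades less (noise-free)."""
        geometry, optics, _ = synthgen.pbr_preset()
        optics = synthgen.with_noise(optics, 0.0)
        concs = np.linspace(0.1, 3.5, 8)
        darks_c = [
            dark_area_fraction(generate_ldp(574.0, c, geometry, optics))
            for c in concs
        ]
        assert np.all(np.diff(darks_c) >= 0)
        intens = np.linspace(100, 800, 8)
        darks_i = [
            dark_area_fraction(generate_ldp(i, 2.0, geometry, optics))
            for i in intens
        ]
        assert np.all(np.diff(darks_i) <= 0)


class TestReferenceGrowthLaw:
    def test_zero_mu_max_keeps_trajectory_flat(self):
        model = TrueGrowthModel(mu_max=0.0)
        curve = simulate_true_growth(1.5, 300.0, model, SINGLE, NOISE_FREE,
                                     hours=12.0)
        assert np.allclose(curve.od730, 1.5)

    def test_unlimited_growth_matches_exponential_closed_form(self):
        """With no attenuation, no light limitation and no shading penalty
        the law reduces to dOD/dt = mu*OD."""
        model = TrueGrowthModel(mu_max=0.08, light_half_sat=0.0)
        optics = OpticalParams(extinction_coeff=1e-9, noise_sd=0.0)
        curve = simulate_true_growth(1.0, 500.0, model, SINGLE, optics,
                                     dt=0.25, hours=10.0, substeps=8)
        exact = np.exp(0.08 * curve.times)
        assert np.allclose(curve.od730, exact, rtol=2e-3)

    def test_full_shading_plateaus_the_trajectory(self):
        """A culture dense enough that the whole path is dark stops growing."""
        geometry, optics, model = synthgen.pbr_preset()
        optics = synthgen.with_noise(optics, 0.0)
        dense_od = 12.0  # ~4.7 g/L: dark fraction ~1 under 100 µmol
        rate, dark = synthgen.true_instantaneous_rate(
            dense_od, 100.0, model, geometry, optics
        )
        assert dark > model.dark_penalty_full
        assert rate == 0.0
        curve = simulate_true_growth(dense_od, 100.0, model, geometry, optics,
                                     hours=6.0)
        assert np.allclose(curve.od730, dense_od)

    def test_shading_penalty_shape(self):
        model = TrueGrowthModel()
        assert shading_penalty(0.0, model) == 1.0
        assert shading_penalty(model.dark_penalty_onset, model) == 1.0
        assert shading_penalty(model.dark_penalty_full, model) == 0.0
        mid = 0.5 * (model.dark_penalty_onset + model.dark_penalty_full)
        assert 0.0 < shading_penalty(mid, model) < 1.0

    def test_growth_rate_peaks_then_declines_with_dark_area(self):
        """Scanning concentration at fixed light, the absolute growth rate
        rises, peaks near the penalty onset, and collapses at the plateau."""
        geometry, optics, model = synthgen.pbr_preset()
        optics = synthgen.with_noise(optics, 0.0)
        ods = np.linspace(0.2, 8.0, 60)
        rates, darks = zip(*(
            synthgen.true_instantaneous_rate(od, 574.0, model, geometry,
                                             optics)
            for od in ods
        ))
        rates, darks = np.asarray(rates), np.asarray(darks)
        peak_dark = darks[np.argmax(rates)]
        assert model.dark_penalty_onset - 0.1 <= peak_dark \
            <= model.dark_penalty_full
        assert rates[-1] < 0.05 * rates.max()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TrueGrowthModel(dark_penalty_onset=0.7, dark_penalty_full=0.65)
        with pytest.raises(ValueError):
            OpticalParams(extinction_coeff=0.0)
        with pytest.raises(ValueError):
            simulate_true_growth(0.0, 100.0, hours=1.0)


class TestDatasetExport:
    def test_csv_round_trip_preserves_records(self, tmp_path):
        ds = generate_ldp_dataset([100.0, 500.0], [0.5, 2.0], SINGLE,
                                  OpticalParams(), seed=5)
        path = tmp_path / "ds.csv"
        synthgen.write_dataset_csv(ds, path)
        loaded = synthgen.read_dataset_csv(path)
        for a, b in zip(ds.records, loaded.records):
            assert (a.intensity, a.concentration) == (b.intensity,
                                                      b.concentration)
            assert np.array_equal(a.ldp, b.ldp)

    def test_png_export_writes_manifest_and_images(self, tmp_path):
        ds = generate_ldp_dataset([100.0], [0.5, 2.0], SINGLE,
                                  OpticalParams(), seed=5)
        manifest = synthgen.write_dataset_pngs(ds, tmp_path / "out")
        import pandas as pd

        df = pd.read_csv(manifest)
        assert len(df) == 2
        from phycolight.imaging import read_ldp_png

        first = read_ldp_png(manifest.parent / df.png_path.iloc[0])
        assert np.array_equal(first, ds.records[0].ldp)
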