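"""Localization post-processing: dialect IO, rendering, drift, astigmatic z."""

import numpy as np
import pandas as pd
import pytest

from escmech.errors import (CalibrationError, FormatError, ParameterError,
                            StateError)
from escmech.storm import (LocalizationTable, apply_drift, assign_z,
                           estimate_drift, fit_astigmatism_calibration,
                           read_localizations, render_image,
                           write_localizations)
from escmech.synthetic import DefocusModel, generate_localization_table


def _table(n=100, seed=0):
    rng = np.random.default_rng(seed)
    return LocalizationTable(pd.DataFrame({
        "frame": np.arange(1, n + 1),
        "x": rng.uniform(0, 1000, n),
        "y": rng.uniform(0, 1000, n),
        "sigma": np.full(n, 150.0),
        "intensity": np.full(n, 900.0),
        "uncertainty": np.full(n, 12.0),
    }))


class TestDialectIO:
    def test_write_read_roundtrip(self, tmp_path):
        tab = _table()
        p = tmp_path / "locs.csv"
        write_localizations(tab, p)
        back = read_localizations(p)
        for col in ("frame", "x", "y", "sigma", "uncertainty"):
            assert np.allclose(back.data[col], tab.data[col])

    def test_header_spacing_variants_are_accepted(self, tmp_path):
        p = tmp_path / "locs.csv"
        p.write_text('"frame","x[nm]","y [nm]"\n1,100.0,200.0\n')
        tab = read_localizations(p)
        assert tab.data.loc[0, "x"] == 100.0
        assert tab.data.loc[0, "y"] == 200.0

    def test_unknown_columns_are_preserved(self, tmp_path):
        p = tmp_path / "locs.csv"
        p.write_text('frame,x [nm],y [nm],chi2\n1,1.0,2.0,0.7\n')
        tab = read_localizations(p)
        assert "chi2" in tab.extras.columns

    def test_empty_file_is_a_format_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(FormatError):
            read_localizations(p)

    def test_missing_mandatory_column_is_a_format_error(self, tmp_path):
        p = tmp_path / "locs.csv"
        p.write_text('frame,x [nm]\n1,1.0\n')
        with pytest.raises(FormatError):
            read_localizations(p)


class TestRendering:
    def test_single_event_occupies_one_histogram_pixel(self):
        tab = LocalizationTable(pd.DataFrame(
            {"frame": [1], "x": [55.0], "y": [75.0]}))
        img = render_image(tab, pixel_size=10.0)
        assert np.count_nonzero(img.data) == 1
        assert img.data.sum() == 1.0

    def test_gaussian_mode_conserves_mass(self):
        tab = _table(200)
        img = render_image(tab, pixel_size=20.0, mode="gaussian")
        assert img.data.sum() == pytest.approx(200.0, abs=1e-6)

    def test_emitter_grid_spacing_is_recovered(self):
        xs, ys = np.meshgrid(np.arange(5) * 500.0, np.arange(5) * 500.0)
        pos = np.column_stack([xs.ravel(), ys.ravel()])
        tab, _ = generate_localization_table(pos, 500, 0.4, 5.0, seed=1)
        img = render_image(tab, pixel_size=20.0)
        marg = img.data.sum(axis=0)
        peaks = np.flatnonzero(marg > marg.max() * 0.3)
        groups = np.split(peaks, np.flatnonzero(np.diff(peaks) > 3) + 1)
        centers = np.array([g.mean() for g in groups]) * 20.0
        assert len(centers) == 5
        assert np.allclose(np.diff(centers), 500.0, atol=20.0)

    def test_empty_table_warns_and_returns_empty_image(self):
        tab = LocalizationTable(pd.DataFrame(
            {"frame": pd.Series(dtype=int), "x": pd.Series(dtype=float),
             "y": pd.Series(dtype=float)}))
        with pytest.warns(UserWarning):
            img = render_image(tab, 10.0)
        assert img.data.sum() == 0


class TestDrift:
    def _drifting_table(self, drift=(0.01, 0.005), n_frames=10000, seed=4):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 5000, size=(60, 2))
        tab, truth = generate_localization_table(
            pos, n_frames, 0.02, 15.0, drift_per_frame=drift, seed=seed)
        return tab, truth

    def test_zero_drift_gives_near_zero_shifts(self):
        tab, _ = self._drifting_table(drift=(0.0, 0.0))
        model = estimate_drift(tab, n_bins=8)
        assert np.abs(model.dx).max() < 10.0
        assert np.abs(model.dy).max() < 10.0

    def test_linear_drift_is_recovered(self):
        tab, _ = self._drifting_table()
        model = estimate_drift(tab, n_bins=10)
        span = model.bin_center_frame[-1] - model.bin_center_frame[0]
        assert abs(model.dx[-1] - 0.01 * span) < 10.0
        assert abs(model.dy[-1] - 0.005 * span) < 10.0

    def test_correction_shrinks_scatter_to_localization_noise(self):
        pos = np.array([[1000.0, 1000.0]])
        tab, _ = generate_localization_table(
            pos, 10000, 0.3, 15.0, drift_per_frame=(0.01, 0.0), seed=6)
        model = estimate_drift(tab, n_bins=10)
        corr = apply_drift(tab, model)
        assert corr.data["x"].std() < 1.3 * 15.0

    def test_reestimation_after_correction_is_near_identity(self):
        tab, _ = self._drifting_table()
        model = estimate_drift(tab, n_bins=10)
        corr = apply_drift(tab, model)
        model2 = estimate_drift(corr, n_bins=10)
        assert np.abs(model2.dx).max() < 10.0
        assert np.abs(model2.dy).max() < 10.0

    def test_step_drift_yields_two_plateaus(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 4000, size=(80, 2))
        tab, _ = generate_localization_table(pos, 4000, 0.05, 10.0, seed=7)
        shifted = tab.data.copy()
        shifted.loc[shifted["frame"] > 2000, "x"] += 80.0
        tab2 = LocalizationTable(shifted)
        model = estimate_drift(tab2, n_bins=8)
        early = model.dx[model.bin_center_frame < 1800]
        late = model.dx[model.bin_center_frame > 2200]
        assert np.abs(early).max() < 10.0
        assert np.abs(late - 80.0).max() < 10.0

    def test_zero_model_is_identity(self):
        tab, _ = self._drifting_table()
        from escmech.storm import DriftModel
        model = DriftModel(np.array([1.0, 10000.0]), np.zeros(2), np.zeros(2))
        out = apply_drift(tab, model)
        assert np.array_equal(out.data["x"], tab.data["x"])

    def test_too_few_bins_is_an_error(self):
        tab, _ = self._drifting_table()
        with pytest.raises(ParameterError):
            estimate_drift(tab, n_bins=1)


def _calibration_stack(model, z_planes, events_per_plane=40, jitter=0.02,
                       seed=9, shuffle=False):
    rng = np.random.default_rng(seed)
    stage_z = np.repeat(z_planes, events_per_plane)
    if shuffle:
        order = rng.permutation(stage_z.size)
        stage_z = stage_z[order]
    n_frames = stage_z.size
    pos = rng.uniform(0, 2000, size=(4, 2))
    tab, _ = generate_localization_table(
        pos, n_frames, 0.8, 10.0, astigmatism_model=model,
        z_positions=np.zeros(4), seed=seed)
    fr = tab.data["frame"].to_numpy()
    sx, sy = model.sigmas(stage_z[fr - 1])
    j = np.abs(rng.normal(1.0, jitter, size=(2, fr.size)))
    tab.data["sigma_x"] = sx * j[0]
    tab.data["sigma_y"] = sy * j[1]
    return tab, stage_z


class TestAstigmatism:
    def test_calibration_matches_generator_model(self):
        model = DefocusModel()
        tab, stage_z = _calibration_stack(model, np.linspace(-400, 400, 17))
        cal = fit_astigmatism_calibration(tab, stage_z)
        zs = np.linspace(-350, 350, 29)
        zs = zs[np.abs(zs) > 50]  # avoid division near the zero crossing
        rel = np.abs(cal.elongation(zs) / model.elongation(zs) - 1.0)
        assert rel.max() < 0.05

    def test_symmetric_spots_raise_calibration_error(self):
        model = DefocusModel(focal_shift_nm=0.0)  # no astigmatism
        tab, stage_z = _calibration_stack(model, np.linspace(-400, 400, 9))
        with pytest.raises(CalibrationError):
            fit_astigmatism_calibration(tab, stage_z)

    def test_plane_order_does_not_matter(self):
        model = DefocusModel()
        planes = np.linspace(-400, 400, 9)
        t1, z1 = _calibration_stack(model, planes, jitter=0.0, seed=3)
        t2, z2 = _calibration_stack(model, planes, jitter=0.0, seed=3,
                                    shuffle=True)
        c1 = fit_astigmatism_calibration(t1, z1)
        c2 = fit_astigmatism_calibration(t2, z2)
        assert np.allclose(c1.coefficients, c2.coefficients, rtol=0.05)

    def test_symmetric_event_maps_to_focus(self):
        model = DefocusModel()
        tab, stage_z = _calibration_stack(model, np.linspace(-400, 400, 17))
        cal = fit_astigmatism_calibration(tab, stage_z)
        ev = LocalizationTable(pd.DataFrame(
            {"frame": [1], "x": [0.0], "y": [0.0],
             "sigma_x": [150.0], "sigma_y": [150.0]}))
        out = assign_z(ev, cal)
        assert abs(out.data.loc[0, "z"]) < 5.0

    def test_known_z_recovered_with_small_bias(self):
        model = DefocusModel()
        tab, stage_z = _calibration_stack(model, np.linspace(-400, 400, 17))
        cal = fit_astigmatism_calibration(tab, stage_z)
        rng = np.random.default_rng(10)
        emitters = rng.uniform(0, 2000, size=(6, 2))
        ev, _ = generate_localization_table(
            emitters, 3000, 0.05, 10.0, astigmatism_model=model,
            z_positions=np.full(6, 200.0), seed=11)
        out = assign_z(ev, cal)
        assert abs(out.data["z"].mean() - 200.0) < 20.0

    def test_out_of_range_events_are_dropped_and_counted(self):
        model = DefocusModel()
        tab, stage_z = _calibration_stack(model, np.linspace(-300, 300, 13))
        cal = fit_astigmatism_calibration(tab, stage_z)
        sx, sy = model.sigmas(np.array([600.0]))  # beyond the scan range
        ev = LocalizationTable(pd.DataFrame(
            {"frame": [1, 2], "x": [0.0, 0.0], "y": [0.0, 0.0],
             "sigma_x": [sx[0], 150.0], "sigma_y": [sy[0], 150.0]}))
        out = assign_z(ev, cal)
        assert out.meta["dropped_out_of_range"] == 1
        assert len(out) == 1

    def test_missing_calibration_is_a_state_error(self):
        ev = LocalizationTable(pd.DataFrame(
            {"frame": [1], "x": [0.0], "y": [0.0],
             "sigma_x": [150.0], "sigma_y": [140.0]}))
        with pytest.raises(StateError):
            assign_z(ev, None)
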