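import numpy as np
import pytest

import epidpsm as ep
from epidpsm import (
    AcquisitionSpec,
    BeamResponse,
    EpidImage,
    PanelGeometry,
    Psm,
    PsmTruthModel,
    acquire,
    apply_flood,
    beam_response_from_psm,
    fit_beam_response_surface,
    grid_calibrate,
    grid_sample_beam_response,
    make_beam_response,
    make_flood,
    make_grid_plan,
    make_truth_psm,
    psm_from_beam_response,
    radial_average,
    remove_flood,
    wide_open_spec,
)
from epidpsm.calibration import GridSamples


def _raw(values, geometry, kind="raw"):
    return EpidImage(values, geometry, kind=kind)


class TestFloodOperators:
    def test_unit_round_trip(self, odd_geometry):
        ones = np.ones(odd_geometry.shape)
        raw = remove_flood(_raw(ones, odd_geometry, "corrected"), _raw(ones, odd_geometry, "flood"))
        np.testing.assert_array_equal(raw.values, 1.0)
        assert raw.kind == "raw"

    def test_remove_flood_hand_example(self, odd_geometry):
        flood = np.ones(odd_geometry.shape)
        flood[1, 2] = 1.02  # away from the central axis, CAX stays exactly 1
        raw = remove_flood(
            _raw(np.ones(odd_geometry.shape), odd_geometry, "corrected"),
            _raw(flood, odd_geometry, "flood"),
        )
        assert raw.values[1, 2] == pytest.approx(1.02, abs=1e-15)

    def test_apply_then_remove_is_identity(self, truth_psm, beams, desk_geometry):
        beam = beams["6MV"]
        raw = acquire(truth_psm, beam, wide_open_spec(desk_geometry, noise_sigma=0.002, seed=1))
        raw.values[truth_psm.dead_mask] = 0.1  # keep flood positive everywhere
        flood = make_flood(
            ep.make_truth_psm(PsmTruthModel(dead_pixel_fraction=0.0, seed=8), desk_geometry), beam
        )
        round_trip = remove_flood(apply_flood(raw, flood), flood)
        np.testing.assert_allclose(round_trip.values, raw.values, rtol=1e-12)

    def test_identity_flood_keeps_image(self, truth_psm, beams, desk_geometry):
        raw = acquire(truth_psm, beams["10MV"], wide_open_spec(desk_geometry))
        flood = _raw(np.ones(desk_geometry.shape), desk_geometry, "flood")
        corrected = apply_flood(raw, flood, dead_mask=truth_psm.dead_mask)
        live = ~truth_psm.dead_mask
        np.testing.assert_allclose(corrected.values[live], raw.values[live], rtol=1e-14)

    def test_flood_equal_to_raw_flattens_image(self, truth_psm, beams, desk_geometry):
        flood = make_flood(truth_psm, beams["6FFF"])
        raw = EpidImage(flood.values.copy(), desk_geometry, kind="raw")
        corrected = apply_flood(raw, flood, dead_mask=truth_psm.dead_mask)
        live = ~truth_psm.dead_mask
        cax = flood.central_axis_value()
        np.testing.assert_allclose(corrected.values[live], cax, rtol=1e-12)

    def test_nonpositive_flood_pixel_is_error(self, odd_geometry):
        flood = np.ones(odd_geometry.shape)
        flood[4, 4] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            apply_flood(
                _raw(np.ones(odd_geometry.shape), odd_geometry),
                _raw(flood, odd_geometry, "flood"),
            )


class TestDecomposition:
    def test_unit_psm_panel_recovers_unit_sensitivity(self, beams, desk_geometry, unit_psm):
        beam = beams["6MV"]
        raw = acquire(unit_psm, beam, wide_open_spec(desk_geometry))
        psm = psm_from_beam_response(raw, make_beam_response(beam, desk_geometry))
        np.testing.assert_allclose(psm.values[~psm.dead_mask], 1.0, atol=1e-12)

    def test_scale_invariance_of_psm_extraction(self, beams, desk_geometry):
        beam = beams["10FFF"]
        br = make_beam_response(beam, desk_geometry)
        raw = _raw(2.0 * br.values, desk_geometry)
        psm = psm_from_beam_response(raw, br)
        np.testing.assert_allclose(psm.values[~psm.dead_mask], 1.0, atol=1e-12)

    def test_noise_free_round_trip_recovers_truth_psm(self, truth_psm, beams, desk_geometry):
        beam = beams["10FFF"]
        raw = acquire(truth_psm, beam, wide_open_spec(desk_geometry))
        psm = psm_from_beam_response(raw, make_beam_response(beam, desk_geometry))
        ok = ~psm.dead_mask & ~truth_psm.dead_mask
        np.testing.assert_allclose(psm.values[ok], truth_psm.values[ok], rtol=1e-12)
        assert psm.dead_mask[truth_psm.dead_mask].all()  # dead pixels land in the PSM

    def test_exact_decomposition_identity(self, truth_psm, beams, desk_geometry):
        """S = raw/B then B' = raw/S returns B exactly on non-dead pixels."""
        beam = beams["6MV"]
        raw = acquire(truth_psm, beam, wide_open_spec(desk_geometry))
        br = make_beam_response(beam, desk_geometry)
        psm = psm_from_beam_response(raw, br)
        br2 = beam_response_from_psm(raw, psm)
        ok = ~psm.dead_mask
        np.testing.assert_allclose(br2.values[ok], br.values[ok], rtol=1e-12)

    def test_dead_pixels_interpolated_in_beam_response(self, truth_psm, beams, desk_geometry):
        beam = beams["10MV"]
        raw = acquire(truth_psm, beam, wide_open_spec(desk_geometry))
        br = beam_response_from_psm(raw, truth_psm)
        assert br.interpolated_mask is not None
        dead = truth_psm.dead_mask
        assert br.interpolated_mask[dead].all()
        assert (br.values[dead] > 0).all()  # filled from neighbours, not left at zero


class TestGridSampling:
    def test_unit_beam_all_samples_one(self, truth_psm, flat_beam, desk_geometry):
        plan = make_grid_plan(desk_geometry, base_seed=2)
        images = [acquire(truth_psm, flat_beam, s) for s in plan.acquisitions]
        samples = grid_sample_beam_response(images, plan)
        np.testing.assert_allclose(samples.values, 1.0, atol=1e-13)

    def test_origin_sample_exactly_one(self, truth_psm, beams, desk_geometry):
        plan = make_grid_plan(desk_geometry, base_seed=2)
        images = [acquire(truth_psm, beams["6MV"], s) for s in plan.acquisitions]
        samples = grid_sample_beam_response(images, plan)
        origin = plan.origin_index()
        assert samples.values[origin] == 1.0

    def test_sensitivity_cancellation_machine_precision(self, beams, desk_geometry):
        """Grid samples are invariant under replacement of the truth PSM."""
        beam = beams["10FFF"]
        plan = make_grid_plan(desk_geometry, base_seed=4)
        results = []
        for seed in (11, 99):
            psm = make_truth_psm(PsmTruthModel(seed=seed), desk_geometry)
            images = [acquire(psm, beam, s) for s in plan.acquisitions]
            results.append(grid_sample_beam_response(images, plan).values)
        np.testing.assert_allclose(results[0], results[1], rtol=1e-12)

    def test_sample_oracle_direct_truth_field_evaluation(self, truth_psm, beams, desk_geometry):
        """Each sample equals the truth-beam per-pixel ratio mean over the ROI."""
        beam = beams["10FFF"]
        plan = make_grid_plan(desk_geometry, base_seed=6)
        images = [acquire(truth_psm, beam, s) for s in plan.acquisitions]
        samples = grid_sample_beam_response(images, plan, roi_halfwidth_px=5)
        X, Y = desk_geometry.grid_mm()
        roi = desk_geometry.central_roi(5)
        xq, yq = X[roi], Y[roi]
        denom = beam.profile(xq, yq)
        for (px, py), value in zip(plan.nodes_mm, samples.values):
            oracle = float(np.mean(beam.profile(xq + px, yq + py) / denom))
            assert value == pytest.approx(oracle, rel=1e-12)

    def test_roi_averaging_suppresses_acquisition_noise(self, beams, desk_geometry, unit_psm):
        """Monte-Carlo: the sample s.e. matches sqrt(2)*sigma/sqrt(N_roi)."""
        beam = beams["6FFF"]
        node = (100.0, 0.0)
        sigma = 0.005
        roi = desk_geometry.central_roi(5)
        n_roi = (roi[0].stop - roi[0].start) * (roi[1].stop - roi[1].start)
        common = dict(field_size_mm=(50.0, 50.0), noise_sigma=sigma)
        vals = []
        for rep in range(100):
            shifted = acquire(unit_psm, beam, AcquisitionSpec(
                field_center_mm=node, panel_offset_mm=(-node[0], -node[1]),
                seed=10_000 + rep, **common))
            origin = acquire(unit_psm, beam, AcquisitionSpec(
                field_center_mm=(0.0, 0.0), seed=20_000 + rep, **common))
            num, den = shifted.values[roi], origin.values[roi]
            vals.append(float(np.mean(num / den)))
        vals = np.asarray(vals)
        expected_se = sigma * np.sqrt(2.0 / n_roi)
        assert vals.std() < 2.0 * expected_se
        assert abs(vals.mean() - vals.mean().round(3)) < 5 * expected_se  # stable mean

    def test_missing_acquisitions_rejected(self, truth_psm, flat_beam, desk_geometry):
        plan = make_grid_plan(desk_geometry, base_seed=2)
        images = [acquire(truth_psm, flat_beam, s) for s in plan.acquisitions][:-1]
        with pytest.raises(ValueError, match="expected"):
            grid_sample_beam_response(images, plan)


class TestSurfaceFit:
    def test_constant_samples_give_unit_surface(self, desk_geometry):
        nodes = [(x, y) for y in (-100, 0, 100) for x in (-100, 0, 100)]
        samples = GridSamples(np.array(nodes, float), np.ones(9), 8.0)
        for degree in (1, 2):
            br, fit = fit_beam_response_surface(samples, desk_geometry, degree)
            np.testing.assert_allclose(br.values, 1.0, atol=1e-12)
            assert fit.rms_residual < 1e-12

    def test_degree_two_polynomial_reproduced_exactly(self, desk_geometry):
        coords = np.arange(-150, 151, 50, dtype=float)
        nodes = np.array([(x, y) for y in coords for x in coords])
        f = 1.0 + 1e-3 * nodes[:, 0] - 2e-5 * nodes[:, 0] * nodes[:, 1] + 1e-5 * nodes[:, 1] ** 2
        samples = GridSamples(nodes, f, 8.0)
        _, fit = fit_beam_response_surface(samples, desk_geometry, degree=3)
        assert np.abs(fit.node_residuals).max() < 1e-10

    def test_fff_truth_fit_within_half_percent(self, beams, desk_geometry, unit_psm):
        beam = beams["10FFF"]
        plan = make_grid_plan(desk_geometry, base_seed=1)
        images = [acquire(unit_psm, beam, s) for s in plan.acquisitions]
        samples = grid_sample_beam_response(images, plan)
        br, fit = fit_beam_response_surface(samples, desk_geometry, degree=4)
        truth = make_beam_response(beam, desk_geometry)
        X, Y = desk_geometry.grid_mm()
        inside = (np.abs(X) <= 150) & (np.abs(Y) <= 150)
        err = np.abs(br.values - truth.values)[inside]
        assert err.max() <= 0.005
        np.testing.assert_array_equal(fit.extrapolated_mask, ~((np.abs(X) <= 150) & (np.abs(Y) <= 150)))

    def test_spline_basis_behind_same_interface(self, beams, desk_geometry, unit_psm):
        beam = beams["6FFF"]
        plan = make_grid_plan(desk_geometry, base_seed=1)
        images = [acquire(unit_psm, beam, s) for s in plan.acquisitions]
        samples = grid_sample_beam_response(images, plan)
        br, fit = fit_beam_response_surface(samples, desk_geometry, basis="spline")
        truth = make_beam_response(beam, desk_geometry)
        X, Y = desk_geometry.grid_mm()
        inside = (np.abs(X) <= 150) & (np.abs(Y) <= 150)
        assert fit.basis == "spline"
        assert np.abs(br.values - truth.values)[inside].max() <= 0.01

    def test_rank_deficient_degree_rejected(self, desk_geometry):
        coords = np.arange(-150, 151, 50, dtype=float)
        nodes = np.array([(x, y) for y in coords for x in coords])
        samples = GridSamples(nodes, np.ones(len(nodes)), 8.0)
        with pytest.raises(ValueError, match="degree"):
            fit_beam_response_surface(samples, desk_geometry, degree=7)


class TestGridCalibrate:
    def test_unit_sensitivity_recovered_within_fit_error(self, beams, desk_geometry, unit_psm):
        beam = beams["10FFF"]
        plan = make_grid_plan(desk_geometry, base_seed=3)
        images = [acquire(unit_psm, beam, s) for s in plan.acquisitions]
        wide = acquire(unit_psm, beam, wide_open_spec(desk_geometry))
        _, psm, _ = grid_calibrate(images, plan, wide)
        X, Y = desk_geometry.grid_mm()
        inside = (np.abs(X) <= 150) & (np.abs(Y) <= 150) & ~psm.dead_mask
        assert np.abs(psm.values[inside] - 1.0).max() < 0.003

    def test_pixel_structure_lands_in_psm_not_beam(self, truth_psm, beams, desk_geometry):
        beam = beams["6FFF"]
        plan = make_grid_plan(desk_geometry, base_seed=3)
        images = [acquire(truth_psm, beam, s) for s in plan.acquisitions]
        wide = acquire(truth_psm, beam, wide_open_spec(desk_geometry))
        br, psm, _ = grid_calibrate(images, plan, wide)
        # the fitted beam-response is smooth (tiny second differences) while
        # the pixel-level gain structure shows up in the PSM
        assert np.std(np.diff(br.values, n=2, axis=1)) < 1e-4
        assert np.std(np.diff(psm.values[~psm.dead_mask.any(axis=1)], n=2, axis=1)) > 1e-3
        ok = ~psm.dead_mask & ~truth_psm.dead_mask
        X, Y = desk_geometry.grid_mm()
        inside = ok & (np.abs(X) <= 150) & (np.abs(Y) <= 150)
        med = np.median(np.abs(psm.values[inside] / truth_psm.values[inside] - 1.0))
        assert med < 0.002


class TestRadialAverage:
    def test_matches_brute_force_on_9x9(self):
        g = PanelGeometry(9, 9, 9.0)
        rng = np.random.default_rng(17)
        values = 1.0 + 0.2 * rng.random((9, 9))
        field = BeamResponse(values, g, normalization="none")
        out = radial_average(field, bin_width_mm=g.pixel_pitch_mm)

        X, Y = g.grid_mm()
        r = np.hypot(X, Y)
        expected = np.empty_like(values)
        for i in range(9):
            for j in range(9):
                b = int(r[i, j] // g.pixel_pitch_mm)
                members = [
                    values[k, l]
                    for k in range(9)
                    for l in range(9)
                    if int(r[k, l] // g.pixel_pitch_mm) == b
                ]
                expected[i, j] = np.mean(members)
        expected /= expected[4, 4]
        np.testing.assert_allclose(out.values, expected, rtol=1e-13)

    def test_radially_symmetric_input_preserved_within_bin_variation(self, beams):
        g = PanelGeometry(64, 64, 400.0)
        br = make_beam_response(beams["6FFF"], g)
        out = radial_average(br, bin_width_mm=g.pixel_pitch_mm)
        X, Y = g.grid_mm()
        r = np.hypot(X, Y)
        idx = np.floor(r / g.pixel_pitch_mm).astype(int)
        max_in_bin_variation = max(
            np.ptp(br.values[idx == b]) for b in np.unique(idx)
        )
        assert np.abs(out.values - br.values / br.central_axis_value()).max() <= max_in_bin_variation + 1e-12

    def test_tilted_input_becomes_radially_symmetric(self, desk_geometry):
        tilted = ep.BeamModel("t", "fff", rolloff_coeff=0.05, tilt=0.01, collimator_radius_mm=1e6)
        br = make_beam_response(tilted, desk_geometry)
        out = radial_average(br, bin_width_mm=2.0)
        X, Y = desk_geometry.grid_mm()
        r = np.hypot(X, Y)
        idx = np.floor(r / 2.0).astype(int)
        for b in (5, 30, 60):
            ring = out.values[idx == b]
            assert np.ptp(ring) < 1e-12

    def test_bin_width_below_half_pitch_rejected(self, desk_geometry, beams):
        br = make_beam_response(beams["6MV"], desk_geometry)
        with pytest.raises(ValueError, match="bin width"):
            radial_average(br, bin_width_mm=0.4 * desk_geometry.pixel_pitch_mm)
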