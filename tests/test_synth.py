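"""Generator correctness: conservation, determinism, noise statistics."""

import math

import numpy as np
import pandas as pd
import pytest

import patchquant as pq
from patchquant.errors import GenerationError, InvalidSpecError
from patchquant.synth import triangular_trace


class TestIlluminationField:
    def test_peak_is_one_at_center(self):
        spec = pq.SceneSpec(image_shape=(64, 64), illum_center=(32, 32), illum_sigma=20)
        field = pq.make_illumination_field(spec)
        assert field[32, 32] == pytest.approx(1.0)
        assert field.max() == pytest.approx(1.0)

    def test_matches_closed_form_pointwise(self):
        sigma = 17.0
        spec = pq.SceneSpec(image_shape=(64, 64), illum_center=(20, 40), illum_sigma=sigma)
        field = pq.make_illumination_field(spec)
        for y, x in [(0, 0), (20, 10), (55, 40), (33, 33)]:
            d2 = (y - 20) ** 2 + (x - 40) ** 2
            assert field[y, x] == pytest.approx(math.exp(-d2 / (2 * sigma**2)), rel=1e-12)

    def test_flat_limit(self):
        spec = pq.SceneSpec(image_shape=(32, 32), illum_min_fraction=1.0)
        assert np.all(pq.make_illumination_field(spec) == 1.0)

    def test_min_fraction_reached_at_far_corner(self):
        spec = pq.SceneSpec(image_shape=(64, 96), illum_min_fraction=0.4)
        field = pq.make_illumination_field(spec)
        corner = min(field[0, 0], field[0, -1], field[-1, 0], field[-1, -1])
        assert corner == pytest.approx(0.4, rel=1e-9)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(InvalidSpecError):
            pq.SceneSpec(illum_sigma=-1.0)


class TestTriangularTrace:
    def test_shape_and_conservation_of_peak(self):
        t = np.linspace(0, 40, 4001)
        v = triangular_trace(t, 10.0, 50.0, 500.0, 40.0)
        assert v[t < 10].max() == 0.0
        assert v.max() == pytest.approx(500.0, abs=0.05)
        # rises at 50/s, falls at 40/s
        assert np.interp(15.0, t, v) == pytest.approx(250.0, abs=0.1)
        assert np.interp(25.0, t, v) == pytest.approx(500 - 40 * 5, abs=0.1)
        assert v[t > 10 + 10 + 12.5].max() == 0.0


class TestCalibrationStack:
    def test_zero_cells_is_offset_background(self):
        spec = pq.SceneSpec.calibration(image_shape=(48, 48), camera_offset=100.0,
                                        read_noise_sd=0.0, shot_noise=False, rng_seed=0)
        stack, gt = pq.render_calibration_stack(spec, [])
        assert stack.n_z == 21
        assert np.allclose(stack.data, 100.0)
        assert len(gt.cells) == 0

    def test_total_conserved_noise_off_flat(self):
        spec = pq.SceneSpec.calibration(
            image_shape=(96, 96), illum_min_fraction=1.0, camera_offset=0.0,
            read_noise_sd=0.0, shot_noise=False, rng_seed=0,
        )
        cell = pq.CellSpec(center=(48, 48), autofluorescence_total=30_000,
                           tagged_molecules=5_000, brightness_per_molecule=10.0)
        stack, _ = pq.render_calibration_stack(spec, [cell])
        assert stack.data.sum() == pytest.approx(30_000 + 5_000 * 10.0, rel=1e-9)

    def test_overlapping_cells_rejected(self):
        spec = pq.SceneSpec.calibration(image_shape=(96, 96), rng_seed=0)
        cells = [pq.CellSpec(center=(48, 48)), pq.CellSpec(center=(52, 50))]
        with pytest.raises(GenerationError):
            pq.render_calibration_stack(spec, cells)

    def test_cell_outside_frame_rejected(self):
        spec = pq.SceneSpec.calibration(image_shape=(64, 64), rng_seed=0)
        with pytest.raises(GenerationError):
            pq.render_calibration_stack(spec, [pq.CellSpec(center=(5, 5))])

    def test_measured_totals_unbiased_over_seeds(self):
        """Noisy per-cell totals agree with expectation within 3 SE (MC)."""
        deviations = []
        for seed in range(5):
            spec = pq.SceneSpec.calibration(
                image_shape=(320, 320), illum_min_fraction=1.0, rng_seed=seed
            )
            rng = np.random.default_rng(seed)
            cells = pq.synth.place_cells(spec, 20, rng, tagged_molecules=3000)
            stack, _ = pq.render_calibration_stack(spec, cells)
            proj = stack.sum_projection()[0] - spec.camera_offset * spec.n_z
            for cell in cells:
                y0, x0 = int(cell.center[0]), int(cell.center[1])
                r = int(max(cell.axes)) + 5
                window = proj[max(y0 - r, 0) : y0 + r + 1, max(x0 - r, 0) : x0 + r + 1]
                deviations.append(window.sum() - cell.total_fluorescence)
        deviations = np.asarray(deviations)
        se = deviations.std(ddof=1) / math.sqrt(len(deviations))
        assert abs(deviations.mean()) <= 3 * se + 1e-9


class TestPatchMovie:
    def test_identity_bleach_keeps_cytoplasm_flat(self, flat_quiet_spec):
        cells = [pq.CellSpec(center=(48, 48), autofluorescence_total=30_000)]
        stack, _ = pq.render_patch_movie(flat_quiet_spec, cells, [])
        proj = stack.sum_projection()
        inside = proj[:, 48, 48]
        assert inside[0] == pytest.approx(inside[-1], rel=1e-12)

    def test_single_patch_trace_conserved(self, flat_quiet_spec):
        cells = [pq.CellSpec(center=(48, 48), autofluorescence_total=0.0,
                             brightness_per_molecule=10.0)]
        patch = pq.PatchSpec(cell_index=0, appear_time=15.0, assembly_rate=50.0,
                             peak_molecules=500.0, disassembly_rate=40.0,
                             motion_sd=0.0, position=(48, 48))
        stack, gt = pq.render_patch_movie(flat_quiet_spec, cells, [patch])
        frame_totals = stack.sum_projection().sum(axis=(1, 2))
        expected = patch.molecules(stack.times) * 10.0
        np.testing.assert_allclose(frame_totals, expected, atol=1e-6)

    def test_cytoplasm_bleaches_by_decay_curve(self, bleach_model):
        spec = pq.SceneSpec(image_shape=(96, 96), illum_min_fraction=1.0,
                            camera_offset=0.0, read_noise_sd=0.0,
                            shot_noise=False, rng_seed=0)
        cells = [pq.CellSpec(center=(48, 48), autofluorescence_total=30_000)]
        stack, _ = pq.render_patch_movie(spec, cells, [], bleach_model)
        trace = stack.sum_projection()[:, 48, 48]
        np.testing.assert_allclose(
            trace / trace[0], bleach_model.decay(stack.times), rtol=1e-9
        )

    def test_patch_referencing_missing_cell(self, flat_quiet_spec):
        cells = [pq.CellSpec(center=(48, 48))]
        patch = pq.PatchSpec(cell_index=3, appear_time=10, assembly_rate=50,
                             peak_molecules=500, disassembly_rate=40)
        with pytest.raises(InvalidSpecError):
            pq.render_patch_movie(flat_quiet_spec, cells, [patch])

    def test_deterministic_given_seed(self):
        spec = pq.SceneSpec(image_shape=(128, 128), n_frames=10, rng_seed=11)
        rng = np.random.default_rng(11)
        cells = pq.synth.place_cells(spec, 2, rng)
        a, _ = pq.render_patch_movie(spec, cells, [])
        b, _ = pq.render_patch_movie(spec, cells, [])
        np.testing.assert_array_equal(a.data, b.data)


class TestGroundTruthIO:
    def test_csv_round_trip(self, tmp_path, movie_scene):
        gt = movie_scene["gt"]
        gt.to_csv(tmp_path / "gt")
        back = pq.GroundTruth.from_csv(tmp_path / "gt")
        pd.testing.assert_frame_equal(gt.cells, back.cells)
        pd.testing.assert_frame_equal(gt.patches, back.patches)
        pd.testing.assert_frame_equal(gt.traces, back.traces)
        assert back.bleach == pytest.approx(gt.bleach)
        assert back.calibration_slope == gt.calibration_slope


class TestODSeries:
    def test_zero_rate_constant(self):
        df = pq.simulate_od_series(0.0, 0.25, np.arange(0, 10, 2.0))
        assert np.allclose(df["od"], 0.25)

    def test_one_doubling(self):
        df = pq.simulate_od_series(0.5, 0.1, [0.0, 2.0])
        assert df["od"].iloc[1] == pytest.approx(0.2, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidSpecError):
            pq.simulate_od_series(-0.1, 0.1, [0, 1])
        with pytest.raises(InvalidSpecError):
            pq.simulate_od_series(0.1, 0.0, [0, 1])
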