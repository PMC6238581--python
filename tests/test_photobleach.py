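"""Histogram mixture, threshold, mask voting, and bleach-decay fitting."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import patchquant as pq
from patchquant import photobleach
from patchquant.errors import DegenerateMixtureError, MaskingError, ThresholdError
from patchquant.photobleach import (
    BleachModel,
    BrightnessHistogram,
    apply_bleach_correction,
    build_intracellular_mask,
    fit_bleach_model,
    fit_pixel_mixture,
    intracellular_threshold,
)


def sample_histogram(rng, means, sds, weights, n=100_000):
    comp = rng.choice(len(means), size=n, p=weights)
    vals = rng.normal(np.asarray(means)[comp], np.asarray(sds)[comp])
    counts, edges = np.histogram(vals, bins=120)
    return BrightnessHistogram(bin_edges=edges, counts=counts)


class TestPixelMixture:
    @pytest.mark.parametrize("order", [(0, 1), (1, 0)])
    def test_recovers_two_populations(self, order):
        """Means within 2 % over seeds, regardless of generation order."""
        means = [(100, 400)[i] for i in order]
        sds = [(10, 60)[i] for i in order]
        weights = [(0.7, 0.3)[i] for i in order]
        errs = []
        for seed in range(25):
            hist = sample_histogram(np.random.default_rng(seed), means, sds, weights)
            model = fit_pixel_mixture(hist)
            errs.append(abs(model.background[1] - 100) / 100)
            errs.append(abs(model.intracellular[1] - 400) / 400)
            assert model.intracellular[1] > model.background[1]
        assert np.median(errs) < 0.02

    def test_single_population_degenerate(self):
        hist = sample_histogram(np.random.default_rng(0), [200], [20], [1.0])
        with pytest.raises(DegenerateMixtureError):
            fit_pixel_mixture(hist)


class TestThreshold:
    def _model(self, sep=20.0):
        return photobleach.PixelMixtureModel(
            background=(0.7, 100.0, 10.0), intracellular=(0.3, 100.0 + sep * 10, 10.0)
        )

    def test_purity_holds_by_numerical_integration(self):
        model = self._model()
        edges = np.linspace(0, 500, 200)
        hist = BrightnessHistogram(bin_edges=edges, counts=np.ones(199))
        t = intracellular_threshold(model, hist, 0.95)
        assert 100.0 < t < 300.0
        intr = 0.3 * quad(lambda v: norm.pdf(v, 300, 10), t, 1000)[0]
        bg = 0.7 * quad(lambda v: norm.pdf(v, 100, 10), t, 1000)[0]
        assert intr / (intr + bg) >= 0.95

    def test_tiny_target_returns_lowest_edge(self):
        model = self._model()
        edges = np.linspace(0, 500, 50)
        hist = BrightnessHistogram(bin_edges=edges, counts=np.ones(49))
        assert intracellular_threshold(model, hist, 1e-9) == edges[0]

    def test_overlapping_populations_error(self):
        model = photobleach.PixelMixtureModel(
            background=(0.999, 100.0, 50.0), intracellular=(0.001, 110.0, 50.0)
        )
        edges = np.linspace(0, 150, 50)  # truncated range: purity never reached
        hist = BrightnessHistogram(bin_edges=edges, counts=np.ones(49))
        with pytest.raises(ThresholdError):
            intracellular_threshold(model, hist, 0.999)

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            mb = rng.uniform(50, 150)
            mi = mb + rng.uniform(10, 20) * 30
            model = photobleach.PixelMixtureModel(
                background=(rng.uniform(0.3, 0.8), mb, rng.uniform(5, 15)),
                intracellular=(0.3, mi, rng.uniform(20, 80)),
            )
            edges = np.linspace(mb - 50, mi + 300, 173)
            hist = BrightnessHistogram(bin_edges=edges, counts=np.ones(172))
            t = intracellular_threshold(model, hist, 0.95)
            wb, mub, sb = model.background
            wi, mui, si = model.intracellular
            brute = next(
                e for e in edges
                if wi * norm.sf(e, mui, si)
                / (wi * norm.sf(e, mui, si) + wb * norm.sf(e, mub, sb))
                >= 0.95
            )
            assert abs(t - brute) <= np.diff(edges).max() + 1e-9


class TestMask:
    def _stack(self, values):
        """Movie whose Z-sum projection at every pixel follows `values` rows."""
        data = np.asarray(values, dtype=float)[:, None, :, :]
        return pq.MovieStack(data)

    def test_threshold_below_minimum_gives_all_true(self):
        frames = np.full((10, 4, 4), 50.0)
        mask = build_intracellular_mask(self._stack(frames), threshold=10.0)
        assert mask.mask.all()

    def test_vote_boundary_eight_of_ten(self):
        frames = np.zeros((10, 2, 2))
        frames[:7, 0, 0] = 100.0  # 7 of 10: excluded
        frames[:8, 0, 1] = 100.0  # 8 of 10: included
        mask = build_intracellular_mask(self._stack(frames), threshold=50.0)
        assert not mask.mask[0, 0]
        assert mask.mask[0, 1]

    def test_empty_mask_error(self):
        frames = np.zeros((10, 4, 4))
        with pytest.raises(MaskingError):
            build_intracellular_mask(self._stack(frames), threshold=10.0)

    def test_mask_matches_cell_footprints(self, corrected_movie, movie_scene):
        """Voting mask agrees with the true ellipse footprint on >= 95 % of pixels."""
        _, report = photobleach.bleach_correct(corrected_movie)
        frame0 = corrected_movie.sum_projection()[0]
        hist = BrightnessHistogram.from_image(frame0)
        mixture = fit_pixel_mixture(hist)
        threshold = intracellular_threshold(mixture, hist)
        mask = build_intracellular_mask(corrected_movie, threshold)
        truth = np.zeros(movie_scene["spec"].image_shape, dtype=bool)
        for cell in movie_scene["cells"]:
            rows, cols, m = cell.footprint(truth.shape)
            truth[rows, cols] |= m
        agreement = (mask.mask == truth).mean()
        assert agreement >= 0.95


def _uniform_stack(trace):
    """Movie where every pixel of every frame equals the trace value."""
    t = np.asarray(trace, dtype=float)
    data = np.broadcast_to(t[:, None, None, None], (len(t), 1, 8, 8)).copy()
    return pq.MovieStack(data)


class TestBleachFit:
    def _mask(self):
        return photobleach.IntracellularMask(
            mask=np.ones((8, 8), bool), threshold=0.0, frames_used=10, min_votes=8
        )

    def test_constant_trace_is_identity(self):
        model = fit_bleach_model(_uniform_stack(np.full(60, 250.0)), self._mask())
        assert model.decay(59.0) == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_biexponential_recovery(self):
        t = np.arange(60.0)
        true = BleachModel(a1=0.3, k1=0.1, a2=0.7, k2=0.005)
        model = fit_bleach_model(_uniform_stack(500 * true.decay(t)), self._mask())
        assert model.a1 == pytest.approx(0.3, rel=0.01)
        assert model.k1 == pytest.approx(0.1, rel=0.01)
        assert model.a2 == pytest.approx(0.7, rel=0.01)
        assert model.k2 == pytest.approx(0.005, rel=0.01)
        assert model.normalization == pytest.approx(500, rel=0.01)

    def test_single_exponential_fallback(self):
        t = np.arange(60.0)
        model = fit_bleach_model(_uniform_stack(400 * np.exp(-0.02 * t)), self._mask())
        assert model.a2 == 0.0  # fallback branch
        assert model.k1 == pytest.approx(0.02, rel=0.01)

    def test_rate_ordering_invariant(self):
        t = np.arange(60.0)
        true = BleachModel(a1=0.6, k1=0.2, a2=0.4, k2=0.01)
        model = fit_bleach_model(_uniform_stack(100 * true.decay(t)), self._mask())
        assert model.k1 >= model.k2 >= 0
        assert model.a1 + model.a2 == pytest.approx(1.0)


class TestApplyCorrection:
    def test_identity_model_is_noop(self, corrected_movie):
        out = apply_bleach_correction(corrected_movie, BleachModel.identity())
        np.testing.assert_array_equal(out.data, corrected_movie.data)

    def test_true_model_flattens_noiseless_trace(self, bleach_model):
        spec = pq.SceneSpec(image_shape=(96, 96), illum_min_fraction=1.0,
                            camera_offset=0.0, read_noise_sd=0.0, shot_noise=False,
                            rng_seed=0)
        cells = [pq.CellSpec(center=(48, 48), autofluorescence_total=40_000)]
        stack, _ = pq.render_patch_movie(spec, cells, [], bleach_model)
        out = apply_bleach_correction(stack, bleach_model)
        trace = out.sum_projection()[:, 48, 48]
        assert np.ptp(trace) / trace[0] < 1e-6

    def test_fit_then_apply_residual_slope(self, corrected_movie):
        """End-to-end correction leaves < 0.1 %/min residual trend."""
        out, report = photobleach.bleach_correct(corrected_movie)
        hist = BrightnessHistogram.from_image(corrected_movie.sum_projection()[0])
        mixture = fit_pixel_mixture(hist)
        thr = intracellular_threshold(mixture, hist)
        mask = build_intracellular_mask(corrected_movie, thr)
        trace = photobleach.median_intracellular_trace(out, mask)
        slope = np.polyfit(out.times / 60.0, trace / trace.mean(), 1)[0]
        assert abs(slope) < 1e-3

    def test_bleach_free_movie_left_nearly_unchanged(self):
        """Full chain on a movie with no bleaching is ~ the identity map."""
        spec = pq.SceneSpec(image_shape=(128, 128), n_frames=60, rng_seed=5)
        rng = np.random.default_rng(5)
        cells = pq.synth.place_cells(spec, 4, rng)
        stack, _ = pq.render_patch_movie(spec, cells, [])
        from patchquant import corrections

        dark, flat = pq.make_reference_images(spec)
        corr = corrections.correct_stack(stack, dark, flat)
        out, report = photobleach.bleach_correct(corr)
        rel = np.abs(out.data - corr.data).max() / corr.data.max()
        assert rel < 2e-2
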