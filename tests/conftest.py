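"""Shared fixtures: small synthetic scenes reused across test modules."""

import numpy as np
import pytest

import patchquant as pq

DEFAULT_BLEACH = dict(a1=0.3, k1=0.1, a2=0.7, k2=0.005)


@pytest.fixture(scope="session")
def bleach_model():
    return pq.BleachModel(**DEFAULT_BLEACH)


@pytest.fixture(scope="session")
def movie_scene(bleach_model):
    """One default-noise patch movie with ground truth and references.

    20 cells / 20 patches on a 320 px field, the desk-scale stand-in for a
    full-size acquisition; rendered once per session because several test
    modules (photobleach, tracking, alignment) exercise it read-only.
    """
    spec = pq.SceneSpec(image_shape=(320, 320), n_z=6, n_frames=60, rng_seed=7)
    rng = np.random.default_rng(7)
    cells = pq.synth.place_cells(spec, 20, rng)
    patches = pq.synth.place_patches(spec, cells, 20, rng)
    stack, gt = pq.render_patch_movie(spec, cells, patches, bleach_model)
    dark, flat = pq.make_reference_images(spec)
    return {"spec": spec, "cells": cells, "patches": patches, "stack": stack,
            "gt": gt, "dark": dark, "flat": flat}


@pytest.fixture(scope="session")
def corrected_movie(movie_scene):
    from patchquant import corrections

    return corrections.correct_stack(
        movie_scene["stack"], movie_scene["dark"], movie_scene["flat"]
    )


@pytest.fixture
def flat_quiet_spec():
    """Flat-illumination, noise-free acquisition for conservation checks."""
    return pq.SceneSpec(
        image_shape=(96, 96), n_z=6, n_frames=60, illum_min_fraction=1.0,
        camera_offset=0.0, read_noise_sd=0.0, shot_noise=False, rng_seed=0,
    )
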