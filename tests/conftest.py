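"""Shared fixtures: a small synthetic head, sensor array, and lead fields.

All heavy objects are session-scoped; tests treat them as read-only.
"""

import warnings

import numpy as np
import pytest

import opmlaminar as om


@pytest.fixture(autouse=True)
def _silence_patch_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="patch at vertex")
        yield


@pytest.fixture(scope="session")
def small_head():
    """Default-radii head at low mesh resolution (642 vertices per layer)."""
    space, scalp = om.make_head_geometry(subdivisions=3, seed=0)
    return space, scalp


@pytest.fixture(scope="session")
def bumpy_head():
    space, scalp = om.make_head_geometry(
        subdivisions=3, bump_amplitude_mm=3.0, seed=5
    )
    return space, scalp


@pytest.fixture(scope="session")
def small_setup(small_head):
    """Geometry + 45 mm single-axis array + lead fields for both layers."""
    space, scalp = small_head
    array = om.pack_sensors(scalp, 45.0, seed=1)
    array = om.build_channel_axes(array, 1)
    array = om.offset_sensors(array, scalp, 6.5)
    conductor = om.fit_conductor(space.pial, array)
    lf_pial = om.leadfield_for_surface(space.pial, array, conductor, "pial")
    lf_white = om.leadfield_for_surface(space.white, array, conductor, "white")
    return dict(
        space=space,
        scalp=scalp,
        array=array,
        conductor=conductor,
        lf_pial=lf_pial,
        lf_white=lf_white,
        pial_model=om.LayerModel(space.pial, lf_pial, "pial"),
        white_model=om.LayerModel(space.white, lf_white, "white"),
    )


@pytest.fixture(scope="session")
def dataset_factory(small_setup):
    """Simulated noisy datasets from the small setup, keyed by arguments."""

    def make(
        surface="pial",
        vertex=100,
        fwhm=10.0,
        snr_db=-5.0,
        n_trials=40,
        seed=7,
        amplitude=10.0,
    ):
        lf = small_setup["lf_pial" if surface == "pial" else "lf_white"]
        mesh = getattr(small_setup["space"], surface)
        patch = om.gaussian_patch(mesh, vertex, fwhm)
        ds = om.simulate_signal(
            patch, lf, amplitude_nam=amplitude, n_trials=n_trials
        )
        return om.add_noise(ds, om.SnrSpec("per_trial_snr", snr_db), seed=seed)

    return make
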