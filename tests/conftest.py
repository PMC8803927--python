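import warnings

import numpy as np
import pytest

from qpicell import synth
from qpicell.pipeline import run_qpi_pipeline


def make_small_scene(seed: int = 7, n_frames: int = 12) -> synth.SceneSpec:
    """A compact two-cell QPI scene used across tests (fast to render)."""
    return synth.SceneSpec(
        field_size_px=(256, 200),
        pixel_size_um=634.0 / 512.0,
        lapse_interval_min=10.0,
        n_frames=n_frames,
        cells=[
            synth.CellSpec(
                initial_mass_pg=300.0,
                doubling_time_h=36.0,
                initial_position_um=(90.0, 70.0),
                speed_um_per_h=18.0,
                persistence_time_min=60.0,
                shape_sigma_um=(8.0, 6.5),
            ),
            synth.CellSpec(
                initial_mass_pg=700.0,
                doubling_time_h=36.0,
                initial_position_um=(230.0, 170.0),
                speed_um_per_h=22.0,
                persistence_time_min=60.0,
                shape_sigma_um=(9.5, 8.0),
            ),
        ],
        background_poly_coeffs=(0.02, 0.03, -0.02, 0.01, 0.015, -0.01),
        frame_offset_sd=0.005,
        intensity_noise_sd=0.5,
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def small_scene():
    spec = make_small_scene()
    truth = synth.simulate_ground_truth(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ifs, truth = synth.render_interferograms(truth, spec)
    return spec, ifs, truth


@pytest.fixture(scope="session")
def small_pipeline(small_scene):
    spec, ifs, truth = small_scene
    results = run_qpi_pipeline(ifs, spec.pixel_size_um, spec.lapse_interval_min)
    return spec, truth, results


def match_track_to_cell(track, truth) -> int:
    """Index of the ground-truth cell whose start is nearest to the track's."""
    p0 = np.asarray(track.positions_um[0])
    d = np.linalg.norm(truth.trajectories[:, track.start_frame] - p0, axis=1)
    return int(d.argmin())
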