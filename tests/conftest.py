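import numpy as np
import pytest

from curtainlab.geometry import DnaGeometry
from curtainlab.render import OpticsConfig, render_kymograph
from curtainlab.simulate import SimulationConfig, simulate_population
from curtainlab.tracking import detect_spots, filter_trajectories, link_trajectories


@pytest.fixture(scope="session")
def geometry():
    return DnaGeometry()


@pytest.fixture(scope="session")
def tracked_scene(geometry):
    """Render a 5-molecule pure-sliding scene (each on its own DNA axis,
    high SNR) and track it; shared by the round-trip recovery tests."""
    d_true = 0.025
    n_frames = 250
    cfg = SimulationConfig(
        d_slide_um2_s=d_true, n_frames=n_frames, seed=42, start_position_bp=24000
    )
    trajs = simulate_population(cfg, 5, geometry)
    for i, t in enumerate(trajs):
        t.axis_per_frame = np.full(t.n_frames, i)
    optics = OpticsConfig()
    stack, sidecar = render_kymograph(
        trajs, optics, geometry, axis_separation_um=2.0, seed=7
    )
    detections = [
        detect_spots(frame, frame_index=f) for f, frame in enumerate(stack)
    ]
    tracks = link_trajectories(
        detections, pixel_size_um=optics.pixel_size_um, geometry=geometry
    )
    kept, _ = filter_trajectories(tracks, 50)
    return {
        "d_true": d_true,
        "n_frames": n_frames,
        "truth": trajs,
        "optics": optics,
        "stack": stack,
        "sidecar": sidecar,
        "detections": detections,
        "tracks": kept,
    }
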