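import numpy as np
import pytest

import lxkin as lk


@pytest.fixture(scope="session")
def acq():
    return lk.AcquisitionSpec()


@pytest.fixture(scope="session")
def lx_gesture():
    return lk.GestureSpec(onset_ms=400, transition_ms=250, hold_ms=250, release_ms=300,
                          amplitude_mm=5.0)


@pytest.fixture(scope="session")
def oral_gesture():
    return lk.GestureSpec(onset_ms=350, transition_ms=220, hold_ms=300, release_ms=250,
                          amplitude_mm=1.0)


@pytest.fixture(scope="session")
def vtr():
    # 19 px (~45 mm) tall, 16 px (~38 mm) wide region enclosing the larynx path
    return lk.VTRSpec("LX", (44, 32, 19, 16))


@pytest.fixture(scope="session")
def seed_point():
    return lk.SeedPoint((56.0, 40.0))


def make_scene(lx_gesture, oral_gesture=None, **kwargs):
    return lk.PhantomScene(
        larynx_blob=lk.Blob((56.0, 40.0), (4.0, 4.0), 1.0),
        larynx_gesture=lx_gesture,
        oral_tissue=lk.FillRegion((20.0, 20.0), 3.0, 1.0) if oral_gesture else None,
        oral_gesture=oral_gesture,
        **kwargs,
    )


@pytest.fixture(scope="session")
def phantom(acq, lx_gesture, oral_gesture):
    """Noiseless canonical phantom: raising larynx + oral closure."""
    scene = make_scene(lx_gesture, oral_gesture)
    video, truth = lk.render_phantom_video(scene, acq, 1800.0, seed=11)
    return scene, video, truth


@pytest.fixture(scope="session")
def tracked(phantom, vtr, seed_point):
    _, video, _ = phantom
    return lk.track_centroids(video, vtr, seed_point)


def brute_force_vtr_centroid(frame: np.ndarray, vtr) -> tuple[float, float]:
    """Independent oracle: intensity-weighted average over the whole VTR."""
    sub = frame[vtr.slices]
    rows = np.arange(vtr.rect_px[0], vtr.rect_px[0] + vtr.rect_px[2], dtype=float)
    cols = np.arange(vtr.rect_px[1], vtr.rect_px[1] + vtr.rect_px[3], dtype=float)
    w = sub.sum()
    return float(sub.sum(axis=1) @ rows / w), float(sub.sum(axis=0) @ cols / w)
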