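import numpy as np
import pytest

from grafhip import PhantomSpec, make_sweep_video, render_frame

ALPHA_GRID = (50.0, 55.0, 60.0, 65.0, 70.0, 75.0)
BETA_GRID = (40.0, 55.0, 70.0)


@pytest.fixture(scope="session")
def default_frame():
    """A clean standard-plane phantom (alpha 60, beta 55, no tilt, no noise)."""
    return render_frame(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def grid_frames():
    """Noise-free phantom frames over the alpha x beta recovery grid."""
    frames = {}
    for a in ALPHA_GRID:
        for b in BETA_GRID:
            frames[(a, b)] = render_frame(PhantomSpec(alpha_true=a, beta_true=b, seed=7))
    return frames


@pytest.fixture(scope="session")
def sweep_videos():
    """Twenty seeded probe-sweep videos crossing the standard plane."""
    videos = []
    for seed in range(20):
        base = PhantomSpec(
            alpha_true=55.0 + (seed % 5) * 4.0,
            beta_true=50.0 + (seed % 3) * 7.0,
            noise_sigma=3.0,
            seed=seed,
        )
        videos.append(make_sweep_video(base, n_frames=9, seed=seed))
    return videos


def bar_image(tilt_deg: float, length: int = 220, width: int = 6, size: int = 256) -> np.ndarray:
    """A bright bar tilted ``tilt_deg`` from vertical on a black background."""
    from skimage.draw import polygon

    img = np.zeros((size, size), dtype=float)
    t = np.radians(tilt_deg)
    c = np.array([size / 2, size / 2])
    d = np.array([np.sin(t), -np.cos(t)])  # toward the top, leaning +x for t>0
    n = np.array([np.cos(t), np.sin(t)])
    corners = [
        c + length / 2 * d + width / 2 * n,
        c + length / 2 * d - width / 2 * n,
        c - length / 2 * d - width / 2 * n,
        c - length / 2 * d + width / 2 * n,
    ]
    rr, cc = polygon([p[1] for p in corners], [p[0] for p in corners], (size, size))
    img[rr, cc] = 200.0
    return img
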