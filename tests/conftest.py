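import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def bernsen_bruteforce(img, window, contrast_threshold):
    """Independent per-pixel sliding-window Bernsen oracle (reflect padding)."""
    img = np.asarray(img, dtype=float)
    half = window // 2
    padded = np.pad(img, half, mode="reflect")
    out = np.zeros(img.shape, dtype=bool)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            win = padded[r : r + window, c : c + window]
            lo, hi = win.min(), win.max()
            if hi - lo >= contrast_threshold:
                out[r, c] = img[r, c] > (hi + lo) / 2.0
    return out


@pytest.fixture(scope="session")
def rendered_study():
    """One standard synthetic patch with ground truth, shared across tests."""
    from morindex import fixtures as fx

    layout = fx.random_nucleus_layout(20, 20, 10, (256, 256), seed=3)
    patch, truth = fx.render_ihc_patch(layout, (256, 256), noise_sd=0.0, seed=3)
    return layout, patch, truth
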