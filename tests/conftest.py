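import numpy as np
import pytest

from sraiflux.field_prep import PreparedField


def make_prepared(
    stable,
    labile,
    background_stable=0.0,
    background_labile=0.0,
    saturation=None,
):
    """PreparedField straight from planes, bypassing focus/projection."""
    stable = np.asarray(stable, dtype=np.float64)
    labile = np.asarray(labile, dtype=np.float64)
    if saturation is None:
        saturation = np.zeros(stable.shape, dtype=bool)
    return PreparedField(
        stable_plane=stable,
        labile_plane=labile,
        background_stable=background_stable,
        background_labile=background_labile,
        saturation_mask=saturation,
        chosen_z=0,
    )


def match_detections(detections, centers, tol_px=3.0):
    """Greedy matching of detections to planted centres within tol_px.

    Returns (n_true_positive, n_false_positive, n_missed).
    """
    remaining = list(centers)
    tp = fp = 0
    for d in detections:
        dy, dx = (d.y, d.x) if hasattr(d, "y") else (d[0], d[1])
        hit = None
        for i, (cy, cx) in enumerate(remaining):
            if (dy - cy) ** 2 + (dx - cx) ** 2 <= tol_px**2:
                hit = i
                break
        if hit is None:
            fp += 1
        else:
            tp += 1
            remaining.pop(hit)
    return tp, fp, len(remaining)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
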