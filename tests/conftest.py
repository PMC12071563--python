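import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mitograde as mg

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def frame():
    """A 5×5 mm slide frame at 0.24 µm/px."""
    return mg.SlideFrame(mpp=0.24, width_px=21000, height_px=21000, slide_id="fx")


@pytest.fixture
def square_region():
    """5×5 mm square tumor region in microns."""
    return mg.rectangle_mm(5.0, 5.0)


@pytest.fixture
def clustered_slide(frame, square_region):
    """One synthetic slide with a planted hotspot at (2.5, 2.5) mm."""
    center = mg.PointUm(2500.0, 2500.0)
    cfg = mg.SlideSimConfig(
        frame=frame, region=square_region, lambda_bg=2.0,
        clusters=(mg.Cluster(center, 200.0, 200),), seed=42,
    )
    dets, labels = mg.generate_point_pattern(cfg)
    return cfg, dets, labels, center


def brute_force_counts(centers, mitoses, r1, r2):
    """Exhaustive all-pairs distance oracle for hotspot counting."""
    from scipy.spatial.distance import cdist

    c = np.asarray(centers, dtype=float)
    m = np.asarray(mitoses, dtype=float)
    if len(m) == 0:
        z = np.zeros(len(c), dtype=int)
        return z, z
    d = cdist(c, m)
    return (d <= r1).sum(axis=1), (d <= r2).sum(axis=1)
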