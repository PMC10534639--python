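import numpy as np
import pytest

import fundusreg as fr


@pytest.fixture(scope="session")
def scene7():
    """Vascular scene with known junction geometry (seed 7)."""
    return fr.generate_tree(7)


@pytest.fixture(scope="session")
def pair0():
    """Default high-overlap noiseless synthetic pair (seed 0)."""
    return fr.generate_pair(0)


@pytest.fixture(scope="session")
def enhanced0(pair0):
    return fr.preprocess(pair0.source)


def draw_polyline_skeleton(scene) -> np.ndarray:
    """Rasterize a scene's segments as 1-px lines (a skeleton-domain tree)."""
    from skimage.draw import line

    A = np.zeros((scene.canvas, scene.canvas), dtype=bool)
    for s in scene.segments:
        rr, cc = line(
            int(round(s.p0[1])), int(round(s.p0[0])),
            int(round(s.p1[1])), int(round(s.p1[0])),
        )
        ok = (rr >= 0) & (rr < scene.canvas) & (cc >= 0) & (cc < scene.canvas)
        A[rr[ok], cc[ok]] = True
    return A
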