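import numpy as np
import pytest

from flexdetect.io_formats import Box
from flexdetect.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def low_contrast_image() -> np.ndarray:
    """Seeded synthetic image with gray levels confined to [100, 140]."""
    rng = np.random.default_rng(42)
    img = rng.integers(100, 141, size=(96, 96, 3)).astype(np.uint8)
    return img


@pytest.fixture(scope="session")
def scene_pair():
    """One degraded synthetic scene plus its ground-truth boxes."""
    return generate_scene(SceneSpec(), seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def random_boxes(rng: np.random.Generator, n: int, n_classes: int = 3,
                 with_conf: bool = False) -> list[Box]:
    out = []
    for _ in range(n):
        w = rng.uniform(0.05, 0.3)
        h = rng.uniform(0.05, 0.3)
        cx = rng.uniform(w / 2, 1 - w / 2)
        cy = rng.uniform(h / 2, 1 - h / 2)
        conf = float(rng.uniform(0.01, 1.0)) if with_conf else None
        out.append(Box(int(rng.integers(n_classes)), cx, cy, w, h, conf))
    return out
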