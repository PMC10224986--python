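import numpy as np
import pytest

from iscmetrics.scene import AnnotatedScene
from iscmetrics.synthetic import (
    DegradationSpec,
    NucleusClassSpec,
    PopulationSpec,
    degrade,
    generate_scene,
)

TWO_CLASSES = (
    NucleusClassSpec(1, "epithelial", 0.5, 683.0, (524.0, 858.0)),
    NucleusClassSpec(2, "lymphocyte", 0.5, 266.0, (221.0, 314.0)),
)


def add_rect(instance_map, iid, r0, c0, h, w):
    instance_map[r0:r0 + h, c0:c0 + w] = iid


def rect_scene(shape, rects, classes):
    """Scene from (iid, r0, c0, h, w) rectangles and an {iid: class} map."""
    m = np.zeros(shape, dtype=np.int32)
    for iid, r0, c0, h, w in rects:
        add_rect(m, iid, r0, c0, h, w)
    return AnnotatedScene(m, dict(classes))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def small_scene_pair(seed, n_instances=8, image=112, dropout=0.2, jitter=0.7,
                     misclassification=0.1, spurious=1.0):
    """A small synthetic gt/pred pair for property tests."""
    pop = PopulationSpec(classes=TWO_CLASSES, n_instances=n_instances,
                         image_shape=(image, image))
    gt = generate_scene(pop, seed=seed)
    spec = DegradationSpec(dropout_rate=dropout, boundary_jitter_px=jitter,
                           misclassification_rate=misclassification,
                           spurious_rate=spurious)
    pred, _ = degrade(gt, spec, seed=seed + 10_000)
    return gt, pred
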