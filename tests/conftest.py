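import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from peelnet.model import FusionConfig, InteractionConfig, MultiStreamClassifier
from peelnet.nn.layers import BackboneConfig
from peelnet.synth import DEFAULT_CLASS_PROFILES, generate_peel_image


@pytest.fixture(scope="session")
def peel_samples():
    """One rendered specimen per class, fixed seeds."""
    return [
        generate_peel_image(prof, size=160, rng=np.random.default_rng(100 + i))
        for i, prof in enumerate(DEFAULT_CLASS_PROFILES)
    ]


@pytest.fixture(scope="session")
def micro_backbone():
    """Tiny four-stage backbone for gradient/determinism tests."""
    return BackboneConfig(
        widths=(2, 3, 4, 5), blocks=(1, 1, 1, 1), strides=(1, 2, 2, 2), bottleneck=False, input_size=16
    )


@pytest.fixture()
def micro_model(micro_backbone):
    return MultiStreamClassifier(
        backbone=micro_backbone,
        interaction=InteractionConfig(forward_ratio=0.4, reverse_ratio=0.34, stage=2, seed=3),
        fusion=FusionConfig(compress_dim=6, n_classes=4),
    )


@pytest.fixture()
def micro_batch():
    rng = np.random.default_rng(7)
    x = tuple(rng.normal(0, 1, (3, 3, 16, 16)).astype(np.float32) for _ in range(3))
    y = np.array([0, 1, 3])
    return x, y
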