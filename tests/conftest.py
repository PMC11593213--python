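import numpy as np
import pytest

from apnealite.archspec import ModelSpec, batchnorm, conv, dense, dropout, flatten, maxpool


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """A small mixed-conv model that exercises every layer kind."""
    return ModelSpec(
        name="tiny",
        input_length=32,
        input_channels=1,
        layers=(
            batchnorm(),
            conv("conv_dsc", kernel_size=5, filters=4, stride=2),
            maxpool(2),
            conv("conv_sc", kernel_size=3, filters=3),
            maxpool(2),
            flatten(),
            dropout(0.25),
            dense(2),
        ),
    )


def random_small_spec(rng: np.random.Generator) -> ModelSpec:
    """Draw a random valid small architecture (used by cross-route checks)."""
    layers = [batchnorm()] if rng.random() < 0.5 else []
    length = int(rng.integers(16, 64))
    cur = length
    for _ in range(int(rng.integers(1, 4))):
        kind = "conv_sc" if rng.random() < 0.5 else "conv_dsc"
        k = int(rng.integers(1, 8))
        stride = int(rng.integers(1, 3))
        padding = "same" if rng.random() < 0.8 or k > cur else "valid"
        layers.append(
            conv(kind, kernel_size=min(k, cur) if padding == "valid" else k,
                 filters=int(rng.integers(1, 7)), stride=stride, padding=padding)
        )
        cur = -(-cur // stride) if padding == "same" else (cur - min(k, cur)) // stride + 1
        if cur >= 2 and rng.random() < 0.5:
            layers.append(maxpool(2))
            cur = (cur - 2) // 2 + 1
    layers += [flatten(), dropout(float(rng.uniform(0, 0.5))), dense(2)]
    return ModelSpec(name="rand", input_length=length, input_channels=1,
                     layers=tuple(layers))
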