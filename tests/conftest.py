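import numpy as np
import pytest

from coarsefine import LayerConfig, Stack, StackConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20241)


@pytest.fixture
def tiny_stack():
    """Two small layers on an 8x8 input: 2x2 windows (7x7 cells, bank 2x3),
    then a 2x2 dilated window with gap 1 (5x5 cells, bank 2x2)."""
    config = StackConfig(
        input_size=(8, 8),
        layers=(
            LayerConfig((2, 2), (2, 3), 0.01, (0, 0)),
            LayerConfig((2, 2), (2, 2), 0.01, (1, 1)),
        ),
    )
    return Stack.create(config, seed=7)


@pytest.fixture
def one_layer_identity_stack():
    """Single layer of 1x1 kernels forming an identity bank: reconstruction
    inverts the forward pass exactly."""
    config = StackConfig(
        input_size=(4, 4),
        layers=(LayerConfig((1, 1), (1, 1), 0.0, (0, 0)),),
    )
    stack = Stack.create(config, seed=0)
    stack.weights[0] = np.ones((1, 1))
    return stack
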