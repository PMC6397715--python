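"""Hierarchy assembly: geometry derivation, output packing, cascades.

The default four-layer configuration processes a 36x36 grayscale image.
Layer 1 slides a 3x3 pixel window with stride 1, giving a 34x34 grid of
window positions ("cells"); its 3x12 filter bank's activations are packed
cell-by-cell into a 102x408 output matrix.  Higher layers slide dilated
windows over the lower cell grid (gaps 2, 5, 11 cells) so their windows
nominally cover 9, 18, and finally all 36 input pixels, with cell grids
28x28, 22x22 and 10x10.

Top-down reconstruction runs the cascade in reverse: an activation at the
top layer is mapped through each bank (``TD = I_TD W``) and scattered with
overlap-add down to a full image at the bottom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import layer as L
from .errors import ConfigurationError, GeometryError, ShapeError
from .geometry import LayerGeometry, window_geometry
from .layer import LayerConfig

__all__ = [
    "StackConfig",
    "Stack",
    "default_layer_configs",
    "default_config",
    "derive_geometry",
    "pack_output",
    "unpack_output",
    "forward_pass",
    "layer_activations",
    "reconstruct",
    "visualize_filter",
]


def default_layer_configs(n_layers: int = 4) -> tuple[LayerConfig, ...]:
    """The standard four-layer hyper-parameters (optionally truncated).

    Receptive fields (3,3), (3,3), (2,2), (2,2); banks (3,12), (10,20),
    (12,24), (8,16); learning rate 5e-4 throughout; dilation gaps 0, 2, 5,
    11 cells, which reproduce the cell-grid sides 34, 28, 22, 10.
    """
    full = (
        LayerConfig((3, 3), (3, 12), 0.0005, (0, 0)),
        LayerConfig((3, 3), (10, 20), 0.0005, (2, 2)),
        LayerConfig((2, 2), (12, 24), 0.0005, (5, 5)),
        LayerConfig((2, 2), (8, 16), 0.0005, (11, 11)),
    )
    if not 1 <= n_layers <= 4:
        raise ConfigurationError(f"default config has 1..4 layers, got {n_layers}")
    return full[:n_layers]


@dataclass(frozen=True)
class StackConfig:
    """Whole-hierarchy configuration."""

    input_size: tuple[int, int] = (36, 36)
    layers: tuple[LayerConfig, ...] = field(default_factory=default_layer_configs)
    n_bottom_up_streams: int = 2
    n_top_down_streams: int = 1

    def __post_init__(self) -> None:
        if min(self.input_size) <= 0:
            raise ConfigurationError(f"non-positive input size {self.input_size}")
        if not self.layers:
            raise ConfigurationError("at least one layer is required")
        if self.n_bottom_up_streams < 1 or self.n_top_down_streams < 0:
            raise ConfigurationError("need >= 1 bottom-up stream")


def default_config(n_layers: int = 4) -> StackConfig:
    return StackConfig(layers=default_layer_configs(n_layers))


def derive_geometry(config: StackConfig) -> list[LayerGeometry]:
    """Per-layer gather geometries, bottom-up.

    Layer 1 reads pixels (cell block 1x1, contiguous windows); layer l > 1
    reads the packed output of layer l-1, whose cells are that layer's
    bank-shaped blocks, gathering field-sized groups of cells separated by
    the configured dilation gap, stride 1 in cell units.  Nominal pixel
    coverage composes multiplicatively (3 -> 9 -> 18 -> 36 by default).
    """
    geoms: list[LayerGeometry] = []
    cell_grid = config.input_size
    cell_block = (1, 1)
    coverage = 1
    for idx, lc in enumerate(config.layers):
        coverage = coverage * lc.receptive_field[0] if idx > 0 else lc.receptive_field[0]
        try:
            geom = window_geometry(
                cell_grid,
                lc.receptive_field,
                cell_block=cell_block,
                gap=lc.dilation_gap,
                stride=lc.stride,
                pixel_coverage=coverage,
            )
        except GeometryError as err:
            raise GeometryError(f"layer {idx + 1}: {err}") from err
        geoms.append(geom)
        cell_grid = geom.grid
        cell_block = lc.bank_shape
    return geoms


def pack_output(
    activations: np.ndarray, geometry: LayerGeometry, bank_shape: tuple[int, int]
) -> np.ndarray:
    """Pack an ``(n, j)`` activation matrix into the 2-D output grid.

    Cell ``(r, c)`` holds a ``j_r x j_c`` block: activation of kernel
    ``(f_r, f_c)`` at window ``(r, c)`` lands at
    ``(r*j_r + f_r, c*j_c + f_c)``.  The layer-1 default yields 102x408.
    """
    activations = np.asarray(activations)
    n_r, n_c = geometry.grid
    j_r, j_c = bank_shape
    if activations.shape != (n_r * n_c, j_r * j_c):
        raise ShapeError(
            f"activations {activations.shape} != ({n_r * n_c}, {j_r * j_c})"
        )
    return (
        activations.reshape(n_r, n_c, j_r, j_c)
        .transpose(0, 2, 1, 3)
        .reshape(n_r * j_r, n_c * j_c)
    )


def unpack_output(
    packed: np.ndarray, geometry: LayerGeometry, bank_shape: tuple[int, int]
) -> np.ndarray:
    """Exact inverse of :func:`pack_output`."""
    packed = np.asarray(packed)
    n_r, n_c = geometry.grid
    j_r, j_c = bank_shape
    if packed.shape != (n_r * j_r, n_c * j_c):
        raise ShapeError(f"packed {packed.shape} != ({n_r * j_r}, {n_c * j_c})")
    return (
        packed.reshape(n_r, j_r, n_c, j_c)
        .transpose(0, 2, 1, 3)
        .reshape(n_r * n_c, j_r * j_c)
    )


@dataclass
class Stack:
    """A configured hierarchy with its geometries, masks and weights."""

    config: StackConfig
    geometries: list[LayerGeometry]
    masks: list[np.ndarray]
    weights: list[np.ndarray]

    @classmethod
    def create(cls, config: StackConfig, seed: int | np.random.Generator = 0) -> "Stack":
        """Build a stack with seeded small uniform random weights."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        geoms = derive_geometry(config)
        masks = [
            L.build_inhibition_mask(lc.bank_shape, lc.topology_variant)
            for lc in config.layers
        ]
        weights = [
            L.init_weights(lc.bank_shape, g.patch_length, rng)
            for lc, g in zip(config.layers, geoms)
        ]
        return cls(config, geoms, masks, weights)

    @property
    def n_layers(self) -> int:
        return len(self.config.layers)

    def copy(self) -> "Stack":
        return Stack(
            self.config,
            list(self.geometries),
            [m.copy() for m in self.masks],
            [w.copy() for w in self.weights],
        )


def layer_activations(
    stack: Stack, image: np.ndarray, up_to: int | None = None
) -> list[np.ndarray]:
    """Bottom-up activations ``(n, j)`` for layers 1..up_to of one image."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape != stack.config.input_size:
        raise ShapeError(
            f"image {image.shape} != configured input {stack.config.input_size}"
        )
    up_to = stack.n_layers if up_to is None else up_to
    acts: list[np.ndarray] = []
    source = image
    for idx in range(up_to):
        geom = stack.geometries[idx]
        patches = L.im2row(source, geom)
        a = L.forward(patches, stack.weights[idx])
        acts.append(a)
        source = pack_output(a, geom, stack.config.layers[idx].bank_shape)
    return acts


def forward_pass(stack: Stack, images: list[np.ndarray]) -> list[list[np.ndarray]]:
    """Cascade every bottom-up stream; returns packed grids per stream per layer."""
    if len(images) != stack.config.n_bottom_up_streams:
        raise ShapeError(
            f"expected {stack.config.n_bottom_up_streams} images, got {len(images)}"
        )
    out: list[list[np.ndarray]] = []
    for img in images:
        acts = layer_activations(stack, img)
        out.append(
            [
                pack_output(a, g, lc.bank_shape)
                for a, g, lc in zip(acts, stack.geometries, stack.config.layers)
            ]
        )
    return out


def reconstruct(
    stack: Stack,
    top_activation: np.ndarray,
    layer_index: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cascade an activation top-down into an image.

    ``top_activation`` may be the ``(n, j)`` activation matrix of layer
    ``layer_index`` (1-based; default: the top layer) or its packed 2-D
    output-grid form.  At each stage the activation is mapped through the
    bank (``TD = I_TD W``) and the resulting patch rows are scattered with
    overlap-add onto the lower grid, which becomes the next top-down
    activation.  Returns ``(image, counts)`` where ``counts`` is the
    bottom-stage per-pixel overlap multiplicity (for optional
    normalization); the raw image keeps the plain sums.
    """
    layer_index = stack.n_layers if layer_index is None else layer_index
    if not 1 <= layer_index <= stack.n_layers:
        raise ShapeError(f"layer index {layer_index} outside 1..{stack.n_layers}")
    geom = stack.geometries[layer_index - 1]
    lc = stack.config.layers[layer_index - 1]
    act = np.asarray(top_activation, dtype=np.float64)
    n, j = geom.n, lc.n_kernels
    if act.shape == (geom.grid[0] * lc.bank_shape[0], geom.grid[1] * lc.bank_shape[1]):
        act = unpack_output(act, geom, lc.bank_shape)
    if act.shape != (n, j):
        raise ShapeError(
            f"layer {layer_index}: top-down activation {act.shape} is neither "
            f"({n}, {j}) nor its packed form"
        )
    counts = np.ones(1)
    for idx in range(layer_index - 1, -1, -1):
        geom = stack.geometries[idx]
        try:
            rows = L.topdown(act, stack.weights[idx])
            grid, counts = L.row2im(rows, geom)
        except ShapeError as err:
            raise ShapeError(f"layer {idx + 1}: {err}") from err
        if idx > 0:
            act = unpack_output(
                grid, stack.geometries[idx - 1], stack.config.layers[idx - 1].bank_shape
            )
        else:
            return grid, counts
    raise AssertionError("unreachable")


def visualize_filter(
    stack: Stack, layer_index: int, kernel_index: int
) -> np.ndarray:
    """Regenerate the image patch a single kernel stands for.

    Activates kernel ``kernel_index`` (row-major, 0-based) with unit
    strength at the top-left window of layer ``layer_index`` (1-based),
    cascades it down with :func:`reconstruct`, and returns the crop of the
    layer's nominal pixel coverage.  For layer 1 this is exactly the 2-D
    kernel itself.
    """
    if not 1 <= layer_index <= stack.n_layers:
        raise ShapeError(f"layer index {layer_index} outside 1..{stack.n_layers}")
    geom = stack.geometries[layer_index - 1]
    lc = stack.config.layers[layer_index - 1]
    if not 0 <= kernel_index < lc.n_kernels:
        raise ShapeError(
            f"kernel index {kernel_index} outside 0..{lc.n_kernels - 1}"
        )
    act = np.zeros((geom.n, lc.n_kernels))
    act[0, kernel_index] = 1.0
    image, _ = reconstruct(stack, act, layer_index)
    side = min(geom.pixel_coverage, *stack.config.input_size)
    return image[:side, :side]
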