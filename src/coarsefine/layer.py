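"""Single-layer mathematics: cumulative inhibition and the weight update.

One layer owns a *filter bank* ``W`` of shape ``(j, i)`` — ``j`` learnable
kernels of length ``i``, arranged conceptually in a 2-D bank of shape
``(j_r, j_c)`` with kernel ``k`` at bank position ``(k // j_c, k % j_c)``.

The bank carries a fixed *inhibition topology*: a binary ``(j, j)`` mask
``M`` with ``M[a, b] = 1`` meaning kernel ``a`` inhibits kernel ``b``.
In the default ("printed") topology a kernel inhibits every kernel in its
own bank row or below, so inhibitive pressure accumulates down the rows.
A kernel's learning signal is the input patch minus the reconstruction
built from its inhibitors only (the *inhibition buffer*), which forces
late rows to encode the residual, finer structure the early rows miss —
an anti-Hebbian deflation scheme that reduces to Sanger's generalized
Hebbian rule for a single-column bank with strict raster ordering.

All maps are linear: activation ``A = I W^T``, top-down synthesis
``TD = I_TD W``.  No nonlinearity, bias, or normalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, NumericError, ShapeError
from .geometry import LayerGeometry

__all__ = [
    "LayerConfig",
    "build_inhibition_mask",
    "init_weights",
    "im2row",
    "row2im",
    "forward",
    "topdown",
    "inhibition_buffer",
    "naive_inhibition_buffer",
    "weight_delta",
    "naive_weight_delta",
    "apply_update",
]

TOPOLOGIES = ("printed", "strict_raster")


@dataclass(frozen=True)
class LayerConfig:
    """Hyper-parameters of one layer.

    Parameters
    ----------
    receptive_field:
        Window extent in lower-grid cells (pixels for the first layer).
    bank_shape:
        ``(j_r, j_c)`` kernels in the filter bank.
    learning_rate:
        Scalar step size for the weight update (dimensionless).
    dilation_gap:
        Cells skipped between consecutive gathered cells of a window.
    stride:
        Cells between consecutive window positions.
    topology_variant:
        ``"printed"`` (bank-row cumulative, the default) or
        ``"strict_raster"`` (cumulative in row-major kernel order).
    """

    receptive_field: tuple[int, int]
    bank_shape: tuple[int, int]
    learning_rate: float = 0.0005
    dilation_gap: tuple[int, int] = (0, 0)
    stride: int = 1
    topology_variant: str = "printed"

    def __post_init__(self) -> None:
        if min(self.receptive_field) <= 0 or min(self.bank_shape) <= 0:
            raise ConfigurationError(
                f"non-positive extents: field={self.receptive_field}, "
                f"bank={self.bank_shape}"
            )
        if self.stride <= 0 or min(self.dilation_gap) < 0:
            raise ConfigurationError(
                f"invalid stride {self.stride} or gap {self.dilation_gap}"
            )
        if not (np.isfinite(self.learning_rate) and self.learning_rate >= 0):
            raise ConfigurationError(f"learning rate must be >= 0, got {self.learning_rate}")
        if self.topology_variant not in TOPOLOGIES:
            raise ConfigurationError(
                f"unknown topology {self.topology_variant!r}; expected one of {TOPOLOGIES}"
            )

    @property
    def n_kernels(self) -> int:
        return self.bank_shape[0] * self.bank_shape[1]


def build_inhibition_mask(
    bank_shape: tuple[int, int], topology_variant: str = "printed"
) -> np.ndarray:
    """Binary ``(j, j)`` mask; entry ``(a, b) = 1`` iff kernel a inhibits b.

    ``printed``: a inhibits b iff bank-row(a) <= bank-row(b); column order
    within a row is irrelevant, every kernel self-inhibits.
    ``strict_raster``: a inhibits b iff a <= b in row-major kernel order.
    """
    j_r, j_c = bank_shape
    if j_r <= 0 or j_c <= 0:
        raise ConfigurationError(f"non-positive bank shape {bank_shape}")
    if topology_variant not in TOPOLOGIES:
        raise ConfigurationError(f"unknown topology {topology_variant!r}")
    k = np.arange(j_r * j_c)
    if topology_variant == "printed":
        row = k // j_c
        mask = row[:, None] <= row[None, :]
    else:
        mask = k[:, None] <= k[None, :]
    return mask.astype(np.float64)


def init_weights(
    bank_shape: tuple[int, int],
    patch_length: int,
    rng: np.random.Generator,
    scale: float = 0.01,
) -> np.ndarray:
    """Uniform random bank in ``[-scale, scale]``, shape ``(j, i)``.

    A small symmetric start keeps early activations and inhibition buffers
    small while breaking the symmetry between kernels.
    """
    j = bank_shape[0] * bank_shape[1]
    return rng.uniform(-scale, scale, size=(j, patch_length))


def im2row(source_grid: np.ndarray, geometry: LayerGeometry) -> np.ndarray:
    """Gather sliding-window patches into rows: ``(n, i)``.

    Row ``p`` is window ``p`` (row-major window order) flattened row-major
    over (cell-row, cell-col, within-cell-row, within-cell-col).
    """
    source_grid = np.asarray(source_grid)
    if source_grid.shape != geometry.source_shape:
        raise ShapeError(
            f"source grid {source_grid.shape} does not match geometry "
            f"source shape {geometry.source_shape}"
        )
    return source_grid.reshape(-1)[geometry.indices]


def row2im(patch_rows: np.ndarray, geometry: LayerGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Overlap-add scatter: the adjoint of :func:`im2row`.

    Every patch entry is *summed* into the source-grid position it was
    gathered from.  Returns ``(grid, counts)`` where ``counts`` holds the
    number of windows covering each element, so callers may normalize.
    """
    patch_rows = np.asarray(patch_rows)
    if patch_rows.shape != geometry.indices.shape:
        raise ShapeError(
            f"patch rows {patch_rows.shape} do not match geometry "
            f"{geometry.indices.shape}"
        )
    size = geometry.source_shape[0] * geometry.source_shape[1]
    flat_idx = geometry.indices.reshape(-1)
    grid = np.bincount(flat_idx, weights=patch_rows.reshape(-1).astype(np.float64), minlength=size)
    counts = np.bincount(flat_idx, minlength=size)
    return grid.reshape(geometry.source_shape), counts.reshape(geometry.source_shape)


def _check_2d(name: str, a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2:
        raise ShapeError(f"{name} must be 2-D, got shape {a.shape}")
    return a


def forward(patches: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Bottom-up activation ``A = I W^T``; shape ``(n, j)``.

    Pure dot-product activation of every kernel on every patch.
    """
    patches = _check_2d("patches", patches)
    weights = _check_2d("weights", weights)
    if patches.shape[1] != weights.shape[1]:
        raise ShapeError(
            f"patch length {patches.shape[1]} != kernel length {weights.shape[1]}"
        )
    return patches @ weights.T


def topdown(topdown_activation: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Top-down synthesis ``TD = I_TD W``; shape ``(n, i)``.

    Each output row is the linear combination of kernels weighted by the
    activation row; a unit one-hot at kernel ``k`` returns ``w_k`` exactly,
    which is the filter-imaging primitive.
    """
    topdown_activation = _check_2d("topdown_activation", topdown_activation)
    weights = _check_2d("weights", weights)
    if topdown_activation.shape[1] != weights.shape[0]:
        raise ShapeError(
            f"activation width {topdown_activation.shape[1]} != kernel count "
            f"{weights.shape[0]}"
        )
    return topdown_activation @ weights


def _check_update_shapes(
    activations: np.ndarray, weights: np.ndarray, mask: np.ndarray
) -> None:
    j = weights.shape[0]
    if mask.shape != (j, j):
        raise ShapeError(f"mask {mask.shape} must be ({j}, {j})")
    if activations.shape[1] != j:
        raise ShapeError(
            f"activation width {activations.shape[1]} != kernel count {j}"
        )


def inhibition_buffer(
    activations: np.ndarray, weights: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Per-patch, per-target reconstruction from inhibitors only.

    Returns ``(n, j*i)``; the slice ``[p, t*i:(t+1)*i]`` is
    ``sum_s M[s, t] * A[p, s] * w_s`` — what kernel ``t``'s inhibitors
    jointly reconstruct of patch ``p``.  Vectorized with einsum; the
    reference semantics live in :func:`naive_inhibition_buffer`.
    """
    activations = _check_2d("activations", activations)
    weights = _check_2d("weights", weights)
    mask = _check_2d("mask", mask)
    _check_update_shapes(activations, weights, mask)
    n = activations.shape[0]
    j, i = weights.shape
    buf = np.einsum("st,ps,si->pti", mask, activations, weights, optimize=True)
    return buf.reshape(n, j * i)


def naive_inhibition_buffer(
    activations: np.ndarray, weights: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Triple-loop oracle for :func:`inhibition_buffer` (small inputs only)."""
    activations = np.asarray(activations, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    n = activations.shape[0]
    j, i = weights.shape
    buf = np.zeros((n, j * i))
    for p in range(n):
        for t in range(j):
            acc = np.zeros(i)
            for s in range(j):
                acc += mask[s, t] * activations[p, s] * weights[s]
            buf[p, t * i : (t + 1) * i] = acc
    return buf


def weight_delta(
    patches: np.ndarray,
    activations: np.ndarray,
    weights: np.ndarray,
    mask: np.ndarray,
    learning_rate: float,
) -> np.ndarray:
    """Anti-Hebbian weight update ``(j, i)``.

    For target kernel ``t``::

        delta[t] = lr * sum_p A[p, t] * (I[p] - IB[p, t])

    where ``IB[p, t]`` is the inhibition-buffer slice.  Computed in the
    algebraically identical factored form

        delta = lr * (A^T I  -  (M^T . A^T A) W)

    (``.`` elementwise) which avoids materializing the ``n x j*i`` buffer;
    equivalence with :func:`naive_weight_delta` is asserted in the tests.
    """
    patches = _check_2d("patches", patches)
    activations = _check_2d("activations", activations)
    weights = _check_2d("weights", weights)
    mask = _check_2d("mask", mask)
    _check_update_shapes(activations, weights, mask)
    if patches.shape != (activations.shape[0], weights.shape[1]):
        raise ShapeError(
            f"patches {patches.shape} inconsistent with activations "
            f"{activations.shape} and weights {weights.shape}"
        )
    if not np.isfinite(learning_rate):
        raise ConfigurationError(f"learning rate must be finite, got {learning_rate}")
    if learning_rate == 0.0:
        return np.zeros_like(weights)
    hebb = activations.T @ patches                      # (j, i)
    gram = activations.T @ activations                  # (j, j) C[t, s]
    inhib = (mask.T * gram) @ weights                   # (j, i)
    return learning_rate * (hebb - inhib)


def naive_weight_delta(
    patches: np.ndarray,
    activations: np.ndarray,
    weights: np.ndarray,
    mask: np.ndarray,
    learning_rate: float,
) -> np.ndarray:
    """Loop oracle for :func:`weight_delta` via the explicit buffer."""
    patches = np.asarray(patches, dtype=np.float64)
    activations = np.asarray(activations, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    buf = naive_inhibition_buffer(activations, weights, mask)
    n = activations.shape[0]
    j, i = weights.shape
    delta = np.zeros((j, i))
    for t in range(j):
        for p in range(n):
            delta[t] += activations[p, t] * (patches[p] - buf[p, t * i : (t + 1) * i])
    return learning_rate * delta


def apply_update(
    weights: np.ndarray, delta: np.ndarray, clip: float | None = None
) -> np.ndarray:
    """Return ``W + delta`` (a new array; inputs untouched).

    No renormalization or decay is applied, matching the purely linear
    scheme; ``clip`` optionally bounds the resulting entry magnitudes as a
    divergence guard (off by default).
    """
    weights = _check_2d("weights", weights)
    delta = _check_2d("delta", delta)
    if weights.shape != delta.shape:
        raise ShapeError(f"weights {weights.shape} != delta {delta.shape}")
    out = weights + delta
    if not np.all(np.isfinite(out)):
        bad = int(np.count_nonzero(~np.isfinite(out)))
        raise NumericError(
            f"{bad} non-finite weight entries after update; "
            "reduce the learning rate or enable clipping"
        )
    if clip is not None:
        np.clip(out, -clip, clip, out=out)
    return out
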