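"""Sliding-window geometry with dilation over cell grids.

A layer reads a *source grid*: for the first layer this is the raw image
(each "cell" is a single pixel); for higher layers it is the packed output
of the layer below, where each cell is a ``b_r x b_c`` block holding the
lower filter bank's activations at one window position.

A window gathers ``field_r x field_c`` cells.  Consecutive gathered cells
may be separated by a *dilation gap* of skipped cells, so the cell-space
step between gathered cells is ``gap + 1``.  Windows slide with a stride
(in cells) over the lower grid.  Each gathered patch is flattened row-major
over (cell-row, cell-col, within-cell-row, within-cell-col).

All coordinates are 0-based; windows are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GeometryError

__all__ = ["LayerGeometry", "window_geometry"]


@dataclass(frozen=True)
class LayerGeometry:
    """Immutable description of one layer's patch-gathering geometry.

    Attributes
    ----------
    grid:
        ``(n_r, n_c)`` number of window positions along each axis.
    cell_block:
        ``(b_r, b_c)`` elements per lower-grid cell (``(1, 1)`` for pixels).
    cell_grid:
        ``(C_r, C_c)`` number of cells in the source grid.
    source_shape:
        Shape of the 2-D source array: ``(C_r * b_r, C_c * b_c)``.
    indices:
        ``(n, i)`` int array; row ``p`` holds the flat indices into the
        raveled source gathered by window ``p`` (row-major window order).
    pixel_coverage:
        Nominal side length, in input pixels, of the image region one
        window represents.
    element_gap:
        ``(gap_r * b_r, gap_c * b_c)`` — the dilation gap expressed in
        source-grid *elements* rather than cells.
    cell_span:
        Extent of one window in cells along each axis, dilation included.
    """

    grid: tuple[int, int]
    cell_block: tuple[int, int]
    cell_grid: tuple[int, int]
    source_shape: tuple[int, int]
    indices: np.ndarray = field(repr=False)
    pixel_coverage: int
    element_gap: tuple[int, int]
    cell_span: tuple[int, int]

    @property
    def n(self) -> int:
        """Number of windows (rows of the patch matrix)."""
        return self.grid[0] * self.grid[1]

    @property
    def patch_length(self) -> int:
        """Flattened patch length i."""
        return self.indices.shape[1]


def window_geometry(
    cell_grid: tuple[int, int],
    field_shape: tuple[int, int],
    *,
    cell_block: tuple[int, int] = (1, 1),
    gap: tuple[int, int] = (0, 0),
    stride: int = 1,
    pixel_coverage: int | None = None,
) -> LayerGeometry:
    """Build the gather geometry for one layer.

    Parameters
    ----------
    cell_grid:
        ``(C_r, C_c)`` cells available in the source grid.
    field_shape:
        ``(f_r, f_c)`` cells gathered per window (the receptive field in
        lower-grid cells).
    cell_block:
        Elements per cell in the packed source.
    gap:
        Cells skipped between consecutive gathered cells of a window.
    stride:
        Cells between consecutive window positions.
    pixel_coverage:
        Nominal input-pixel coverage to record; defaults to ``f_r`` (which
        is exact only when cells are pixels).

    Raises
    ------
    ConfigurationError
        For non-positive extents.
    GeometryError
        If the dilated window does not fit inside the source grid.
    """
    C_r, C_c = cell_grid
    f_r, f_c = field_shape
    b_r, b_c = cell_block
    g_r, g_c = gap
    if min(C_r, C_c, f_r, f_c, b_r, b_c, stride) <= 0 or min(g_r, g_c) < 0:
        raise ConfigurationError(
            f"non-positive geometry extents: cells={cell_grid}, field={field_shape}, "
            f"block={cell_block}, gap={gap}, stride={stride}"
        )
    step_r, step_c = g_r + 1, g_c + 1
    span_r = (f_r - 1) * step_r + 1
    span_c = (f_c - 1) * step_c + 1
    if span_r > C_r or span_c > C_c:
        raise GeometryError(
            f"window span {span_r}x{span_c} (field {f_r}x{f_c}, gap {g_r}x{g_c}) "
            f"exceeds source cell grid {C_r}x{C_c}"
        )
    n_r = (C_r - span_r) // stride + 1
    n_c = (C_c - span_c) // stride + 1
    src_cols = C_c * b_c

    # Flat source index of element (cell_row*b_r+u, cell_col*b_c+v).
    cell_rows = (
        (stride * np.arange(n_r))[:, None] + (step_r * np.arange(f_r))[None, :]
    )  # (n_r, f_r)
    cell_cols = (
        (stride * np.arange(n_c))[:, None] + (step_c * np.arange(f_c))[None, :]
    )  # (n_c, f_c)
    rows = cell_rows[:, :, None] * b_r + np.arange(b_r)[None, None, :]  # (n_r, f_r, b_r)
    cols = cell_cols[:, :, None] * b_c + np.arange(b_c)[None, None, :]  # (n_c, f_c, b_c)

    flat = (
        rows[:, None, :, None, :, None] * src_cols
        + cols[None, :, None, :, None, :]
    )  # (n_r, n_c, f_r, f_c, b_r, b_c): row-major patch order (a, b, u, v)
    indices = np.ascontiguousarray(
        flat.reshape(n_r * n_c, f_r * f_c * b_r * b_c)
    )

    return LayerGeometry(
        grid=(n_r, n_c),
        cell_block=(b_r, b_c),
        cell_grid=(C_r, C_c),
        source_shape=(C_r * b_r, C_c * b_c),
        indices=indices,
        pixel_coverage=f_r if pixel_coverage is None else pixel_coverage,
        element_gap=(g_r * b_r, g_c * b_c),
        cell_span=(span_r, span_c),
    )
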