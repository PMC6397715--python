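"""Spectral and visual characterization of trained filter banks.

The coarse-to-fine claim is quantified spectrally: each kernel's image is
regenerated top-down, its radially averaged 2-D power spectrum computed,
and spectra averaged within each bank row.  If cumulative inhibition
works as intended, later (more inhibited) rows carry more power at high
spatial frequency, so the power-weighted mean frequency (spectral
centroid) increases with bank-row index.

Frequencies are reported in cycles per regenerated patch side (the
receptive field), making rows comparable across layers of different
coverage.  Power is normalized so that the total over all bins equals the
image's squared norm (Parseval), and converted to dB relative to the
profile maximum for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ShapeError
from .stack import Stack, visualize_filter

__all__ = [
    "RadialSpectrum",
    "SpectrumProfile",
    "image_spectrum",
    "spectral_centroid",
    "row_power_spectrum",
    "smooth_trace",
    "render_filters",
    "snapshot_reconstruction",
]


@dataclass(frozen=True)
class RadialSpectrum:
    """Radially averaged periodogram of one image.

    ``frequency``: ring index in cycles per image side (0 = DC).
    ``power``: mean power per bin in the ring, normalized so that
    ``sum(power * count)`` equals the image's squared norm.
    ``count``: number of 2-D frequency bins in each ring.
    """

    frequency: np.ndarray
    power: np.ndarray
    count: np.ndarray

    @property
    def power_db(self) -> np.ndarray:
        """Power relative to the profile maximum, in dB (floor -300 dB)."""
        ref = self.power.max()
        if ref <= 0:
            return np.full_like(self.power, -300.0)
        with np.errstate(divide="ignore"):
            db = 10.0 * np.log10(self.power / ref)
        return np.maximum(db, -300.0)


def image_spectrum(image: np.ndarray) -> RadialSpectrum:
    """Radially averaged power spectrum of a 2-D image.

    The 2-D periodogram ``|F|^2 / N`` (so its total equals ``sum x^2``)
    is binned by the integer-rounded radial frequency in cycles per image
    side.  A constant image puts all power in the DC ring.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ShapeError(f"expected a non-empty 2-D image, got shape {image.shape}")
    h, w = image.shape
    power2d = np.abs(np.fft.fft2(image)) ** 2 / (h * w)
    fy = np.fft.fftfreq(h)[:, None] * min(h, w)
    fx = np.fft.fftfreq(w)[None, :] * min(h, w)
    ring = np.rint(np.hypot(fy, fx)).astype(int)
    n_rings = ring.max() + 1
    count = np.bincount(ring.ravel(), minlength=n_rings)
    total = np.bincount(ring.ravel(), weights=power2d.ravel(), minlength=n_rings)
    power = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return RadialSpectrum(
        frequency=np.arange(n_rings, dtype=np.float64), power=power, count=count
    )


def spectral_centroid(spectrum: RadialSpectrum, include_dc: bool = True) -> float:
    """Power-weighted mean frequency of a radial spectrum.

    Ring power is weighted by its bin count so the centroid matches the
    2-D periodogram's mass distribution.
    """
    w = spectrum.power * spectrum.count
    f = spectrum.frequency
    if not include_dc:
        w, f = w[1:], f[1:]
    total = w.sum()
    if total <= 0:
        return 0.0
    return float((f * w).sum() / total)


@dataclass(frozen=True)
class SpectrumProfile:
    """Per-bank-row average spectrum of regenerated filter images.

    ``frequency`` is in cycles per receptive-field patch; ``power_db`` has
    one row per bank row, referenced to the profile's maximum power.
    """

    frequency: np.ndarray
    power: np.ndarray      # (j_r, n_rings) linear, Parseval-normalized
    power_db: np.ndarray   # (j_r, n_rings)
    centroids: np.ndarray  # (j_r,)


def row_power_spectrum(stack: Stack, layer_index: int) -> SpectrumProfile:
    """Average power spectrum of each bank row's regenerated filters.

    Every kernel of layer ``layer_index`` (1-based) is imaged with
    :func:`coarsefine.stack.visualize_filter`; spectra are averaged over
    the kernels of each bank row.  All-zero (untrained) banks yield zero
    power with a warning.
    """
    lc = stack.config.layers[layer_index - 1]
    j_r, j_c = lc.bank_shape
    rows_power = []
    freq = None
    for r in range(j_r):
        spectra = []
        for c in range(j_c):
            img = visualize_filter(stack, layer_index, r * j_c + c)
            sp = image_spectrum(img)
            spectra.append(sp)
            freq = sp.frequency
        rows_power.append(np.mean([sp.power for sp in spectra], axis=0))
    power = np.asarray(rows_power)
    counts = spectra[-1].count
    if power.max() <= 0:
        warnings.warn(f"layer {layer_index}: all-zero filter spectra (untrained bank?)")
        db = np.full_like(power, -300.0)
        cents = np.zeros(j_r)
    else:
        ref = power.max()
        with np.errstate(divide="ignore"):
            db = np.maximum(10.0 * np.log10(np.where(power > 0, power, np.nan) / ref), -300.0)
        db = np.nan_to_num(db, nan=-300.0)
        cents = np.array(
            [
                spectral_centroid(RadialSpectrum(freq, p, counts))
                for p in power
            ]
        )
    return SpectrumProfile(frequency=freq, power=power, power_db=db, centroids=cents)


def smooth_trace(
    values: np.ndarray, window_fraction: float = 0.2
) -> np.ndarray:
    """Locally weighted regression (LOWESS) smoothing of a 1-D trace.

    ``window_fraction`` is the fraction of the data used per local fit;
    windows larger than the trace are clamped with a warning.  The
    smoothed curve is evaluated at the original sample positions, so a
    constant trace is returned unchanged.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1 or values.size == 0:
        raise ShapeError(f"expected a non-empty 1-D trace, got shape {values.shape}")
    if not 0 < window_fraction:
        raise ValueError(f"window fraction must be > 0, got {window_fraction}")
    if window_fraction > 1:
        warnings.warn(f"window fraction {window_fraction} clamped to 1.0")
        window_fraction = 1.0
    if values.size < 3:
        return values.copy()
    x = np.arange(values.size, dtype=np.float64)
    return lowess(values, x, frac=window_fraction, return_sorted=False)


def render_filters(
    stack: Stack, layer_index: int, pad: int = 1
) -> np.ndarray:
    """Mosaic of a layer's regenerated filter images in bank layout.

    Bank rows map to mosaic rows (coarse rows on top); each tile is
    min-max normalized independently so every kernel's structure is
    visible regardless of its magnitude.
    """
    lc = stack.config.layers[layer_index - 1]
    j_r, j_c = lc.bank_shape
    tiles = [
        visualize_filter(stack, layer_index, k) for k in range(j_r * j_c)
    ]
    th, tw = tiles[0].shape
    mosaic = np.zeros((j_r * (th + pad) - pad, j_c * (tw + pad) - pad))
    for k, tile in enumerate(tiles):
        lo, hi = tile.min(), tile.max()
        norm = (tile - lo) / (hi - lo) if hi > lo else np.zeros_like(tile)
        r, c = divmod(k, j_c)
        mosaic[r * (th + pad) : r * (th + pad) + th, c * (tw + pad) : c * (tw + pad) + tw] = norm
    return mosaic


def snapshot_reconstruction(
    stack: Stack,
    stream_source,
    iterations: list[int],
    **train_kwargs,
) -> dict[int, np.ndarray]:
    """Train a copy of ``stack`` and capture reconstructions of the
    constant stream at the requested iterations.

    Thin wrapper over :func:`coarsefine.training.train_layerwise` using its
    sampling callback; iterations not on the sampling cadence are captured
    at the nearest later sample.
    """
    from .training import train_layerwise

    wanted = sorted(set(int(i) for i in iterations))
    shots: dict[int, np.ndarray] = {}

    def callback(t: int, _stack: Stack, recon: np.ndarray) -> None:
        for target in wanted:
            if target not in shots and t >= target:
                shots[target] = recon.copy()

    train_layerwise(stack.copy(), stream_source, callback=callback, **train_kwargs)
    return shots
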