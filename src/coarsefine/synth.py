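"""Seeded synthetic image streams for training and testing.

The training regime pairs a *variable* stream (a fresh image every
iteration, standing in for a natural-image dataset) with one *constant*
target image whose reconstruction is tracked over time.  Pink noise
(power spectral density falling as ``1/f^beta``) emulates the roughly
log-linear spatial-frequency spectrum of natural images; gratings and
Gaussian-blob scenes provide controlled fixtures.  Every generator is a
pure function of its parameters and seed, so any image in a stream can be
replayed exactly.

All images are float64 in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .errors import ConfigurationError, ShapeError

__all__ = [
    "pink_noise_image",
    "grating_image",
    "blob_scene",
    "StreamPair",
    "stream_pair",
    "load_cifar_batch",
    "load_cifar_stream",
]

DEFAULT_SIZE = (36, 36)


def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi - lo == 0:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def pink_noise_image(
    size: tuple[int, int] = DEFAULT_SIZE,
    beta: float = 2.0,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Random-phase noise with amplitude spectrum proportional to f^(-beta/2).

    Synthesized in the frequency domain: complex Gaussian coefficients are
    shaped by the radial-frequency envelope, inverse transformed and
    min-max rescaled to [0, 1].  The radially averaged log power falls
    close to linearly with log frequency with slope ``-beta``; ``beta = 2``
    approximates natural-image statistics, ``beta -> 0`` is white noise.
    """
    h, w = size
    if h < 2 or w < 2:
        raise ConfigurationError(f"degenerate image size {size}")
    if beta < 0:
        raise ConfigurationError(f"spectral exponent must be >= 0, got {beta}")
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.rfftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    envelope = np.zeros_like(f)
    nonzero = f > 0
    envelope[nonzero] = f[nonzero] ** (-beta / 2.0)
    coeff = rng.normal(size=f.shape) + 1j * rng.normal(size=f.shape)
    img = np.fft.irfft2(coeff * envelope, s=size)
    return _minmax(img)


def grating_image(
    size: tuple[int, int] = DEFAULT_SIZE,
    frequency: float = 4.0,
    orientation: float = 0.0,
    phase: float = 0.0,
) -> np.ndarray:
    """Sinusoidal grating, ``frequency`` in cycles per image side.

    ``sin(2 pi f (x cos t + y sin t) / N + phase)`` rescaled to [0, 1];
    orientation 0 varies along columns only (identical rows).  Frequencies
    at or above Nyquist (N/2 cycles) are rejected as aliased.
    """
    h, w = size
    n = min(h, w)
    if frequency < 0 or frequency >= n / 2:
        raise ConfigurationError(
            f"frequency {frequency} outside [0, Nyquist={n / 2}) for size {size}"
        )
    if frequency == 0:
        return np.full(size, 0.5 * (np.sin(phase) + 1.0))
    y, x = np.mgrid[0:h, 0:w]
    arg = 2 * np.pi * frequency * (x * np.cos(orientation) + y * np.sin(orientation)) / n
    return 0.5 * (np.sin(arg + phase) + 1.0)


def blob_scene(
    size: tuple[int, int] = DEFAULT_SIZE,
    n_blobs: int = 6,
    width: float = 3.0,
    seed: int | np.random.SeedSequence = 0,
    centers: list[tuple[float, float]] | None = None,
) -> np.ndarray:
    """Sum of Gaussian bumps, clipped to [0, 1].

    Centers and amplitudes are drawn from the seeded generator unless
    ``centers`` is given explicitly (amplitude 1 each).  ``n_blobs = 0``
    yields a blank image.
    """
    h, w = size
    if n_blobs < 0 or width <= 0:
        raise ConfigurationError(f"invalid blob count {n_blobs} or width {width}")
    rng = np.random.default_rng(seed)
    img = np.zeros(size)
    if centers is None:
        centers = [(rng.uniform(0, h - 1), rng.uniform(0, w - 1)) for _ in range(n_blobs)]
        amps = rng.uniform(0.5, 1.0, size=len(centers))
    else:
        amps = np.ones(len(centers))
    y, x = np.mgrid[0:h, 0:w]
    for (cy, cx), a in zip(centers, amps):
        img += a * np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2 * width**2))
    return np.clip(img, 0.0, 1.0)


@dataclass(frozen=True)
class StreamPair:
    """A variable image stream plus one constant target image.

    ``image(k)`` returns iteration ``k``'s fresh variable image, derived
    deterministically from (seed, k), so the stream is replayable without
    storing it.  ``constant`` never changes.
    """

    constant: np.ndarray
    _variable: Callable[[int], np.ndarray]
    n_iterations: int

    def image(self, iteration: int) -> np.ndarray:
        return self._variable(iteration)

    def streams(self, iteration: int) -> list[np.ndarray]:
        """Per-stream images for one iteration: [variable, constant]."""
        return [self.image(iteration), self.constant]


def stream_pair(
    n_iterations: int,
    size: tuple[int, int] = DEFAULT_SIZE,
    kind: str = "pink_noise",
    seed: int = 0,
    beta: float = 2.0,
) -> StreamPair:
    """Build the two-stream training input: fresh pink-noise (or blob)
    images each iteration plus one constant image of the same kind.

    Iteration ``k``'s variable image uses a child seed spawned from
    ``(seed, k)``; the constant image uses ``(seed, "constant")`` — i.e.
    a distinct deterministic child.
    """
    if kind not in ("pink_noise", "blobs"):
        raise ConfigurationError(f"unknown stream kind {kind!r}")

    def make(child_seed: np.random.SeedSequence) -> np.ndarray:
        if kind == "pink_noise":
            return pink_noise_image(size, beta=beta, seed=child_seed)
        return blob_scene(size, seed=child_seed)

    constant = make(np.random.SeedSequence(entropy=seed, spawn_key=(0xC0,)))

    def variable(k: int) -> np.ndarray:
        return make(np.random.SeedSequence(entropy=seed, spawn_key=(1, k)))

    return StreamPair(constant=constant, _variable=variable, n_iterations=n_iterations)


# --- CIFAR-10 binary batches (optional, never required by tests) ---------

_CIFAR_RECORD = 3073  # 1 label byte + 3 * 1024 channel bytes
_LUMA = (0.299, 0.587, 0.114)


def load_cifar_batch(path: str | Path) -> np.ndarray:
    """Read one CIFAR-10 binary batch into grayscale images in [0, 1].

    Returns ``(N, 32, 32)`` float64 (luminance conversion 0.299/0.587/0.114).
    Raises ``IOError`` for a missing or malformed file.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"CIFAR batch not found: {path}")
    raw = np.fromfile(path, dtype=np.uint8)
    if raw.size == 0 or raw.size % _CIFAR_RECORD != 0:
        raise IOError(
            f"corrupt CIFAR batch {path}: {raw.size} bytes is not a multiple "
            f"of the {_CIFAR_RECORD}-byte record"
        )
    records = raw.reshape(-1, _CIFAR_RECORD)
    rgb = records[:, 1:].reshape(-1, 3, 32, 32).astype(np.float64) / 255.0
    return np.tensordot(np.asarray(_LUMA), rgb, axes=(0, 1))


def load_cifar_stream(
    path: str | Path,
    size: tuple[int, int] = DEFAULT_SIZE,
    mode: str = "pad",
) -> np.ndarray:
    """Adapt a CIFAR-10 batch to the configured input size.

    ``mode="pad"`` (default) zero-pads 32x32 frames symmetrically, which
    preserves the native image statistics; ``mode="resize"`` rescales with
    bilinear interpolation instead.
    """
    imgs = load_cifar_batch(path)
    h, w = size
    if mode == "pad":
        if h < 32 or w < 32:
            raise ConfigurationError(f"cannot pad 32x32 into smaller size {size}")
        top, left = (h - 32) // 2, (w - 32) // 2
        out = np.zeros((imgs.shape[0], h, w))
        out[:, top : top + 32, left : left + 32] = imgs
        return out
    if mode == "resize":
        from scipy.ndimage import zoom

        return np.stack([zoom(im, (h / 32, w / 32), order=1) for im in imgs])
    raise ConfigurationError(f"unknown adaptation mode {mode!r}")
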