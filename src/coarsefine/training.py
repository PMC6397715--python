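"""Layer-wise training with a derivative-based stopping rule.

Training proceeds one layer at a time, bottom-up, mimicking successive
critical periods: the current layer adapts while all layers below are
frozen, and is itself frozen once its reconstruction stops improving.
Per iteration, each bottom-up stream (a fresh variable image and the
constant target) is cascaded through the frozen layers, the current
layer's anti-Hebbian weight delta is computed, and the deltas are applied
sequentially, one stream at a time.

The stopping rule tracks ``d_t``, the mean absolute pixel difference
between the constant input and its (normalized) reconstruction through
the layers trained so far; the layer stops when an exponential moving
average of ``|d_t - d_{t-1}|`` falls below a threshold (default 1e-4)
after a short burn-in.  Cosine similarity between input and
reconstruction is sampled every fifth iteration for the progress trace.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable

import numpy as np

from . import layer as L
from .errors import ShapeError
from .stack import Stack, StackConfig, layer_activations, pack_output, reconstruct
from .layer import LayerConfig

__all__ = [
    "StoppingRule",
    "TrainState",
    "SimilarityTrace",
    "cosine_similarity",
    "normalize_image",
    "stopping_metric",
    "train_layerwise",
    "save_checkpoint",
    "load_checkpoint",
    "write_trace_csv",
    "read_trace_csv",
]

#: iterations before the stopping rule may fire (the derivative is
#: trivially small right after initialization)
DEFAULT_BURN_IN = 50


@dataclass(frozen=True)
class StoppingRule:
    """Convergence test on the smoothed derivative of the reconstruction error.

    ``threshold``: stop once the EMA of ``|d_t - d_{t-1}|`` drops below it.
    ``ema_coefficient``: weight of history in the EMA (0.99 smooths at the
    scale of a few hundred iterations).  ``burn_in``: iterations per layer
    before stopping is allowed.
    """

    threshold: float = 1e-4
    ema_coefficient: float = 0.99
    burn_in: int = DEFAULT_BURN_IN

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if not 0 < self.ema_coefficient < 1:
            raise ValueError(
                f"ema coefficient must be in (0, 1), got {self.ema_coefficient}"
            )


@dataclass
class TrainState:
    """Mutable bookkeeping for one layer-wise run."""

    iteration: int = 0
    current_layer: int = 1  # 1-based index of the layer being trained
    frozen: list[bool] = dc_field(default_factory=list)
    layer_iteration: int = 0
    prev_diff: float | None = None
    smoothed_abs_derivative: float = np.inf
    layer_outcomes: list[str] = dc_field(default_factory=list)
    layer_start_iterations: list[int] = dc_field(default_factory=list)
    seed: int = 0


@dataclass
class SimilarityTrace:
    """Sampled (iteration, cosine similarity, stopping metric) triples.

    The similarity compares the constant input with its reconstruction
    from the *top* layer's output, whatever layer is currently training —
    the regeneration pathway always runs through the whole hierarchy.
    Mean-centered cosine (Pearson correlation) is the default: min-max
    cosine between two non-negative images is dominated by their shared
    positive offset and saturates near 1 regardless of structure.
    """

    iterations: list[int] = dc_field(default_factory=list)
    similarity: list[float] = dc_field(default_factory=list)
    stopping: list[float] = dc_field(default_factory=list)
    crop_margin: int = 2
    normalization: str = "centered"
    sample_every: int = 5

    def append(self, iteration: int, sim: float, stop_metric: float) -> None:
        self.iterations.append(iteration)
        self.similarity.append(float(sim))
        self.stopping.append(float(stop_metric))


def normalize_image(image: np.ndarray, mode: str = "minmax") -> np.ndarray:
    """Per-image normalization: min-max to [0, 1] or mean-centering."""
    image = np.asarray(image, dtype=np.float64)
    if mode == "minmax":
        lo, hi = image.min(), image.max()
        if hi - lo == 0:
            return np.zeros_like(image)
        return (image - lo) / (hi - lo)
    if mode == "centered":
        return image - image.mean()
    raise ValueError(f"unknown normalization mode {mode!r}")


def cosine_similarity(
    input_image: np.ndarray,
    reconstruction: np.ndarray,
    crop_margin: int = 2,
    normalization: str = "minmax",
) -> float:
    """Cosine of the angle between the cropped, normalized images.

    Both images are cropped by ``crop_margin`` pixels on every side (to
    discard the darkened-frame artifact of overlap-add reconstruction,
    whose extent is the bottom window size minus one), independently
    normalized, flattened and compared.  Zero-norm vectors yield 0.0 with
    a warning rather than NaN.
    """
    a = np.asarray(input_image, dtype=np.float64)
    b = np.asarray(reconstruction, dtype=np.float64)
    if a.shape != b.shape:
        raise ShapeError(f"image shapes differ: {a.shape} vs {b.shape}")
    m = crop_margin
    if m < 0 or 2 * m >= min(a.shape):
        raise ShapeError(f"crop margin {m} leaves no pixels of {a.shape}")
    if m:
        a, b = a[m:-m, m:-m], b[m:-m, m:-m]
    a = normalize_image(a, normalization).ravel()
    b = normalize_image(b, normalization).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("zero-norm image in cosine similarity; returning 0.0")
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def stopping_metric(
    input_image: np.ndarray,
    reconstruction: np.ndarray,
    state: TrainState,
    rule: StoppingRule,
) -> tuple[TrainState, bool]:
    """Update the smoothed |derivative| of the reconstruction error.

    ``d_t`` is the mean absolute difference between the input and the
    min-max normalized reconstruction; the first iteration of a layer has
    no derivative and never stops.  Returns ``(state, stop_flag)``.
    """
    a = np.asarray(input_image, dtype=np.float64)
    b = normalize_image(reconstruction, "minmax")
    if a.shape != b.shape:
        raise ShapeError(f"image shapes differ: {a.shape} vs {b.shape}")
    d = float(np.mean(np.abs(a - b)))
    if state.prev_diff is None:
        state.prev_diff = d
        return state, False
    derivative = d - state.prev_diff
    state.prev_diff = d
    c = rule.ema_coefficient
    if not np.isfinite(state.smoothed_abs_derivative):
        state.smoothed_abs_derivative = abs(derivative)
    else:
        state.smoothed_abs_derivative = (
            c * state.smoothed_abs_derivative + (1 - c) * abs(derivative)
        )
    stop = (
        state.layer_iteration > rule.burn_in
        and state.smoothed_abs_derivative < rule.threshold
    )
    return state, stop


def train_layerwise(
    stack: Stack,
    stream_source: Callable[[int], list[np.ndarray]],
    stopping_rule: StoppingRule | None = None,
    seed: int = 0,
    max_iterations: int | list[int] = 500_000,
    constant_stream: int = 1,
    trace: SimilarityTrace | None = None,
    callback: Callable[[int, Stack, np.ndarray], None] | None = None,
) -> tuple[Stack, TrainState, SimilarityTrace]:
    """Train each layer in turn until its stopping criterion fires.

    Parameters
    ----------
    stack:
        The hierarchy to train (modified in place; also returned).
    stream_source:
        ``stream_source(t)`` returns one image per bottom-up stream for
        iteration ``t`` (e.g. ``StreamPair.streams``).
    stopping_rule:
        Convergence rule; defaults to threshold 1e-4, EMA 0.99.
    max_iterations:
        Global cap, or a per-layer list of caps.  Hitting a cap freezes
        the layer with outcome ``"max_iterations"`` (never silent).
    constant_stream:
        Index of the constant target stream used for the stopping metric
        and the similarity trace.
    callback:
        Optional ``callback(iteration, stack, reconstruction)`` invoked at
        every trace sample (for snapshotting).

    The similarity trace is sampled at iteration 2 (the conventional early
    baseline) and every fifth iteration thereafter.  Reconstruction for
    both metrics runs top-down from the current layer's own output, so
    only trained layers participate.
    """
    rule = stopping_rule or StoppingRule()
    trace = trace or SimilarityTrace()
    n_layers = stack.n_layers
    caps = (
        list(max_iterations)
        if isinstance(max_iterations, (list, tuple))
        else [int(max_iterations)] * n_layers
    )
    if len(caps) != n_layers:
        raise ValueError(f"need {n_layers} per-layer caps, got {len(caps)}")
    state = TrainState(frozen=[False] * n_layers, seed=seed)

    t = 0
    for layer_idx in range(n_layers):  # 0-based
        state.current_layer = layer_idx + 1
        state.layer_iteration = 0
        state.prev_diff = None
        state.smoothed_abs_derivative = np.inf
        lc = stack.config.layers[layer_idx]
        geom = stack.geometries[layer_idx]
        mask = stack.masks[layer_idx]
        state.layer_start_iterations.append(t + 1)
        outcome = "max_iterations"
        while state.layer_iteration < caps[layer_idx]:
            t += 1
            state.iteration = t
            state.layer_iteration += 1
            images = stream_source(t)
            const_act = None
            for s_idx, img in enumerate(images):
                source = img if layer_idx == 0 else _cascade_source(
                    stack, img, layer_idx
                )
                patches = L.im2row(np.asarray(source, dtype=np.float64), geom)
                acts = L.forward(patches, stack.weights[layer_idx])
                if lc.learning_rate > 0:
                    # Patch-averaged step: the raw sum over the ~1e3 window
                    # positions makes the effective step rate*n*lambda exceed
                    # the stability bound of this Oja-type recursion and the
                    # weights overflow within tens of iterations, so the
                    # configured rate is applied to the mean over windows.
                    delta = L.weight_delta(
                        patches,
                        acts,
                        stack.weights[layer_idx],
                        mask,
                        lc.learning_rate / geom.n,
                    )
                    stack.weights[layer_idx] = L.apply_update(
                        stack.weights[layer_idx], delta
                    )
                if s_idx == constant_stream:
                    const_act = acts
            if const_act is None:
                raise ValueError(
                    f"constant stream index {constant_stream} outside the "
                    f"{len(images)} streams supplied"
                )
            # stopping: constant stream reconstructed from the layer being
            # trained (only trained layers participate)
            recon, _ = reconstruct(stack, const_act, layer_idx + 1)
            target = np.asarray(images[constant_stream], dtype=np.float64)
            state, stop = stopping_metric(target, recon, state, rule)
            # sample every fifth iteration, plus each layer's second
            # iteration (the conventional early baseline of a phase)
            if state.layer_iteration == 2 or t % trace.sample_every == 0:
                # trace: reconstruction through the whole hierarchy
                full = _top_reconstruction(stack, const_act, layer_idx)
                sim = cosine_similarity(
                    target, full, trace.crop_margin, trace.normalization
                )
                trace.append(t, sim, state.smoothed_abs_derivative)
                if callback is not None:
                    callback(t, stack, full)
            if stop:
                outcome = "converged"
                break
        state.frozen[layer_idx] = True
        state.layer_outcomes.append(outcome)
    return stack, state, trace


def _top_reconstruction(
    stack: Stack, activation: np.ndarray, layer_idx: int
) -> np.ndarray:
    """Cascade layer ``layer_idx``'s (0-based) activation up to the top
    layer and reconstruct the image from there."""
    act = activation
    for k in range(layer_idx + 1, stack.n_layers):
        source = pack_output(
            act, stack.geometries[k - 1], stack.config.layers[k - 1].bank_shape
        )
        act = L.forward(L.im2row(source, stack.geometries[k]), stack.weights[k])
    recon, _ = reconstruct(stack, act, stack.n_layers)
    return recon


def _cascade_source(stack: Stack, image: np.ndarray, layer_idx: int) -> np.ndarray:
    """Packed output of layer ``layer_idx`` (0-based: the layer below the
    one being trained) for one image, through frozen layers only."""
    acts = layer_activations(stack, np.asarray(image, dtype=np.float64), up_to=layer_idx)
    return pack_output(
        acts[-1], stack.geometries[layer_idx - 1], stack.config.layers[layer_idx - 1].bank_shape
    )


# --- persistence ---------------------------------------------------------


def _config_to_dict(config: StackConfig) -> dict:
    return {
        "input_size": list(config.input_size),
        "n_bottom_up_streams": config.n_bottom_up_streams,
        "n_top_down_streams": config.n_top_down_streams,
        "layers": [
            {
                "receptive_field": list(lc.receptive_field),
                "bank_shape": list(lc.bank_shape),
                "learning_rate": lc.learning_rate,
                "dilation_gap": list(lc.dilation_gap),
                "stride": lc.stride,
                "topology_variant": lc.topology_variant,
            }
            for lc in config.layers
        ],
    }


def config_from_dict(d: dict) -> StackConfig:
    return StackConfig(
        input_size=tuple(d["input_size"]),
        layers=tuple(
            LayerConfig(
                receptive_field=tuple(lc["receptive_field"]),
                bank_shape=tuple(lc["bank_shape"]),
                learning_rate=lc["learning_rate"],
                dilation_gap=tuple(lc["dilation_gap"]),
                stride=lc["stride"],
                topology_variant=lc["topology_variant"],
            )
            for lc in d["layers"]
        ),
        n_bottom_up_streams=d.get("n_bottom_up_streams", 2),
        n_top_down_streams=d.get("n_top_down_streams", 1),
    )


def save_checkpoint(path: str | Path, stack: Stack, state: TrainState | None = None) -> None:
    """Write weights + config (+ state) to an ``.npz`` container.

    Arrays ``layer_1`` .. ``layer_L`` hold the filter banks; ``meta`` holds
    a JSON string with the configuration and training state.
    """
    meta = {"config": _config_to_dict(stack.config)}
    if state is not None:
        meta["state"] = {
            "iteration": state.iteration,
            "current_layer": state.current_layer,
            "frozen": state.frozen,
            "layer_outcomes": state.layer_outcomes,
            "seed": state.seed,
        }
    arrays = {f"layer_{i + 1}": w for i, w in enumerate(stack.weights)}
    np.savez(Path(path), meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[Stack, dict]:
    """Rebuild a stack (bit-identical weights) from :func:`save_checkpoint`."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        config = config_from_dict(meta["config"])
        stack = Stack.create(config, seed=0)
        for i in range(stack.n_layers):
            stack.weights[i] = data[f"layer_{i + 1}"].copy()
    return stack, meta


def write_trace_csv(path: str | Path, trace: SimilarityTrace) -> None:
    """Export the trace as CSV (iteration, similarity, stopping_metric)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "similarity", "stopping_metric"])
        for it, sim, stop in zip(trace.iterations, trace.similarity, trace.stopping):
            writer.writerow([it, f"{sim:.10g}", f"{stop:.10g}"])


def read_trace_csv(path: str | Path) -> SimilarityTrace:
    trace = SimilarityTrace()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            trace.append(
                int(row["iteration"]),
                float(row["similarity"]),
                float(row["stopping_metric"]),
            )
    return trace
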