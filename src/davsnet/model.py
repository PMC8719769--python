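"""Executable vessel-segmentation network.

The runtime interprets the symbolic :class:`~davsnet.graph.NetworkGraph`
directly: every layer kind has a NumPy forward and backward
implementation (convolutions via im2col and BLAS contractions), so the
parameter audit and the executable model share one single source of
truth.  Activations are ``(N, H, W, C)`` float arrays; the two class
channels are ordered ``(vessel, background)``.

Max-pooling retains, per 2x2 window and channel, the flat row-major
index of the first maximum; max-unpooling scatters values back to those
positions and zeroes elsewhere (the encoder-to-decoder index transfer).
Batch normalisation keeps running statistics (momentum 0.9) used in
inference mode, making inference deterministic and bitwise repeatable.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .graph import (
    INPUT_NAME,
    GraphError,
    NetworkGraph,
    ParamAudit,
    TensorShape,
    build_davsnet_graph,
    count_parameters,
    graph_from_json,
    graph_to_json,
    propagate_shapes,
)

__all__ = [
    "DavsNet",
    "init_parameters",
    "parameter_element_counts",
    "predict_mask",
    "Runtime",
    "BN_EPS",
    "BN_MOMENTUM",
]

BN_EPS = 1e-5
#: fraction of the running statistic retained per update
BN_MOMENTUM = 0.9

ModelParameters = dict  # layer name -> {"weight": ..., "bias": ...} / BN arrays


def init_parameters(
    graph: NetworkGraph,
    seed: int = 0,
    dtype=np.float32,
    shapes: Optional[Mapping[str, TensorShape]] = None,
) -> ModelParameters:
    """Fan-in-scaled (He) random initialisation, reproducible from ``seed``.

    Convolution weights are drawn from N(0, sqrt(2/fan_in)) with zero
    biases; batch-norm scale/shift start at 1/0 with zero-mean,
    unit-variance running statistics.
    """
    if shapes is None:
        shapes = propagate_shapes(graph)
    rng = np.random.default_rng(seed)
    params: ModelParameters = {}
    for spec in graph:
        if spec.kind == "convolution":
            kh, kw = spec.kernel
            cin = shapes[spec.inputs[0]].channels
            fan_in = kh * kw * cin
            std = np.sqrt(2.0 / fan_in)
            params[spec.name] = {
                "weight": rng.normal(0.0, std, size=(kh, kw, cin, spec.filters)).astype(dtype),
                "bias": np.zeros(spec.filters, dtype=dtype),
            }
        elif spec.kind == "batch_norm":
            c = shapes[spec.name].channels
            params[spec.name] = {
                "gamma": np.ones(c, dtype=dtype),
                "beta": np.zeros(c, dtype=dtype),
                "running_mean": np.zeros(c, dtype=dtype),
                "running_var": np.ones(c, dtype=dtype),
            }
    return params


def parameter_element_counts(params: ModelParameters) -> dict[str, dict[str, int]]:
    """Trainable element counts per layer (running statistics excluded)."""
    out = {}
    for name, arrs in params.items():
        counts = {}
        if "weight" in arrs:
            counts["weight"] = arrs["weight"].size
            counts["bias"] = arrs["bias"].size
        else:
            counts["bn"] = arrs["gamma"].size + arrs["beta"].size
        out[name] = counts
    return out


def predict_mask(probs: np.ndarray) -> np.ndarray:
    """Binarise a class-probability map: 1 where P(vessel) > P(background).

    Ties go to background, so a totally uninformative map predicts the
    majority class.
    """
    probs = np.asarray(probs)
    if probs.shape[-1] != 2:
        raise ValueError(f"expected 2 class channels, got shape {probs.shape}")
    return (probs[..., 0] > probs[..., 1]).astype(np.uint8)


# ---------------------------------------------------------------------------
# Layer forward/backward primitives
# ---------------------------------------------------------------------------

def _conv_forward(x, W, b):
    kh, kw = W.shape[:2]
    if kh == kw == 1:
        y = x @ W[0, 0] + b
        return y, x
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    v = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (N,H,W,C,kh,kw)
    y = np.tensordot(v, W, axes=([4, 5, 3], [0, 1, 2])) + b
    return y, xp


def _conv_backward(dy, cache, W):
    kh, kw = W.shape[:2]
    if kh == kw == 1:
        x = cache
        dW = np.tensordot(x, dy, axes=([0, 1, 2], [0, 1, 2]))[None, None]
        db = dy.sum(axis=(0, 1, 2))
        dx = dy @ W[0, 0].T
        return dx, dW, db
    xp = cache
    ph, pw = kh // 2, kw // 2
    v = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (N,H,W,Cin,kh,kw)
    # dW[u,v,ci,co] = sum_{n,i,j} x[n,i+u,j+v,ci] * dy[n,i,j,co]
    dW = np.tensordot(v, dy, axes=([0, 1, 2], [0, 1, 2])).transpose(1, 2, 0, 3)
    db = dy.sum(axis=(0, 1, 2))
    # dx = same-padded correlation of dy with the spatially flipped,
    # in/out-transposed kernel
    Wt = W[::-1, ::-1].transpose(0, 1, 3, 2)  # (kh,kw,Cout,Cin)
    dyp = np.pad(dy, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    dv = sliding_window_view(dyp, (kh, kw), axis=(1, 2))
    dx = np.tensordot(dv, Wt, axes=([4, 5, 3], [0, 1, 2]))
    return dx, dW, db


def _pool_forward(x):
    n, h, w, c = x.shape
    win = (
        x.reshape(n, h // 2, 2, w // 2, 2, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, h // 2, w // 2, 4, c)
    )
    idx = win.argmax(axis=3)  # first (row-major) max on ties
    y = np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return y, idx


def _unpool(y, idx, out_hw):
    n, h, w, c = y.shape
    oh, ow = out_hw
    if idx.shape != y.shape:
        raise GraphError(
            f"pooling indices shape {idx.shape} does not match feature shape {y.shape}"
        )
    z = np.zeros((n, h, w, 4, c), dtype=y.dtype)
    np.put_along_axis(z, idx[:, :, :, None, :], y[:, :, :, None, :], axis=3)
    return (
        z.reshape(n, h, w, 2, 2, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, oh, ow, c)
    )


def _pool_window(dz):
    n, oh, ow, c = dz.shape
    return (
        dz.reshape(n, oh // 2, 2, ow // 2, 2, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, oh // 2, ow // 2, 4, c)
    )


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Graph executor
# ---------------------------------------------------------------------------

class Runtime:
    """Executes a :class:`NetworkGraph` with explicit parameter arrays.

    ``forward`` walks the ordered layer list, caching whatever the
    corresponding ``backward`` needs; ``backward`` walks it in reverse,
    accumulating gradients for parameters and for the requested
    activations.  Sub-ranges of the layer list can be executed by
    seeding ``activations`` (used by ``encode``/``decode``).
    """

    def __init__(self, graph: NetworkGraph, shapes: Optional[Mapping[str, TensorShape]] = None):
        self.graph = graph
        self.shapes = shapes if shapes is not None else propagate_shapes(graph)
        self._cache: dict[str, object] = {}

    def forward(
        self,
        params: ModelParameters,
        activations: dict[str, np.ndarray],
        training: bool = False,
        indices: Optional[dict[str, np.ndarray]] = None,
        layers: Optional[Sequence] = None,
    ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
        """Run (a sub-range of) the graph.

        ``activations`` must contain every external input of the executed
        range (at least :data:`INPUT_NAME` for a full run) and is updated
        in place.  ``indices`` maps pool-layer names to argmax indices;
        pools executed in this run add theirs, unpools read their
        partner's.  Returns ``(activations, indices)``.
        """
        if indices is None:
            indices = {}
        cache = self._cache
        for spec in self.graph if layers is None else layers:
            xs = [activations[i] for i in spec.inputs]
            x = xs[0]
            kind = spec.kind
            if kind == "convolution":
                p = params[spec.name]
                y, cc = _conv_forward(x, p["weight"], p["bias"])
                cache[spec.name] = cc
            elif kind == "batch_norm":
                p = params[spec.name]
                if training:
                    mu = x.mean(axis=(0, 1, 2))
                    var = x.var(axis=(0, 1, 2))
                    p["running_mean"][...] = BN_MOMENTUM * p["running_mean"] + (1 - BN_MOMENTUM) * mu
                    p["running_var"][...] = BN_MOMENTUM * p["running_var"] + (1 - BN_MOMENTUM) * var
                else:
                    mu, var = p["running_mean"], p["running_var"]
                inv_std = 1.0 / np.sqrt(var + BN_EPS)
                xhat = (x - mu) * inv_std
                y = p["gamma"] * xhat + p["beta"]
                cache[spec.name] = (xhat, inv_std, training)
            elif kind == "relu":
                y = np.maximum(x, 0)
                cache[spec.name] = x > 0
            elif kind == "depth_concat":
                y = np.concatenate(xs, axis=-1)
                cache[spec.name] = [a.shape[-1] for a in xs]
            elif kind == "max_pool":
                y, idx = _pool_forward(x)
                indices[spec.name] = idx
            elif kind == "max_unpool":
                if spec.partner not in indices:
                    raise GraphError(
                        f"max_unpool {spec.name!r}: no pooling indices for partner {spec.partner!r}"
                    )
                s = self.shapes[spec.name]
                y = _unpool(x, indices[spec.partner], (s.height, s.width))
            elif kind == "softmax":
                y = _softmax(x)
                cache[spec.name] = None  # probs retrievable from activations
            elif kind == "pixel_classification":
                y = predict_mask(x)
            else:  # pragma: no cover
                raise GraphError(f"unhandled kind {kind!r}")
            activations[spec.name] = y
        return activations, indices

    def backward(
        self,
        params: ModelParameters,
        seed_grads: dict[str, np.ndarray],
        activations: dict[str, np.ndarray],
        indices: dict[str, np.ndarray],
    ) -> ModelParameters:
        """Backpropagate from ``seed_grads`` (layer name -> dL/d-activation).

        Requires a preceding ``forward(..., training=True)`` whose caches
        are still current.  Returns parameter gradients in the same
        nesting as ``params`` (running statistics get no gradient).
        """
        grads: ModelParameters = {}
        acc = dict(seed_grads)
        cache = self._cache
        for spec in reversed(self.graph.layers):
            dy = acc.pop(spec.name, None)
            if dy is None:
                continue
            kind = spec.kind
            if kind == "convolution":
                p = params[spec.name]
                dx, dW, db = _conv_backward(dy, cache[spec.name], p["weight"])
                grads[spec.name] = {"weight": dW, "bias": db}
                din = [dx]
            elif kind == "batch_norm":
                p = params[spec.name]
                xhat, inv_std, was_training = cache[spec.name]
                grads[spec.name] = {
                    "gamma": (dy * xhat).sum(axis=(0, 1, 2)),
                    "beta": dy.sum(axis=(0, 1, 2)),
                }
                dxhat = dy * p["gamma"]
                if was_training:
                    m = float(np.prod(dy.shape[:3]))
                    dx = (
                        inv_std
                        / m
                        * (
                            m * dxhat
                            - dxhat.sum(axis=(0, 1, 2))
                            - xhat * (dxhat * xhat).sum(axis=(0, 1, 2))
                        )
                    )
                else:
                    dx = dxhat * inv_std
                din = [dx]
            elif kind == "relu":
                din = [dy * cache[spec.name]]
            elif kind == "depth_concat":
                splits = np.cumsum(cache[spec.name])[:-1]
                din = np.split(dy, splits, axis=-1)
            elif kind == "max_pool":
                # gradient routes to the recorded argmax positions only:
                # identical scatter to the unpool forward
                s_in = self.shapes[spec.inputs[0]]
                din = [_unpool(dy, indices[spec.name], (s_in.height, s_in.width))]
            elif kind == "max_unpool":
                idx = indices[spec.partner]
                win = _pool_window(dy)
                din = [np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]]
            elif kind == "softmax":
                p = activations[spec.name]
                din = [p * (dy - (dy * p).sum(axis=-1, keepdims=True))]
            else:
                continue  # pixel_classification: no gradient path
            for inp, d in zip(spec.inputs, din):
                if inp == INPUT_NAME:
                    continue
                if inp in acc:
                    acc[inp] = acc[inp] + d
                else:
                    acc[inp] = d
        return grads


# ---------------------------------------------------------------------------
# Model object
# ---------------------------------------------------------------------------

@dataclass
class EncodeResult:
    """Output of the encoder: bottom feature, skip activations, pool indices."""

    bottom: np.ndarray
    skips: tuple[np.ndarray, np.ndarray, np.ndarray]
    indices: tuple[np.ndarray, np.ndarray, np.ndarray]


class DavsNet:
    """The densely aggregating encoder-decoder segmentation model.

    Parameters
    ----------
    input_shape : (height, width)
        Spatial size of the network input; each dimension must be
        divisible by 8.  Default 640x640.
    seed : int
        Seed for the fan-in-scaled random weight initialisation.
    dtype : numpy dtype
        Arithmetic precision (float32 by default; float64 is useful for
        gradient checking).
    """

    #: names of the encoder Conv-A activations carried by the outer dense paths
    SKIP_LAYERS = ("EDB1-C1-relu", "EDB2-C1-relu", "EDB3-C1-relu")
    POOL_LAYERS = ("Pool-1", "Pool-2", "Pool-3")
    BOTTOM_LAYER = "Pool-3"
    LOGIT_LAYER = "D-Bneck-3-relu"  # softmax input

    def __init__(self, input_shape=(640, 640), seed: int = 0, dtype=np.float32):
        h, w = input_shape
        self.graph = build_davsnet_graph(TensorShape(int(h), int(w), 3))
        self.shapes = propagate_shapes(self.graph)
        self.audit: ParamAudit = count_parameters(self.graph, self.shapes)
        self.dtype = np.dtype(dtype)
        self.params = init_parameters(self.graph, seed=seed, dtype=self.dtype, shapes=self.shapes)
        self.runtime = Runtime(self.graph, self.shapes)
        self._split = next(
            i for i, s in enumerate(self.graph.layers) if s.name == self.BOTTOM_LAYER
        ) + 1

    # -- plumbing -----------------------------------------------------------

    def _as_batch(self, image: np.ndarray) -> tuple[np.ndarray, bool]:
        x = np.asarray(image)
        single = x.ndim == 3
        if single:
            x = x[None]
        if x.ndim != 4 or x.shape[-1] != 3:
            raise GraphError(f"expected (H, W, 3) or (N, H, W, 3) input, got {x.shape}")
        s = self.graph.input_shape
        if x.shape[1] != s.height or x.shape[2] != s.width:
            raise GraphError(
                f"input spatial size {x.shape[1]}x{x.shape[2]} does not match the "
                f"model's configured {s.height}x{s.width}"
            )
        if x.dtype == np.uint8:
            x = x.astype(self.dtype) / 255.0
        else:
            x = x.astype(self.dtype, copy=False)
        return x, single

    # -- inference ----------------------------------------------------------

    def forward(self, image: np.ndarray, training: bool = False) -> np.ndarray:
        """Full forward pass; returns the per-pixel (vessel, background)
        probability map with the same batchness as the input."""
        acts, _ = self.forward_collect(image, training=training)
        probs = acts["softmax"]
        return probs[0] if np.asarray(image).ndim == 3 else probs

    def forward_collect(self, image, training=False):
        """Forward pass returning all layer activations and pool indices."""
        x, _ = self._as_batch(image)
        return self.runtime.forward(self.params, {INPUT_NAME: x}, training=training)

    def encode(self, image: np.ndarray) -> EncodeResult:
        """Run the encoder only (inference mode).

        Returns the bottom feature (1/8 scale, 256 channels), the three
        Conv-A skip activations feeding the outer dense paths, and the
        three sets of pooling indices.
        """
        x, single = self._as_batch(image)
        acts, idx = self.runtime.forward(
            self.params, {INPUT_NAME: x}, training=False, layers=self.graph.layers[: self._split]
        )
        take = (lambda a: a[0]) if single else (lambda a: a)
        return EncodeResult(
            bottom=take(acts[self.BOTTOM_LAYER]),
            skips=tuple(take(acts[n]) for n in self.SKIP_LAYERS),
            indices=tuple(take(idx[n]) for n in self.POOL_LAYERS),
        )

    def decode(self, bottom, skips, indices) -> np.ndarray:
        """Run the decoder from an :class:`EncodeResult`'s components."""
        single = np.asarray(bottom).ndim == 3
        lift = (lambda a: np.asarray(a)[None]) if single else np.asarray
        acts = {self.BOTTOM_LAYER: lift(bottom)}
        for name, a in zip(self.SKIP_LAYERS, skips):
            acts[name] = lift(a)
        idx = {name: lift(i) for name, i in zip(self.POOL_LAYERS, indices)}
        acts, _ = self.runtime.forward(
            self.params, acts, training=False, indices=idx, layers=self.graph.layers[self._split:]
        )
        probs = acts["softmax"]
        return probs[0] if single else probs

    def segment(self, image: np.ndarray) -> np.ndarray:
        """Binary vessel mask (1 = vessel) for an image at the model's size."""
        return predict_mask(self.forward(image))

    # -- training hook (delegates to davsnet.training) ----------------------

    def fit(self, images, masks, fovs=None, config=None, **kwargs):
        """Train on ``images``/``masks`` and return a
        :class:`~davsnet.training.TrainingResult`.  See
        :func:`davsnet.training.train` for the keyword arguments."""
        from .training import train

        return train(self, images, masks, fovs=fovs, config=config, **kwargs)

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        """Self-describing checkpoint: graph JSON plus every named array.

        The round trip save -> load -> forward is bit-exact (arrays are
        stored at their native dtype, running statistics included).
        """
        payload = {"__graph__": np.frombuffer(graph_to_json(self.graph).encode(), dtype=np.uint8)}
        for lname, arrs in self.params.items():
            for pname, arr in arrs.items():
                payload[f"{lname}//{pname}"] = arr
        with open(path, "wb") as fh:
            np.savez(fh, **payload)

    @classmethod
    def load(cls, path) -> "DavsNet":
        with np.load(path) as data:
            graph = graph_from_json(bytes(data["__graph__"]).decode())
            obj = cls.__new__(cls)
            obj.graph = graph
            obj.shapes = propagate_shapes(graph)
            obj.audit = count_parameters(graph, obj.shapes)
            obj.params = {}
            for key in data.files:
                if key == "__graph__":
                    continue
                lname, pname = key.split("//")
                obj.params.setdefault(lname, {})[pname] = data[key].copy()
        obj.dtype = obj.params["EDB1-C1"]["weight"].dtype
        obj.runtime = Runtime(obj.graph, obj.shapes)
        obj._split = next(i for i, s in enumerate(obj.graph.layers) if s.name == cls.BOTTOM_LAYER) + 1
        return obj
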