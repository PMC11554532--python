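"""Compact numpy execution engine for :class:`~planefusion.model_zoo.ModelGraph`.

Executes a layer graph forward (inference and training mode) and
backward, with stochastic-gradient-descent-with-momentum (SGDM) updates
and an L2 penalty.  Layout is NHWC throughout; convolutions use im2col
over "same"-padded inputs with ceil-division output sizes, matching the
shape-inference rules in ``model_zoo``.

This engine exists to execute and train the two residual architectures
(and their width-scaled variants) at desk scale; it is deliberately
minimal — no autograd tape beyond the graph itself, no GPU paths.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .model_zoo import ModelGraph, infer_shapes


class TrainingDivergence(RuntimeError):
    """Raised when the loss turns non-finite during training."""


def _same_pad(size: int, kernel: int, stride: int) -> tuple[int, int]:
    out = max(1, -(-size // stride))
    total = max((out - 1) * stride + kernel - size, 0)
    return total // 2, total - total // 2


def _im2col(x: np.ndarray, kernel: int, stride: int) -> tuple[np.ndarray, tuple]:
    """Return (patches reshaped to (N*OH*OW, k*k*C), padded shape)."""
    n, h, w, c = x.shape
    pt, pb = _same_pad(h, kernel, stride)
    pl, pr = _same_pad(w, kernel, stride)
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    win = sliding_window_view(xp, (kernel, kernel), axis=(1, 2))  # n,H',W',c,k,k
    win = win[:, ::stride, ::stride]
    n_, oh, ow, c_, kh, kw = win.shape
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n_ * oh * ow, kh * kw * c_)
    return cols, (xp.shape, (pt, pl), (oh, ow))


def _col2im(dcols: np.ndarray, x_shape: tuple, pad_info: tuple, kernel: int, stride: int) -> np.ndarray:
    """Scatter column gradients back to the (unpadded) input."""
    n, h, w, c = x_shape
    xp_shape, (pt, pl), (oh, ow) = pad_info
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    dwin = dcols.reshape(n, oh, ow, kernel, kernel, c)
    for ki in range(kernel):
        for kj in range(kernel):
            dxp[:, ki : ki + oh * stride : stride, kj : kj + ow * stride : stride, :] += dwin[
                :, :, :, ki, kj, :
            ]
    return dxp[:, pt : pt + h, pl : pl + w, :]


class NumpyNetwork:
    """Executable instantiation of a :class:`ModelGraph`.

    Parameters are He-initialized from ``rng``.  ``forward`` caches
    intermediates when ``training=True`` so that ``backward`` can
    produce gradients; ``sgd_step`` applies classical momentum with an
    L2 penalty on weights (not biases or batchnorm affine terms).
    """

    BN_MOMENTUM = 0.9
    BN_EPS = 1e-5

    def __init__(self, graph: ModelGraph, rng: np.random.Generator):
        graph.validate()
        self.graph = graph
        self.report = infer_shapes(graph)
        self.order = graph.topological_order()
        self.params: dict[str, dict[str, np.ndarray]] = {}
        self.velocity: dict[str, dict[str, np.ndarray]] = {}
        self.bn_stats: dict[str, dict[str, np.ndarray]] = {}
        self._cache: dict = {}
        in_ch = {}
        for name in self.order:
            spec = graph.layer(name)
            preds = graph.predecessors(name)
            if spec.kind == "input":
                continue
            hin, win, cin = self.report.shapes[preds[0]]
            if spec.kind == "conv":
                # He init on the *effective* receptive field: once the map is
                # smaller than the kernel, padding zeros most taps and the
                # nominal k^2 fan-in would shrink activations ~3x per layer.
                fan_in = min(spec.kernel, hin) * min(spec.kernel, win) * cin
                w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(spec.kernel**2 * cin, spec.depth))
                self.params[name] = {"W": w.astype(np.float32), "b": np.zeros(spec.depth, np.float32)}
            elif spec.kind == "fc":
                # zero head: untrained network predicts exactly uniform, so
                # the initial cross-entropy starts at ln(num_classes)
                w = np.zeros((cin, spec.depth))
                self.params[name] = {"W": w.astype(np.float32), "b": np.zeros(spec.depth, np.float32)}
            elif spec.kind == "batchnorm":
                self.params[name] = {
                    "gamma": np.ones(cin, np.float32),
                    "beta": np.zeros(cin, np.float32),
                }
                self.bn_stats[name] = {
                    "mean": np.zeros(cin, np.float32),
                    "var": np.ones(cin, np.float32),
                }
        for lname, p in self.params.items():
            self.velocity[lname] = {k: np.zeros_like(v) for k, v in p.items()}

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Run the graph on a batch ``(n, h, w, c)``; returns softmax probs."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1:] != tuple(self.graph.input_shape):
            raise ValueError(
                f"expected input of shape (n, {self.graph.input_shape}), got {x.shape}"
            )
        acts: dict[str, np.ndarray] = {}
        cache: dict = {}
        for name in self.order:
            spec = self.graph.layer(name)
            preds = self.graph.predecessors(name)
            if spec.kind == "input":
                acts[name] = x
                continue
            a = acts[preds[0]]
            if spec.kind == "conv":
                cols, pad_info = _im2col(a, spec.kernel, spec.stride)
                w, bias = self.params[name]["W"], self.params[name]["b"]
                out = cols @ w + bias
                oh, ow = pad_info[2]
                acts[name] = out.reshape(a.shape[0], oh, ow, spec.depth)
                if training:
                    cache[name] = (cols, a.shape, pad_info)
            elif spec.kind == "relu":
                acts[name] = np.maximum(a, 0.0)
                if training:
                    cache[name] = a > 0
            elif spec.kind == "maxpool":
                n, h, w_, c = a.shape
                pt, pb = _same_pad(h, spec.kernel, spec.stride)
                pl, pr = _same_pad(w_, spec.kernel, spec.stride)
                ap = np.pad(a, ((0, 0), (pt, pb), (pl, pr), (0, 0)), constant_values=-np.inf)
                win = sliding_window_view(ap, (spec.kernel, spec.kernel), axis=(1, 2))
                win = win[:, :: spec.stride, :: spec.stride]
                flat = win.reshape(*win.shape[:4], -1)
                acts[name] = flat.max(axis=-1)
                if training:
                    cache[name] = (flat.argmax(axis=-1), a.shape, (pt, pl), win.shape)
            elif spec.kind == "batchnorm":
                gamma, beta = self.params[name]["gamma"], self.params[name]["beta"]
                if training:
                    mu = a.mean(axis=(0, 1, 2))
                    var = a.var(axis=(0, 1, 2))
                    stats = self.bn_stats[name]
                    stats["mean"] = self.BN_MOMENTUM * stats["mean"] + (1 - self.BN_MOMENTUM) * mu
                    stats["var"] = self.BN_MOMENTUM * stats["var"] + (1 - self.BN_MOMENTUM) * var
                else:
                    mu = self.bn_stats[name]["mean"]
                    var = self.bn_stats[name]["var"]
                inv = 1.0 / np.sqrt(var + self.BN_EPS)
                xhat = (a - mu) * inv
                acts[name] = gamma * xhat + beta
                if training:
                    cache[name] = (xhat, inv)
            elif spec.kind == "add":
                acts[name] = acts[preds[0]] + acts[preds[1]]
            elif spec.kind == "gap":
                acts[name] = a.mean(axis=(1, 2))
                if training:
                    cache[name] = a.shape
            elif spec.kind == "fc":
                w, bias = self.params[name]["W"], self.params[name]["b"]
                acts[name] = a @ w + bias
                if training:
                    cache[name] = a
            elif spec.kind == "softmax":
                z = a - a.max(axis=-1, keepdims=True)
                ez = np.exp(z)
                acts[name] = ez / ez.sum(axis=-1, keepdims=True)
        self._cache = {"acts": acts, "layer": cache} if training else {}
        out_name = self.order[-1]
        return acts[out_name]

    def gap_features(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Inference-mode activations at the GAP layer, row order preserved."""
        gap_name = next(n for n in self.order if self.graph.layer(n).kind == "gap")
        outs = []
        for start in range(0, len(x), batch_size):
            batch = np.asarray(x[start : start + batch_size], dtype=np.float32)
            if len(batch) == 0:
                continue
            self.forward(batch, training=False)
            # forward with training=False drops caches, so recompute by
            # truncated execution: run forward keeping only needed acts
            outs.append(self._partial_forward(batch, gap_name))
        width = self.report.gap_width
        if not outs:
            return np.zeros((0, width), dtype=np.float32)
        return np.concatenate(outs, axis=0)

    def _partial_forward(self, x: np.ndarray, stop_name: str) -> np.ndarray:
        acts: dict[str, np.ndarray] = {}
        for name in self.order:
            spec = self.graph.layer(name)
            preds = self.graph.predecessors(name)
            if spec.kind == "input":
                acts[name] = np.asarray(x, dtype=np.float32)
            else:
                a = acts[preds[0]]
                if spec.kind == "conv":
                    cols, pad_info = _im2col(a, spec.kernel, spec.stride)
                    out = cols @ self.params[name]["W"] + self.params[name]["b"]
                    oh, ow = pad_info[2]
                    acts[name] = out.reshape(a.shape[0], oh, ow, spec.depth)
                elif spec.kind == "relu":
                    acts[name] = np.maximum(a, 0.0)
                elif spec.kind == "maxpool":
                    n, h, w_, c = a.shape
                    pt, pb = _same_pad(h, spec.kernel, spec.stride)
                    pl, pr = _same_pad(w_, spec.kernel, spec.stride)
                    ap = np.pad(a, ((0, 0), (pt, pb), (pl, pr), (0, 0)), constant_values=-np.inf)
                    win = sliding_window_view(ap, (spec.kernel, spec.kernel), axis=(1, 2))
                    win = win[:, :: spec.stride, :: spec.stride]
                    acts[name] = win.reshape(*win.shape[:4], -1).max(axis=-1)
                elif spec.kind == "batchnorm":
                    mu = self.bn_stats[name]["mean"]
                    var = self.bn_stats[name]["var"]
                    inv = 1.0 / np.sqrt(var + self.BN_EPS)
                    acts[name] = self.params[name]["gamma"] * (a - mu) * inv + self.params[name]["beta"]
                elif spec.kind == "add":
                    acts[name] = acts[preds[0]] + acts[preds[1]]
                elif spec.kind == "gap":
                    acts[name] = a.mean(axis=(1, 2))
                elif spec.kind == "fc":
                    acts[name] = a @ self.params[name]["W"] + self.params[name]["b"]
                elif spec.kind == "softmax":
                    z = a - a.max(axis=-1, keepdims=True)
                    ez = np.exp(z)
                    acts[name] = ez / ez.sum(axis=-1, keepdims=True)
            if name == stop_name:
                return acts[name]
        raise KeyError(stop_name)

    # ------------------------------------------------------------------
    def loss_and_grads(self, x: np.ndarray, y: np.ndarray) -> tuple[float, dict]:
        """Cross-entropy loss (mean over batch) and parameter gradients."""
        probs = self.forward(x, training=True)
        n = len(x)
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(n), y] + eps)))
        acts = self._cache["acts"]
        cache = self._cache["layer"]
        grads: dict[str, dict[str, np.ndarray]] = {}
        dacts: dict[str, np.ndarray] = {}
        # combined softmax + CE gradient at the softmax layer's input
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        softmax_name = self.order[-1]
        dacts[self.graph.predecessors(softmax_name)[0]] = dlogits
        for name in reversed(self.order[:-1]):
            spec = self.graph.layer(name)
            if name not in dacts:
                continue
            d = dacts[name]
            preds = self.graph.predecessors(name)
            if spec.kind == "input":
                continue
            if spec.kind == "conv":
                cols, a_shape, pad_info = cache[name]
                dout = d.reshape(-1, spec.depth)
                grads[name] = {
                    "W": cols.T @ dout,
                    "b": dout.sum(axis=0),
                }
                # dcols columns are ordered (k, k, c), matching _im2col
                dcols = dout @ self.params[name]["W"].T
                dx = _col2im(dcols, a_shape, pad_info, spec.kernel, spec.stride)
                self._accum(dacts, preds[0], dx)
            elif spec.kind == "relu":
                self._accum(dacts, preds[0], d * cache[name])
            elif spec.kind == "maxpool":
                argmax, a_shape, (pt, pl), win_shape = cache[name]
                n_, oh, ow, c = win_shape[:4]
                k = spec.kernel
                # recover padded size exactly as in forward
                pt_, pb_ = _same_pad(a_shape[1], k, spec.stride)
                pl_, pr_ = _same_pad(a_shape[2], k, spec.stride)
                dxp = np.zeros(
                    (a_shape[0], a_shape[1] + pt_ + pb_, a_shape[2] + pl_ + pr_, c), dtype=d.dtype
                )
                ki, kj = np.unravel_index(argmax, (k, k))
                ni, oi, oj, ci = np.indices((n_, oh, ow, c))
                np.add.at(
                    dxp,
                    (ni, oi * spec.stride + ki, oj * spec.stride + kj, ci),
                    d,
                )
                self._accum(
                    dacts, preds[0], dxp[:, pt_ : pt_ + a_shape[1], pl_ : pl_ + a_shape[2], :]
                )
            elif spec.kind == "batchnorm":
                xhat, inv = cache[name]
                gamma = self.params[name]["gamma"]
                m = d.shape[0] * d.shape[1] * d.shape[2]
                dgamma = (d * xhat).sum(axis=(0, 1, 2))
                dbeta = d.sum(axis=(0, 1, 2))
                grads[name] = {"gamma": dgamma, "beta": dbeta}
                dxhat = d * gamma
                dx = (
                    inv
                    / m
                    * (m * dxhat - dxhat.sum(axis=(0, 1, 2)) - xhat * (dxhat * xhat).sum(axis=(0, 1, 2)))
                )
                self._accum(dacts, preds[0], dx)
            elif spec.kind == "add":
                self._accum(dacts, preds[0], d)
                self._accum(dacts, preds[1], d)
            elif spec.kind == "gap":
                a_shape = cache[name]
                h, w = a_shape[1], a_shape[2]
                dx = np.broadcast_to(d[:, None, None, :] / (h * w), a_shape).copy()
                self._accum(dacts, preds[0], dx)
            elif spec.kind == "fc":
                a = cache[name]
                grads[name] = {"W": a.T @ d, "b": d.sum(axis=0)}
                self._accum(dacts, preds[0], d @ self.params[name]["W"].T)
        self._cache = {}
        return loss, grads

    @staticmethod
    def _accum(dacts: dict, name: str, grad: np.ndarray) -> None:
        if name in dacts:
            dacts[name] = dacts[name] + grad
        else:
            dacts[name] = grad

    def sgd_step(
        self, grads: dict, learning_rate: float, momentum: float, l2_weight: float
    ) -> None:
        for lname, g in grads.items():
            for pname, dp in g.items():
                p = self.params[lname][pname]
                v = self.velocity[lname][pname]
                reg = l2_weight * p if pname == "W" else 0.0
                v *= momentum
                v -= learning_rate * (dp + reg)
                p += v
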