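"""Convolutional feature backbones behind a minimal adapter contract.

The pipeline treats the backbone as a frozen feature extractor: only the
final affine head is ever trained. Any network qualifies as a backbone if it
exposes

* ``pooled_dim``                       -- dimension of the pooled feature vector,
* ``forward(batch)``                   -- last-convolutional-layer activations
  ``A`` of shape (N, C, H', W') and the globally average-pooled features
  (N, C), and
* ``input_gradient(batch, head_w)``    -- the gradient of the scalar
  ``head_w . pooled`` with respect to the input pixels (used by integrated
  gradients).

Because global average pooling directly follows the last convolution, the
gradient of a head logit with respect to ``A`` is the head weight divided by
the spatial cell count -- the quantity Grad-CAM spatially averages.

:class:`TinyConvBackbone` is the shipped concrete backbone: a 3-block CNN
with fixed, seeded He-initialized random filters. Random convolutional
features are a classical, surprisingly strong image representation for
linear probes, and a fixed-weight backbone keeps every experiment exactly
reproducible. Implemented directly on NumPy with explicit forward and
backward passes.
"""

from __future__ import annotations

from typing import Protocol, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class BackboneAdapter(Protocol):
    """Structural contract for pluggable convolutional backbones."""

    pooled_dim: int
    input_channels: int

    def forward(self, batch: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Return (last_conv_activations (N,C,H',W'), pooled_features (N,C))."""
        ...

    def input_gradient(self, batch: np.ndarray, head_w: np.ndarray) -> np.ndarray:
        """Gradient of ``head_w . pooled`` w.r.t. the input, per batch item."""
        ...


# ---------------------------------------------------------------------------
# numpy conv primitives (stride 1, 3x3, same padding)
# ---------------------------------------------------------------------------


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-size stride-1 cross-correlation with reflect padding.

    x: (N,C,H,W), w: (O,C,3,3). Reflect padding avoids the spurious border
    edges zero padding would create on dark, non-zero-mean plate images.
    """
    n, c, h, wd = x.shape
    o = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="reflect")
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    # im2col + single GEMM is far faster than contracting the strided view
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * 9)
    out = cols @ w.reshape(o, c * 9).T
    return out.reshape(n, h, wd, o).transpose(0, 3, 1, 2) + b[None, :, None, None]


def conv2d_input_grad(g: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Gradient of conv2d w.r.t. its input (adjoint of reflect-pad + conv).

    Full correlation of the upstream grad with channel-transposed flipped
    kernels gives the gradient w.r.t. the padded array; the pad ring is then
    folded back onto the interior rows/columns it mirrors.
    """
    n, o, h, wd = g.shape
    wt = np.transpose(w, (1, 0, 2, 3))[:, :, ::-1, ::-1]
    c = wt.shape[0]
    gp = np.pad(g, ((0, 0), (0, 0), (2, 2), (2, 2)))
    win = sliding_window_view(gp, (3, 3), axis=(2, 3))  # (N,O,H+2,W+2,3,3)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * (h + 2) * (wd + 2), o * 9)
    gxp = (cols @ wt.reshape(c, o * 9).T).reshape(n, h + 2, wd + 2, c)
    gxp = gxp.transpose(0, 3, 1, 2)
    gx = np.ascontiguousarray(gxp[:, :, 1:-1, 1:-1])
    # fold the reflected ring: padded row 0 mirrors interior row 1, etc.
    gx[:, :, 1, :] += gxp[:, :, 0, 1:-1]
    gx[:, :, -2, :] += gxp[:, :, -1, 1:-1]
    gx[:, :, :, 1] += gxp[:, :, 1:-1, 0]
    gx[:, :, :, -2] += gxp[:, :, 1:-1, -1]
    gx[:, :, 1, 1] += gxp[:, :, 0, 0]
    gx[:, :, 1, -2] += gxp[:, :, 0, -1]
    gx[:, :, -2, 1] += gxp[:, :, -1, 0]
    gx[:, :, -2, -2] += gxp[:, :, -1, -1]
    return gx


def avgpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def avgpool2_grad(g: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0


# ---------------------------------------------------------------------------
# the 3-block backbone
# ---------------------------------------------------------------------------


#: Rec. 601 luminance weights
_LUM = np.array([0.299, 0.587, 0.114])


class TinyConvBackbone:
    """Fixed-weight 3-block CNN: conv-ReLU-pool x2 then conv-ReLU, then GAP.

    Channel plan 3 -> 20 -> 32 -> ``pooled_dim`` (default 32). The first
    layer combines a small hand-designed front end with seeded random
    filters:

    * ON/OFF luminance channels (brightness, darkness) -- half-wave
      rectified opposite-sign luminance, the retinal ON/OFF split;
    * R-G and G-R color-opponent channels -- respond to brown plate versus
      green tissue;
    * remaining channels random with their per-channel spatial mean shrunk
      to ``dc_gain``, so responses to spatially uniform input (plate tint)
      are attenuated while edge/texture responses are untouched.

    The four surface channels form an isolated pathway: identity taps carry
    them to the last convolutional layer, keeping spatially broad surface
    cues visible to Grad-CAM there, while every other downstream filter is
    blinded to them so their high-gain responses cannot drown the random
    texture/shape pathway. Weights are never trained in the classification
    protocol (a pretext task can train them via :func:`fit_backbone`); the
    default backbone is reproducible from (seed, widths) alone. Input sides
    must be divisible by 8.
    """

    N_FIXED = 4  # 2 ON/OFF luminance + 2 color-opponent surface channels

    def __init__(self, pooled_dim: int = 32, seed: int = 7,
                 widths: Tuple[int, int] = (20, 32), dc_gain: float = 0.1,
                 structured: bool = True):
        self.pooled_dim = int(pooled_dim)
        self.input_channels = 3
        self.seed = int(seed)
        self.dc_gain = float(dc_gain)
        self.structured = bool(structured)
        rng = np.random.default_rng(seed)
        c1, c2 = widths
        self.w1 = rng.normal(0, np.sqrt(2.0 / (3 * 9)), size=(c1, 3, 3, 3))
        mean = self.w1.mean(axis=(2, 3), keepdims=True)
        self.w1 = self.w1 - (1.0 - self.dc_gain) * mean
        self.b1 = np.zeros(c1)
        self.w2 = rng.normal(0, np.sqrt(2.0 / (c1 * 9)), size=(c2, c1, 3, 3))
        self.b2 = np.zeros(c2)
        self.w3 = rng.normal(0, np.sqrt(2.0 / (c2 * 9)), size=(self.pooled_dim, c2, 3, 3))
        self.b3 = np.zeros(self.pooled_dim)
        if self.structured and c1 > self.N_FIXED and c2 > 4 and self.pooled_dim > 4:
            self._install_front_end(c1)
        # single precision throughout: deterministic, and twice the GEMM speed
        for name in ("w1", "b1", "w2", "b2", "w3", "b3"):
            setattr(self, name, getattr(self, name).astype(np.float32))

    def _install_front_end(self, c1: int) -> None:
        # The front end is specified in raw [0, 1] intensity units; since the
        # backbone sees channel-standardized inputs (ImageNet constants), the
        # raw-unit linear map is folded into weights and biases here.
        norm_mean = np.array([0.485, 0.456, 0.406])
        norm_sd = np.array([0.229, 0.224, 0.225])
        u9 = np.ones((3, 3)) / 9.0

        def raw_filter(ch: int, raw_w: np.ndarray, raw_bias: float,
                       gain: float, kernel: np.ndarray) -> None:
            self.w1[ch] = gain * (raw_w * norm_sd)[:, None, None] * kernel
            # uniform kernels sum to 1; derivative kernels sum to 0 per cell
            ksum = kernel.sum()
            self.b1[ch] = gain * ksum * float(raw_w @ norm_mean) + gain * raw_bias

        # ch0/1: OFF (darkness) and ON (brightness) half-wave luminance pair,
        # split at an intensity between dark agar and bright tissue
        raw_filter(0, -_LUM, 0.30, 3.0, u9)
        raw_filter(1, _LUM, -0.30, 3.0, u9)
        # ch2/3: color opponents -- R-G fires on the brown plate, G-R on
        # green tissue; each silent on the other surface
        # R-G gets a higher gain than the luminance pair: opponent contrast
        # on the plate is ~5x smaller in raw units than the dark/bright
        # split. G-R (green tissue) is already strong in raw units.
        raw_filter(2, np.array([1.0, -1.0, 0.0]), 0.0, 30.0, u9)
        raw_filter(3, np.array([-1.0, 1.0, 0.0]), 0.0, 10.0, u9)
        # identity taps carry the surface channels to the last conv layer;
        # all other downstream filters are blinded to them so the high-gain
        # surface responses cannot drown the random texture/shape pathway
        for layer_w in (self.w2, self.w3):
            for j in range(4):
                layer_w[j] = 0.0
                layer_w[j, j, 1, 1] = 1.0
            layer_w[4:, 0:4] = 0.0

    # -- forward -----------------------------------------------------------

    def _forward_cached(self, x: np.ndarray):
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("backbone expects a (N, 3, H, W) batch")
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError("input side lengths must be divisible by 8")
        z1 = conv2d(x, self.w1, self.b1)
        a1 = np.maximum(z1, 0.0)
        p1 = avgpool2(a1)
        z2 = conv2d(p1, self.w2, self.b2)
        a2 = np.maximum(z2, 0.0)
        p2 = avgpool2(a2)
        z3 = conv2d(p2, self.w3, self.b3)
        a3 = np.maximum(z3, 0.0)
        # the network's final stage is one more 2x2 average pool; the
        # activations entering global pooling therefore live on a coarse
        # (input/8) grid, as in deep reference backbones, while conv3 still
        # computes on the finer grid. GAP over either grid is identical.
        a_last = avgpool2(a3)
        pooled = a_last.mean(axis=(2, 3))
        return dict(x=x, z1=z1, p1=p1, z2=z2, p2=p2, z3=z3, a3=a3,
                    a_last=a_last, pooled=pooled)

    def forward(self, batch: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        cache = self._forward_cached(np.asarray(batch, dtype=np.float32))
        return cache["a_last"], cache["pooled"]

    def features(self, batch: np.ndarray, chunk: int = 64) -> np.ndarray:
        """Pooled features for a possibly large batch, computed in chunks."""
        batch = np.asarray(batch, dtype=np.float32)
        outs = [self.forward(batch[i:i + chunk])[1] for i in range(0, len(batch), chunk)]
        return np.concatenate(outs, axis=0)

    # -- backward ----------------------------------------------------------

    def input_gradient(self, batch: np.ndarray, head_w: np.ndarray) -> np.ndarray:
        """d(head_w . pooled)/d(input) for each batch item."""
        x = np.asarray(batch, dtype=np.float32)
        head_w = np.asarray(head_w, dtype=np.float32)
        if head_w.shape != (self.pooled_dim,):
            raise ValueError("head_w must have shape (pooled_dim,)")
        cache = self._forward_cached(x)
        hw = cache["a3"].shape[2] * cache["a3"].shape[3]
        g = np.broadcast_to(
            head_w[None, :, None, None] / hw, cache["a3"].shape
        ) * (cache["z3"] > 0)
        g = conv2d_input_grad(g, self.w3)
        g = avgpool2_grad(g) * (cache["z2"] > 0)
        g = conv2d_input_grad(g, self.w2)
        g = avgpool2_grad(g) * (cache["z1"] > 0)
        return conv2d_input_grad(g, self.w1)


def conv2d_weight_grad(x: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Gradient of conv2d w.r.t. its weights. x: conv input, g: upstream grad."""
    n, c, h, wd = x.shape
    o = g.shape[1]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="reflect")
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * 9)
    gmat = g.transpose(1, 0, 2, 3).reshape(o, n * h * wd)
    return (gmat @ cols).reshape(o, c, 3, 3)


# ---------------------------------------------------------------------------
# generic pretraining (the desk-scale analog of ImageNet pretraining)
# ---------------------------------------------------------------------------


def fit_backbone(
    backbone: "TinyConvBackbone",
    x: np.ndarray,
    y: np.ndarray,
    epochs: int = 8,
    learning_rate: float = 3e-3,
    batch_size: int = 32,
    seed: int = 0,
) -> list:
    """Train the whole CNN (plus a temporary softmax head) on a pretext task.

    ``x`` is an (N, 3, H, W) batch, ``y`` integer labels of any cardinality.
    The temporary classification head is discarded afterwards; only the
    convolutional weights persist. Returns the per-epoch training accuracy.

    This is how a reusable backbone is produced: trained once on generic
    synthetic plant variation (pseudo-accessions differing in size, color,
    contour and background), then frozen for every downstream experiment,
    mirroring the pretrain-then-transfer recipe of large-scale classifiers.
    """
    rng = np.random.default_rng(seed)
    n = len(x)
    k = int(y.max()) + 1
    d = backbone.pooled_dim
    head_w = rng.normal(0, 0.05, size=(k, d))
    head_b = np.zeros(k)
    params = [backbone.w1, backbone.b1, backbone.w2, backbone.b2,
              backbone.w3, backbone.b3, head_w, head_b]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        correct = 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = x[idx], y[idx]
            cache = backbone._forward_cached(xb)
            pooled = cache["pooled"]
            logits = pooled @ head_w.T + head_b
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            correct += int((logits.argmax(axis=1) == yb).sum())
            g = p
            g[np.arange(len(yb)), yb] -= 1.0
            g /= len(yb)
            g_head_w = g.T @ pooled
            g_head_b = g.sum(axis=0)
            g_pooled = g @ head_w
            h3w3 = cache["a3"].shape[2] * cache["a3"].shape[3]
            ga3 = (g_pooled[:, :, None, None] / h3w3) * (cache["z3"] > 0)
            gw3 = conv2d_weight_grad(cache["p2"], ga3)
            gb3 = ga3.sum(axis=(0, 2, 3))
            gp2 = conv2d_input_grad(ga3, backbone.w3)
            ga2 = avgpool2_grad(gp2) * (cache["z2"] > 0)
            gw2 = conv2d_weight_grad(cache["p1"], ga2)
            gb2 = ga2.sum(axis=(0, 2, 3))
            gp1 = conv2d_input_grad(ga2, backbone.w2)
            ga1 = avgpool2_grad(gp1) * (cache["z1"] > 0)
            gw1 = conv2d_weight_grad(cache["x"], ga1)
            gb1 = ga1.sum(axis=(0, 2, 3))
            grads = [gw1, gb1, gw2, gb2, gw3, gb3, g_head_w, g_head_b]
            t += 1
            for j, (par, gr) in enumerate(zip(params, grads)):
                m[j] = beta1 * m[j] + (1 - beta1) * gr
                v[j] = beta2 * v[j] + (1 - beta2) * gr**2
                par -= learning_rate * (m[j] / (1 - beta1**t)) / (
                    np.sqrt(v[j] / (1 - beta2**t)) + eps)
        history.append(correct / n)
    return history


class LinearToyBackbone:
    """Minimal closed-form adapter used to verify attribution algebra.

    Channel k's activation map is ``mask_k * mean(input)``, pooled by global
    averaging; everything is linear in the input, so Grad-CAM channel
    weights, integrated gradients and completeness sums all have exact
    hand-derivable values.
    """

    def __init__(self, masks: np.ndarray):
        self.masks = np.asarray(masks, dtype=np.float64)  # (C, H', W')
        self.pooled_dim = self.masks.shape[0]
        self.input_channels = 3

    def forward(self, batch: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        batch = np.asarray(batch, dtype=np.float64)
        s = batch.mean(axis=(1, 2, 3))
        a = s[:, None, None, None] * self.masks[None]
        return a, a.mean(axis=(2, 3))

    def input_gradient(self, batch: np.ndarray, head_w: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float64)
        n, c, h, w = batch.shape
        coef = float((np.asarray(head_w) * self.masks.mean(axis=(1, 2))).sum())
        return np.full(batch.shape, coef / (c * h * w))


def to_nchw(images) -> np.ndarray:
    """Stack NormalizedImages (or HWC arrays) into an (N, 3, H, W) batch."""
    arrs = []
    for im in images:
        pix = getattr(im, "pixels", im)
        arrs.append(np.transpose(np.asarray(pix, dtype=np.float64), (2, 0, 1)))
    return np.stack(arrs, axis=0)
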