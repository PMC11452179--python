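"""Numpy implementation of the core+readout encoding network.

The architecture is a two-layer convolutional core shared by all neurons,
followed by a per-neuron Gaussian readout:

* layer 1: 16 space-time separable kernels (2 x 11 x 11 spatial maps, each
  paired with a 21-tap temporal kernel), valid convolution in space and
  time, then batch normalisation and an ELU;
* layer 2: 16 separable kernels (16 x 5 x 5 spatial, 11-tap temporal),
  zero-padded in space, valid in time, batch norm, ELU;
* readout: an isotropic 2D Gaussian mask N(mu_x, mu_y; sigma) over the core
  feature map, a 16-vector of feature weights, a bias, and a softplus.

Temporal kernels are parameterised as truncated Fourier series (k = 7 and
k = 3 sine/cosine pairs for the two layers) on a unit grid, shared within a
recording up to a learnable time-stretch tau, and masked by a logistic
envelope.  The linearised (LN) variant replaces both ELUs by the identity,
making the whole core affine.

Forward and backward passes are written out by hand (there is no autograd
here); gradients are exercised against finite differences in the test
suite.  All convolutions use a "valid in time" convention: an output at
index t depends on input frames t .. t+30, so predictions align with the
last frame of the receptive window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .stimuli import CANVAS

_BN_EPS = 1e-5


@dataclass
class CoreConfig:
    n_features: tuple[int, int] = (16, 16)
    kernel1_space: int = 11
    kernel1_time: int = 21
    kernel2_space: int = 5
    kernel2_time: int = 11
    fourier_k: tuple[int, int] = (7, 3)
    nonlinearity: str = "elu"  # "elu" (CNN) or "identity" (LN variant)
    batch_norm: bool = True
    #: include the harmonic index j in the Fourier phase (the stated
    #: "first k sines and cosines"); off reproduces the degenerate
    #: single-frequency form
    harmonics: bool = True
    #: (a, b) in the logistic envelope sigmoid(t + a*b*tau)
    envelope_constants: tuple[float, float] = (21.0, 0.95)

    def __post_init__(self) -> None:
        for length, k in zip((self.kernel1_time, self.kernel2_time), self.fourier_k):
            if k > length // 3:
                raise ValueError(
                    f"fourier order {k} exceeds floor(length/3) = {length // 3}"
                )

    @property
    def temporal_support(self) -> int:
        return self.kernel1_time + self.kernel2_time - 1


def default_fourier_k(length: int) -> int:
    """Fourier order keeping the kernel well under the Nyquist limit."""
    return length // 3


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def temporal_kernel(
    alpha: np.ndarray,
    beta: np.ndarray,
    tau: float,
    length: int,
    harmonics: bool = True,
    envelope_constants: tuple[float, float] = (21.0, 0.95),
) -> np.ndarray:
    """Fourier-parameterised temporal kernel(s).

    ``alpha``/``beta`` have shape [..., k]; the result has shape
    [..., length].  The kernel is
    ``w = sum_j alpha_j sin(2 pi j tau t eps) + beta_j cos(2 pi j tau t eps)``
    on a unit grid t of ``length`` steps, with the logistic envelope
    ``eps = sigmoid(t + a * b * tau)``.
    """
    if tau <= 0:
        raise ValueError("stretch factor tau must be positive")
    alpha = np.asarray(alpha)
    beta = np.asarray(beta)
    k = alpha.shape[-1]
    t = np.linspace(0.0, 1.0, length)
    a, b = envelope_constants
    eps = _sigmoid(t + a * b * tau)
    j = np.arange(1, k + 1) if harmonics else np.ones(k)
    phase = 2.0 * np.pi * j[:, None] * tau * t[None, :] * eps[None, :]  # [k, L]
    return np.einsum("...k,kl->...l", alpha, np.sin(phase)) + np.einsum(
        "...k,kl->...l", beta, np.cos(phase)
    )


def _temporal_kernel_grads(alpha, beta, tau, length, harmonics, envelope_constants):
    """Kernel plus the partials needed for backprop (w, sin, cos, dphase/dtau)."""
    k = alpha.shape[-1]
    t = np.linspace(0.0, 1.0, length)
    a, b = envelope_constants
    eps = _sigmoid(t + a * b * tau)
    deps_dtau = eps * (1.0 - eps) * a * b
    j = np.arange(1, k + 1) if harmonics else np.ones(k)
    phase = 2.0 * np.pi * j[:, None] * t[None, :] * tau * eps[None, :]
    dphase_dtau = 2.0 * np.pi * j[:, None] * t[None, :] * (
        eps[None, :] + tau * deps_dtau[None, :]
    )
    sin, cos = np.sin(phase), np.cos(phase)
    w = np.einsum("fk,kl->fl", alpha, sin) + np.einsum("fk,kl->fl", beta, cos)
    return w, sin, cos, dphase_dtau


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def readout_grid(shape=CANVAS, kernel1_space: int = 11) -> tuple[np.ndarray, np.ndarray]:
    """Centred pixel coordinates (x per column, y per row) of core-grid nodes.

    Core node (i, j) sees the stimulus patch centred at canvas pixel
    (i + K//2, j + K//2); coordinates are reported relative to the canvas
    centre so a readout at (0, 0) sits in the middle of the stimulus.
    """
    H, W = shape
    off = kernel1_space // 2
    Hc, Wc = H - kernel1_space + 1, W - kernel1_space + 1
    ys = np.arange(Hc) + off - (H - 1) / 2.0
    xs = np.arange(Wc) + off - (W - 1) / 2.0
    return xs, ys


class CoreReadout:
    """One core+readout network with hand-written forward/backward passes.

    Parameters live in ``self.params`` (a dict of float64 arrays); batch
    norm running statistics live in ``self.buffers``.  ``n_neurons`` is the
    number of readouts sharing the core.
    """

    def __init__(
        self,
        config: CoreConfig,
        n_neurons: int,
        seed: int = 0,
        canvas: tuple[int, int] = CANVAS,
        dtype=np.float64,
    ) -> None:
        self.config = config
        self.n_neurons = n_neurons
        self.canvas = canvas
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        F1, F2 = config.n_features
        k1, k2 = config.fourier_k
        Ks1, Ks2 = config.kernel1_space, config.kernel2_space
        self.params = {
            "S1": 0.1 * rng.standard_normal((F1, 2, Ks1, Ks1)),
            "alpha1": 0.3 * rng.standard_normal((F1, k1)),
            "beta1": 0.3 * rng.standard_normal((F1, k1)),
            "S2": 0.1 * rng.standard_normal((F2, F1, Ks2, Ks2)),
            "alpha2": 0.3 * rng.standard_normal((F2, k2)),
            "beta2": 0.3 * rng.standard_normal((F2, k2)),
            "tau": np.array(1.0),
            "bn1_gamma": np.ones(F1),
            "bn1_beta": np.zeros(F1),
            "bn2_gamma": np.ones(F2),
            "bn2_beta": np.zeros(F2),
            "mu": 2.0 * rng.standard_normal((n_neurons, 2)),  # (x, y), centred px
            "log_sigma": np.full(n_neurons, np.log(2.5)),
            "W": 0.1 * rng.standard_normal((n_neurons, F2)),
            "bias": np.zeros(n_neurons),
        }
        self.buffers = {
            "bn1_mean": np.zeros(F1),
            "bn1_var": np.ones(F1),
            "bn2_mean": np.zeros(F2),
            "bn2_var": np.ones(F2),
        }
        if self.dtype != np.float64:
            self.params = {k: v.astype(self.dtype) for k, v in self.params.items()}
            self.buffers = {k: v.astype(self.dtype) for k, v in self.buffers.items()}
        self.bn_momentum = 0.1
        self.seed = seed
        self._xs, self._ys = readout_grid(canvas, config.kernel1_space)

    # ------------------------------------------------------------------ utils
    @property
    def time_offset(self) -> int:
        """Output index t corresponds to input frame t + time_offset."""
        return self.config.temporal_support - 1

    def copy(self) -> "CoreReadout":
        other = CoreReadout(self.config, self.n_neurons, seed=self.seed,
                            canvas=self.canvas, dtype=self.dtype)
        other.params = {k: v.copy() for k, v in self.params.items()}
        other.buffers = {k: v.copy() for k, v in self.buffers.items()}
        return other

    def full_kernels(self, layer: int) -> np.ndarray:
        """Assembled space x time kernels (rank-1 per kernel by construction)."""
        cfg = self.config
        if layer == 1:
            w = temporal_kernel(self.params["alpha1"], self.params["beta1"],
                                float(self.params["tau"]), cfg.kernel1_time,
                                cfg.harmonics, cfg.envelope_constants)
            return self.params["S1"][..., None] * w[:, None, None, None, :]
        w = temporal_kernel(self.params["alpha2"], self.params["beta2"],
                            float(self.params["tau"]), cfg.kernel2_time,
                            cfg.harmonics, cfg.envelope_constants)
        return self.params["S2"][..., None] * w[:, None, None, None, :]

    def readout_density(self) -> np.ndarray:
        """Gaussian readout masks over the core grid, [N, Hc, Wc]."""
        mu = self.params["mu"]
        sigma = np.exp(self.params["log_sigma"])
        dx = self._xs[None, None, :] - mu[:, 0, None, None]
        dy = self._ys[None, :, None] - mu[:, 1, None, None]
        s2 = sigma[:, None, None] ** 2
        return np.exp(-(dx**2 + dy**2) / (2 * s2)) / (2 * np.pi * s2)

    # ---------------------------------------------------------------- forward
    def forward(self, x: np.ndarray, train: bool = False, cache_out: bool = False):
        """Predict rates for an input [B, 2, T, H, W] (or [2, T, H, W]).

        Returns ``pred`` of shape [B, N, T - temporal_support + 1] (squeezed
        to [N, T'] for unbatched input), and a cache for ``backward`` when
        ``cache_out`` is true.
        """
        squeeze = x.ndim == 4
        if squeeze:
            x = x[None]
        x = np.ascontiguousarray(x, dtype=self.dtype)
        B, C, T, H, W = x.shape
        cfg = self.config
        if (H, W) != self.canvas:
            raise ValueError(f"spatial size {(H, W)} != canvas {self.canvas}")
        if T < cfg.temporal_support:
            raise ValueError(
                f"chunk length {T} below temporal support {cfg.temporal_support}"
            )
        p = self.params
        tau = float(p["tau"])

        # ---- layer 1
        w1, sin1, cos1, dph1 = _temporal_kernel_grads(
            p["alpha1"], p["beta1"], tau, cfg.kernel1_time, cfg.harmonics,
            cfg.envelope_constants)
        xp = sliding_window_view(x, (cfg.kernel1_space, cfg.kernel1_space),
                                 axis=(3, 4))  # [B,C,T,Hc,Wc,Ks,Ks]
        y1 = np.einsum("bctijuv,fcuv->bftij", xp, p["S1"], optimize=True)
        y1w = sliding_window_view(y1, cfg.kernel1_time, axis=2)
        y2 = np.einsum("bftijd,fd->bftij", y1w, w1, optimize=True)
        y3, bn1 = self._bn_forward(y2, "bn1", train)
        z1 = _elu(y3) if cfg.nonlinearity == "elu" else y3

        # ---- layer 2
        pad = cfg.kernel2_space // 2
        z1p = np.pad(z1, ((0, 0), (0, 0), (0, 0), (pad, pad), (pad, pad)))
        w2, sin2, cos2, dph2 = _temporal_kernel_grads(
            p["alpha2"], p["beta2"], tau, cfg.kernel2_time, cfg.harmonics,
            cfg.envelope_constants)
        zp = sliding_window_view(z1p, (cfg.kernel2_space, cfg.kernel2_space),
                                 axis=(3, 4))
        y4 = np.einsum("bftijuv,gfuv->bgtij", zp, p["S2"], optimize=True)
        y4w = sliding_window_view(y4, cfg.kernel2_time, axis=2)
        y5 = np.einsum("bgtijd,gd->bgtij", y4w, w2, optimize=True)
        y6, bn2 = self._bn_forward(y5, "bn2", train)
        core = _elu(y6) if cfg.nonlinearity == "elu" else y6

        # ---- readout
        D = self.readout_density()
        R = p["W"][:, :, None, None] * D[:, None, :, :]  # [N, F2, Hc, Wc]
        pre = np.einsum("bgtij,ngij->bnt", core, R, optimize=True) + p["bias"][
            None, :, None
        ]
        pred = softplus(pre)

        cache = None
        if cache_out:
            cache = dict(
                x=x, y1=y1, y2=y2, y3=y3, z1=z1, y4=y4, y5=y5, y6=y6, core=core,
                pre=pre, bn1=bn1, bn2=bn2, w1=w1, w2=w2,
                sin1=sin1, cos1=cos1, dph1=dph1, sin2=sin2, cos2=cos2, dph2=dph2,
                D=D, squeeze=squeeze,
            )
        if squeeze:
            pred = pred[0]
        return (pred, cache) if cache_out else pred

    # ------------------------------------------------------------- batch norm
    def _bn_forward(self, y, name, train):
        if not self.config.batch_norm:
            return y, None
        gamma = self.params[f"{name}_gamma"][None, :, None, None, None]
        beta = self.params[f"{name}_beta"][None, :, None, None, None]
        if train:
            mean = y.mean(axis=(0, 2, 3, 4))
            var = y.var(axis=(0, 2, 3, 4))
            self.buffers[f"{name}_mean"] *= 1 - self.bn_momentum
            self.buffers[f"{name}_mean"] += self.bn_momentum * mean
            self.buffers[f"{name}_var"] *= 1 - self.bn_momentum
            self.buffers[f"{name}_var"] += self.bn_momentum * var
        else:
            mean = self.buffers[f"{name}_mean"]
            var = self.buffers[f"{name}_var"]
        inv = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (y - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        out = gamma * xhat + beta
        return out, dict(xhat=xhat, inv=inv, train=train)

    def _bn_backward(self, dout, bn, name, grads):
        if not self.config.batch_norm:
            return dout
        gamma = self.params[f"{name}_gamma"]
        xhat, inv = bn["xhat"], bn["inv"]
        grads[f"{name}_gamma"] = np.einsum("bftij,bftij->f", dout, xhat)
        grads[f"{name}_beta"] = dout.sum(axis=(0, 2, 3, 4))
        g = gamma[None, :, None, None, None] * inv[None, :, None, None, None]
        if not bn["train"]:
            return dout * g
        m = dout[:, 0].size  # elements per channel
        mean_d = dout.mean(axis=(0, 2, 3, 4))
        mean_dx = np.einsum("bftij,bftij->f", dout, xhat) / m
        return g * (
            dout
            - mean_d[None, :, None, None, None]
            - xhat * mean_dx[None, :, None, None, None]
        )

    # --------------------------------------------------------------- backward
    def backward(self, dpred: np.ndarray, cache: dict, compute_dx: bool = False):
        """Gradients of a scalar loss given dL/dpred.

        Returns ``(grads, dx)``; ``dx`` (same shape as the input) is only
        computed on request -- it is the quantity the MEI ascent needs.
        """
        cfg = self.config
        p = self.params
        if cache["squeeze"] and dpred.ndim == 2:
            dpred = dpred[None]
        grads: dict[str, np.ndarray] = {}

        dpre = dpred * _sigmoid(cache["pre"])
        grads["bias"] = dpre.sum(axis=(0, 2))
        core, D = cache["core"], cache["D"]
        # readout
        pooled = np.einsum("bgtij,nij->bngt", core, D, optimize=True)
        grads["W"] = np.einsum("bnt,bngt->ng", dpre, pooled, optimize=True)
        dD = np.einsum("bnt,bgtij,ng->nij", dpre, core, p["W"], optimize=True)
        sigma = np.exp(p["log_sigma"])
        dx_ = self._xs[None, None, :] - p["mu"][:, 0, None, None]
        dy_ = self._ys[None, :, None] - p["mu"][:, 1, None, None]
        s2 = sigma[:, None, None] ** 2
        q = (dx_**2 + dy_**2) / (2 * s2)
        grads["mu"] = np.stack(
            [
                np.einsum("nij,nij->n", dD, D * dx_ / s2),
                np.einsum("nij,nij->n", dD, D * dy_ / s2),
            ],
            axis=1,
        )
        grads["log_sigma"] = np.einsum("nij,nij->n", dD, D * (2 * q - 2))
        dcore = np.einsum("bnt,ng,nij->bgtij", dpre, p["W"], D, optimize=True)

        # ---- layer 2 backward
        if cfg.nonlinearity == "elu":
            dcore = dcore * _elu_grad(cache["y6"])
        dy5 = self._bn_backward(dcore, cache["bn2"], "bn2", grads)
        dy4, dw2 = self._temporal_backward(dy5, cache["y4"], cache["w2"],
                                           cfg.kernel2_time)
        grads["alpha2"] = np.einsum("fl,kl->fk", dw2, cache["sin2"])
        grads["beta2"] = np.einsum("fl,kl->fk", dw2, cache["cos2"])
        dtau2 = np.einsum(
            "fl,fl->",
            dw2,
            np.einsum("fk,kl->fl", p["alpha2"], cache["cos2"] * cache["dph2"])
            - np.einsum("fk,kl->fl", p["beta2"], cache["sin2"] * cache["dph2"]),
        )
        pad = cfg.kernel2_space // 2
        z1p = np.pad(cache["z1"],
                     ((0, 0), (0, 0), (0, 0), (pad, pad), (pad, pad)))
        zp = sliding_window_view(z1p, (cfg.kernel2_space, cfg.kernel2_space),
                                 axis=(3, 4))
        grads["S2"] = np.einsum("bgtij,bftijuv->gfuv", dy4, zp, optimize=True)
        dz1p = self._spatial_transpose(dy4, p["S2"])
        dz1 = dz1p[:, :, :, pad:-pad, pad:-pad] if pad else dz1p

        # ---- layer 1 backward
        if cfg.nonlinearity == "elu":
            dz1 = dz1 * _elu_grad(cache["y3"])
        dy2 = self._bn_backward(dz1, cache["bn1"], "bn1", grads)
        dy1, dw1 = self._temporal_backward(dy2, cache["y1"], cache["w1"],
                                           cfg.kernel1_time)
        grads["alpha1"] = np.einsum("fl,kl->fk", dw1, cache["sin1"])
        grads["beta1"] = np.einsum("fl,kl->fk", dw1, cache["cos1"])
        dtau1 = np.einsum(
            "fl,fl->",
            dw1,
            np.einsum("fk,kl->fl", p["alpha1"], cache["cos1"] * cache["dph1"])
            - np.einsum("fk,kl->fl", p["beta1"], cache["sin1"] * cache["dph1"]),
        )
        grads["tau"] = np.array(dtau1 + dtau2)
        xp = sliding_window_view(cache["x"],
                                 (cfg.kernel1_space, cfg.kernel1_space),
                                 axis=(3, 4))
        grads["S1"] = np.einsum("bftij,bctijuv->fcuv", dy1, xp, optimize=True)

        dx = None
        if compute_dx:
            dx = self._spatial_transpose(dy1, p["S1"])
            if cache["squeeze"]:
                dx = dx[0]
        if not self.config.batch_norm:
            for name in ("bn1", "bn2"):
                grads[f"{name}_gamma"] = np.zeros_like(p[f"{name}_gamma"])
                grads[f"{name}_beta"] = np.zeros_like(p[f"{name}_beta"])
        return grads, dx

    @staticmethod
    def _temporal_backward(dy, y_in, w, L):
        """Backward through y[t] = sum_d w[f,d] y_in[t+d]."""
        yw = sliding_window_view(y_in, L, axis=2)
        dw = np.einsum("bftij,bftijd->fd", dy, yw, optimize=True)
        dy_pad = np.pad(dy, ((0, 0), (0, 0), (L - 1, L - 1), (0, 0), (0, 0)))
        dyw = sliding_window_view(dy_pad, L, axis=2)
        dy_in = np.einsum("bftijd,fd->bftij", dyw, w[:, ::-1], optimize=True)
        return dy_in, dw

    @staticmethod
    def _spatial_transpose(dy, S):
        """Backward through a valid spatial conv; returns dL/d(input).

        ``dy`` is [B, F, T, I, J], ``S`` is [F, C, Kh, Kw]; the result has
        spatial size (I + Kh - 1, J + Kw - 1).  Implemented as a scatter-add
        over kernel offsets to avoid materialising padded window tensors.
        """
        B, F, T, I, J = dy.shape
        _, C, Kh, Kw = S.shape
        tmp = np.tensordot(dy, S, axes=([1], [0]))  # [B,T,I,J,C,Kh,Kw]
        dx = np.zeros((B, C, T, I + Kh - 1, J + Kw - 1), dtype=dy.dtype)
        for u in range(Kh):
            for v in range(Kw):
                dx[:, :, :, u:u + I, v:v + J] += tmp[..., u, v].transpose(
                    0, 4, 1, 2, 3
                )
        return dx


def poisson_loss(pred: np.ndarray, target: np.ndarray, average: bool = False):
    """Poisson negative log-likelihood sum(pred - target*log(pred)).

    Returns ``(loss, dloss/dpred)``.  Predictions must be strictly positive.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if np.any(pred <= 0):
        raise ValueError("Poisson loss requires strictly positive predictions")
    loss = float(np.sum(pred - target * np.log(pred)))
    grad = 1.0 - target / pred
    if average:
        loss /= pred.size
        grad = grad / pred.size
    return loss, grad


class Adam:
    """Adam optimiser over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float = 0.01, betas=(0.9, 0.999),
                 eps: float = 1e-8, lr_scale: dict | None = None):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        #: per-parameter learning-rate multipliers; position-like parameters
        #: (readout centres, in pixels) need larger steps than weights
        self.lr_scale = lr_scale or {}
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            lr = self.lr * self.lr_scale.get(k, 1.0)
            params[k] = params[k] - lr * mhat / (np.sqrt(vhat) + self.eps)
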