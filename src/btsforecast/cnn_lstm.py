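"""Multi-channel conv-LSTM forecaster with self-adaptive pre-training.

A deliberately small network: a one-dimensional temporal convolution layer
(valid cross-correlation over the lookback window, shared across channels)
feeds an LSTM whose final hidden state is mapped to a scalar one-step
forecast by a linear head.  Training is full-batch gradient descent on mean
squared error — deterministic under a seed — with analytic gradients written
out below and verified against finite differences in the test suite.

Self-adaptive pre-training (SaPt) warm-starts the joint model by training on
one input channel at a time (the others zero-masked), with the epoch count
of each stage adapted by early stopping on validation loss, before joint
fine-tuning on all channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .dataset import SupervisedSet
from .pso import PsoConfig, PsoResult, pso_optimize


class TrainingError(RuntimeError):
    """Divergence during training; message carries the epoch index."""


@dataclass(frozen=True)
class CnnLstmSpec:
    """Hyperparameters of the conv-LSTM forecaster.

    n_epochs — training epochs of full-batch gradient descent;
    n_hidden — LSTM hidden units;
    learning_rate — fixed step size of the gradient method;
    n_kernels / kernel_width — conv layer shape; the layer is a linear
    filter bank by default (the convolution as printed carries no
    activation), with an optional ReLU behind ``conv_relu``;
    use_conv — when False the LSTM consumes the raw channels directly
    (the conv-ablation variant).
    """

    n_epochs: int = 150
    n_hidden: int = 16
    learning_rate: float = 0.01
    n_kernels: int = 16
    kernel_width: int = 3
    use_conv: bool = True
    conv_relu: bool = False
    grad_clip: float = 5.0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def conv1d(block: np.ndarray, kernels: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    """Valid cross-channel temporal convolution (no kernel flip).

    block: (B, C, T) or (C, T); kernels: (K, C, w).  Output (B, K, T-w+1):
    C[k, j] = sum_c sum_u W[k, c, u] * X[c, j+u]  (+ bias[k]).
    """
    X = np.asarray(block, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    K, C, w = kernels.shape
    if X.shape[1] != C:
        raise ValueError("channel count mismatch between block and kernels")
    if w < 1 or w > X.shape[2]:
        raise ValueError("kernel width must satisfy 1 <= width <= T")
    Xw = sliding_window_view(X, w, axis=2)  # (B, C, Tc, w)
    F = np.einsum("bcjw,kcw->bkj", Xw, kernels)
    if bias is not None:
        F += bias[None, :, None]
    return F[0] if single else F


@dataclass
class CnnLstmModel:
    """Weights plus spec; created via :func:`init_model`."""

    spec: CnnLstmSpec
    n_channels: int
    Wc: np.ndarray  # (K, C, w) conv kernels
    bc: np.ndarray  # (K,)
    Wx: np.ndarray  # (4H, K_in) input-to-gate weights, gate order i,f,g,o
    Wh: np.ndarray  # (4H, H)
    b: np.ndarray   # (4H,)
    v: np.ndarray   # (H,) head weights
    b_out: float

    def params(self) -> list[np.ndarray]:
        return [self.Wc, self.bc, self.Wx, self.Wh, self.b, self.v]

    def copy(self) -> "CnnLstmModel":
        return CnnLstmModel(
            spec=self.spec, n_channels=self.n_channels,
            Wc=self.Wc.copy(), bc=self.bc.copy(), Wx=self.Wx.copy(),
            Wh=self.Wh.copy(), b=self.b.copy(), v=self.v.copy(), b_out=self.b_out,
        )


def init_model(spec: CnnLstmSpec, n_channels: int, seed: int = 0) -> CnnLstmModel:
    """Seeded scaled-uniform initialization; forget-gate bias starts at 1."""
    rng = np.random.default_rng(seed)
    H = spec.n_hidden
    K_in = spec.n_kernels if spec.use_conv else n_channels
    w = spec.kernel_width

    def u(shape, fan_in):
        s = 1.0 / np.sqrt(max(fan_in, 1))
        return rng.uniform(-s, s, size=shape)

    Wc = u((spec.n_kernels, n_channels, w), n_channels * w)
    bc = np.zeros(spec.n_kernels)
    Wx = u((4 * H, K_in), K_in)
    Wh = u((4 * H, H), H)
    b = np.zeros(4 * H)
    b[H : 2 * H] = 1.0  # forget gate
    v = u(H, H)
    return CnnLstmModel(spec=spec, n_channels=n_channels, Wc=Wc, bc=bc,
                        Wx=Wx, Wh=Wh, b=b, v=v, b_out=0.0)


def _forward(model: CnnLstmModel, X: np.ndarray, cache: bool = False):
    """Forward pass for a batch X (B, C, T) -> predictions (B,)."""
    spec = model.spec
    H = spec.n_hidden
    if spec.use_conv:
        # im2col: (B, Tc, C*w) contiguous, so the convolution is one matmul
        Xw = sliding_window_view(X, spec.kernel_width, axis=2)
        B_, C_, Tc_, w_ = Xw.shape
        Xcol = np.ascontiguousarray(Xw.transpose(0, 2, 1, 3)).reshape(B_, Tc_, C_ * w_)
        Wcf = model.Wc.reshape(model.Wc.shape[0], -1)
        Fpre = (Xcol @ Wcf.T).transpose(0, 2, 1) + model.bc[None, :, None]
        F = np.maximum(Fpre, 0.0) if spec.conv_relu else Fpre
    else:
        Xcol, Fpre, F = None, None, X
    B, _, Tc = F.shape
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    steps = []
    for t in range(Tc):
        x_t = F[:, :, t]
        z = x_t @ model.Wx.T + h @ model.Wh.T + model.b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        if cache:
            steps.append((x_t, h, c, i, f, g, o, c_new, tanh_c))
        h, c = h_new, c_new
    yhat = h @ model.v + model.b_out
    if cache:
        return yhat, (Xcol, Fpre, F, steps, h)
    return yhat


def predict_multi(model: CnnLstmModel, sset: SupervisedSet) -> np.ndarray:
    """One forecast per supervised sample, chronological order."""
    if sset.channels != model.n_channels:
        raise ValueError(
            f"model expects {model.n_channels} channels, got {sset.channels}"
        )
    return np.asarray(_forward(model, sset.inputs), dtype=float)


def _backward(model: CnnLstmModel, X: np.ndarray, y: np.ndarray):
    """MSE loss and analytic gradients for the full batch."""
    spec = model.spec
    H = spec.n_hidden
    yhat, (Xcol, Fpre, F, steps, h_last) = _forward(model, X, cache=True)
    B = y.size
    resid = yhat - y
    loss = float(resid @ resid) / B

    d_yhat = 2.0 * resid / B
    g_v = h_last.T @ d_yhat
    g_bout = float(d_yhat.sum())
    dh = d_yhat[:, None] * model.v[None, :]
    dc = np.zeros_like(dh)

    g_Wx = np.zeros_like(model.Wx)
    g_Wh = np.zeros_like(model.Wh)
    g_b = np.zeros_like(model.b)
    dF = np.zeros_like(F)

    for t in range(len(steps) - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, g, o, c_new, tanh_c = steps[t]
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c**2)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dc = dc * f
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
            axis=1,
        )
        g_Wx += dz.T @ x_t
        g_Wh += dz.T @ h_prev
        g_b += dz.sum(axis=0)
        dF[:, :, t] = dz @ model.Wx
        dh = dz @ model.Wh

    if spec.use_conv:
        if spec.conv_relu:
            dF = dF * (Fpre > 0.0)
        K = model.Wc.shape[0]
        dFt = dF.transpose(1, 0, 2).reshape(K, -1)  # (K, B*Tc)
        g_Wc = (dFt @ Xcol.reshape(-1, Xcol.shape[-1])).reshape(model.Wc.shape)
        g_bc = dF.sum(axis=(0, 2))
    else:
        g_Wc = np.zeros_like(model.Wc)
        g_bc = np.zeros_like(model.bc)
    return loss, (g_Wc, g_bc, g_Wx, g_Wh, g_b, g_v, g_bout)


def _sgd_step(model: CnnLstmModel, grads, lr: float, clip: float) -> None:
    names = ["Wc", "bc", "Wx", "Wh", "b", "v"]
    gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads[:-1]) + grads[-1] ** 2)
    scale = lr if gnorm <= clip else lr * clip / gnorm
    for name, g in zip(names, grads[:-1]):
        setattr(model, name, getattr(model, name) - scale * g)
    model.b_out -= scale * grads[-1]


def mse_loss(model: CnnLstmModel, sset: SupervisedSet) -> float:
    pred = _forward(model, sset.inputs)
    r = pred - sset.targets
    return float(r @ r) / sset.targets.size


def fit_cnn_lstm(
    train: SupervisedSet,
    val: SupervisedSet | None,
    spec: CnnLstmSpec,
    seed: int = 0,
    model: CnnLstmModel | None = None,
) -> tuple[CnnLstmModel, dict]:
    """Train by full-batch gradient descent for ``spec.n_epochs`` epochs.

    An existing ``model`` (e.g. a SaPt warm start) is fine-tuned in place of
    a fresh initialization.  Returns the model and a history dict with
    per-epoch train (and validation) loss.  Raises :class:`TrainingError`
    on divergence, naming the epoch.
    """
    if train.n_samples == 0:
        raise ValueError("empty training set")
    m = model.copy() if model is not None else init_model(spec, train.channels, seed)
    if spec.n_epochs == 0:
        warnings.warn("0 training epochs: returning initialization forecasts", stacklevel=2)
        return m, {"train_loss": [], "val_loss": []}
    hist: dict = {"train_loss": [], "val_loss": []}
    for epoch in range(spec.n_epochs):
        loss, grads = _backward(m, train.inputs, train.targets)
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite training loss at epoch {epoch}")
        _sgd_step(m, grads, spec.learning_rate, spec.grad_clip)
        hist["train_loss"].append(loss)
        if val is not None:
            hist["val_loss"].append(mse_loss(m, val))
    return m, hist


def _mask_channels(sset: SupervisedSet, keep: int) -> SupervisedSet:
    X = np.zeros_like(sset.inputs)
    X[:, keep, :] = sset.inputs[:, keep, :]
    return SupervisedSet(inputs=X, targets=sset.targets,
                         lookback=sset.lookback, target_channel=sset.target_channel)


def sapt_pretrain(
    model: CnnLstmModel,
    train: SupervisedSet,
    val: SupervisedSet,
    patience: int = 5,
    max_epochs: int = 200,
    seed: int = 0,
) -> CnnLstmModel:
    """Self-adaptive per-channel pre-training.

    Channels are visited in order; for each, the network trains on that
    channel alone (others zero-masked) until validation loss has not
    improved for ``patience`` epochs (or ``max_epochs`` is hit), keeping the
    best-validation weights of the stage.  ``patience=0`` disables the whole
    procedure and returns the input model unchanged.
    """
    if patience == 0:
        return model
    m = model.copy()
    lr = m.spec.learning_rate
    for ch in range(train.channels):
        tr = _mask_channels(train, ch)
        va = _mask_channels(val, ch)
        best = m.copy()
        best_loss = mse_loss(m, va)
        since_improve = 0
        for epoch in range(max_epochs):
            loss, grads = _backward(m, tr.inputs, tr.targets)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite pre-training loss at channel {ch}, epoch {epoch}")
            _sgd_step(m, grads, lr, m.spec.grad_clip)
            vloss = mse_loss(m, va)
            if vloss < best_loss - 1e-12:
                best, best_loss, since_improve = m.copy(), vloss, 0
            else:
                since_improve += 1
                if since_improve >= patience:
                    break
        m = best
    return m


DEFAULT_CNN_BOUNDS = ((50, 300), (4, 64), (-4.0, -1.0))  # epochs, hidden, log10 lr


def tune_cnn_lstm(
    train: SupervisedSet,
    val: SupervisedSet,
    bounds=DEFAULT_CNN_BOUNDS,
    pso_config: PsoConfig | None = None,
    base_spec: CnnLstmSpec | None = None,
    seed: int = 0,
) -> tuple[CnnLstmSpec, PsoResult]:
    """Particle-swarm search over (epochs, hidden units, log10 learning rate).

    Fitness is the validation MSE of a model trained from the shared seed at
    the candidate hyperparameters.  The base spec's own setting is seeded
    into the swarm, so tuning never validates worse than the default.
    """
    base = base_spec or CnnLstmSpec()
    cfg = pso_config or PsoConfig(swarm_size=6, iterations=4)

    def objective(pos: np.ndarray) -> float:
        spec = replace(
            base,
            n_epochs=int(round(pos[0])),
            n_hidden=int(round(pos[1])),
            learning_rate=float(10.0 ** pos[2]),
        )
        try:
            m, _ = fit_cnn_lstm(train, None, spec, seed=seed)
        except TrainingError:
            return np.inf
        return mse_loss(m, val)

    default_pos = [
        float(np.clip(base.n_epochs, *bounds[0])),
        float(np.clip(base.n_hidden, *bounds[1])),
        float(np.clip(np.log10(base.learning_rate), *bounds[2])),
    ]
    result = pso_optimize(objective, bounds=bounds,
                          integer_mask=[True, True, False], config=cfg,
                          initial_positions=[default_pos])
    best = replace(
        base,
        n_epochs=int(result.best_position[0]),
        n_hidden=int(result.best_position[1]),
        learning_rate=float(10.0 ** result.best_position[2]),
    )
    return best, result
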