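"""GRU and Conv1D building blocks and the daily-pattern autoencoders.

A day of home activity is a binary matrix (time bins x sensors, default
48 x S at 30-min resolution).  Two autoencoder architectures compress it
to a latent vector:

* **GRU**: a single recurrent encoder layer reads the day bin-by-bin; the
  final hidden state is the latent code.  The decoder is a mirrored GRU
  fed the latent code at every step, with a per-step linear readout.
* **Conv1D**: two convolution + ReLU + max-pool blocks along the time axis
  followed by a dense map to the latent code; the decoder is dense
  (latent -> hidden -> logits) rather than transposed convolutions — at
  48-bin resolution the mirror buys nothing and the dense decoder keeps
  the parameter count small.

Both are trained to minimise the binary log loss of the reconstruction
(sigmoid outputs) with adam/rmsprop/sgd, deterministically given a seed.

The cell/layer forward passes are exposed as plain-numpy functions
(:func:`gru_cell_forward`, :func:`conv1d_forward`) so they can be checked
against independent oracles; the trained models use the same math through
the autodiff graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "GRUCellParams",
    "Conv1DLayerParams",
    "AEConfig",
    "EmbeddingSet",
    "gru_cell_forward",
    "conv1d_forward",
    "binary_log_loss",
    "train_autoencoder",
    "encode_days",
    "GRUAutoencoder",
    "ConvAutoencoder",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass(frozen=True)
class GRUCellParams:
    """Weights of one GRU cell.

    ``W_*`` map the input, ``U_*`` the previous hidden state; ``b_*`` are
    biases.  All recurrent matrices are square of size ``hidden_size``.
    """

    W_z: np.ndarray
    U_z: np.ndarray
    b_z: np.ndarray
    W_r: np.ndarray
    U_r: np.ndarray
    b_r: np.ndarray
    W_h: np.ndarray
    U_h: np.ndarray
    b_h: np.ndarray

    def __post_init__(self) -> None:
        h = self.U_z.shape[0]
        for U in (self.U_z, self.U_r, self.U_h):
            if U.shape != (h, h):
                raise ValueError("recurrent matrices must be square and consistent")
        for W in (self.W_z, self.W_r, self.W_h):
            if W.shape[1] != h:
                raise ValueError("input matrices must map to hidden_size")

    @property
    def hidden_size(self) -> int:
        return self.U_z.shape[0]


def gru_cell_forward(
    params: GRUCellParams, x_t: np.ndarray, h_prev: np.ndarray
) -> np.ndarray:
    """One GRU step.

    ``z = sigmoid(x W_z + h U_z + b_z)`` (update gate),
    ``r = sigmoid(x W_r + h U_r + b_r)`` (reset gate),
    ``h' = (1 - z) * h + z * tanh(x W_h + (r * h) U_h + b_h)``.

    Inputs are row vectors or (batch, dim) arrays.
    """
    x_t = np.atleast_2d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    if x_t.shape[1] != params.W_z.shape[0] or h_prev.shape[1] != params.hidden_size:
        raise ValueError("input/state dimensions do not match the cell parameters")
    z = _sigmoid(x_t @ params.W_z + h_prev @ params.U_z + params.b_z)
    r = _sigmoid(x_t @ params.W_r + h_prev @ params.U_r + params.b_r)
    cand = np.tanh(x_t @ params.W_h + (r * h_prev) @ params.U_h + params.b_h)
    h = (1.0 - z) * h_prev + z * cand
    return h


@dataclass(frozen=True)
class Conv1DLayerParams:
    """One temporal convolution layer: kernels (K, C_in, C_out), biases (C_out,)."""

    kernels: np.ndarray
    biases: np.ndarray
    pool: int = 1  # max-pool width applied after the ReLU (1 = none)

    def __post_init__(self) -> None:
        if self.kernels.ndim != 3 or self.biases.shape != (self.kernels.shape[2],):
            raise ValueError("kernels must be (K, C_in, C_out) with matching biases")

    @property
    def n_filters(self) -> int:
        return self.kernels.shape[2]


def conv1d_forward(params: Conv1DLayerParams, x: np.ndarray) -> np.ndarray:
    """Valid temporal convolution + ReLU + optional max-pool.

    ``x`` is (T, C_in) or (batch, T, C_in); output map j is
    ``ReLU(b_j + sum_i k_ij * x_i)`` with convolution along time only.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    K = params.kernels.shape[0]
    if x.shape[1] < K:
        raise ValueError("kernel longer than the input sequence")
    from numpy.lib.stride_tricks import sliding_window_view

    windows = sliding_window_view(x, K, axis=1)  # (B, To, Ci, K)
    y = np.einsum("btik,kic->btc", windows, params.kernels) + params.biases
    y = np.maximum(y, 0.0)
    if params.pool > 1:
        B, T, C = y.shape
        To = T // params.pool
        y = y[:, : To * params.pool, :].reshape(B, To, params.pool, C).max(axis=2)
    return y[0] if squeeze else y


def binary_log_loss(y: np.ndarray, y_hat: np.ndarray, eps: float = 1e-12) -> float:
    """Mean binary log loss; y_hat = 0.5 everywhere gives ln 2."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(y_hat, dtype=float), eps, 1.0 - eps)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


@dataclass(frozen=True)
class AEConfig:
    """Autoencoder configuration.

    Defaults: GRU hidden size 32 (latent = final hidden state) or Conv1D
    blocks of 16/8 filters, kernel 5, pool 2 with a dense latent of 16;
    adam, 200 epochs, batch 16.  ``latent_dim`` must compress the input.
    """

    arch: str  # "gru" | "conv1d"
    time_steps: int = 48
    n_sensors: int = 2
    hidden: int = 32
    latent_dim: int | None = None  # default: hidden (gru) or 16 (conv1d)
    conv_filters: tuple[int, int] = (16, 8)
    kernel: int = 5
    pool: int = 2
    optimizer: str = "adam"
    lr: float = 0.005
    epochs: int = 200
    batch_size: int = 16
    seed: int = 0
    loss: str = "binary_log_loss"

    def __post_init__(self) -> None:
        if self.arch not in ("gru", "conv1d"):
            raise ValueError("arch must be 'gru' or 'conv1d'")
        latent = self.resolved_latent
        if latent >= self.time_steps * self.n_sensors:
            raise ValueError("latent_dim must compress the input")

    @property
    def resolved_latent(self) -> int:
        if self.latent_dim is not None:
            return self.latent_dim
        return self.hidden if self.arch == "gru" else 16


@dataclass
class EmbeddingSet:
    """Latent vectors, one per input day."""

    dates: list
    vectors: np.ndarray  # (n_days, latent_dim)
    final_loss: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.dates) != self.vectors.shape[0]:
            raise ValueError("one vector per day required")
        if self.vectors.size and not np.isfinite(self.vectors).all():
            raise ValueError("embedding vectors must be finite")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class GRUAutoencoder:
    """Sequence autoencoder with a GRU encoder and mirrored GRU decoder."""

    def __init__(self, cfg: AEConfig):
        if cfg.arch != "gru":
            raise ValueError("config is not for the gru architecture")
        self.cfg = cfg
        H, S = cfg.hidden, cfg.n_sensors
        L = cfg.resolved_latent
        if L != H:
            raise ValueError("gru latent is the final hidden state: latent_dim == hidden")
        rng = np.random.default_rng(cfg.seed)
        P = {}
        for gate in "zrh":
            P[f"enc_W{gate}"] = _glorot(rng, S, H, (S, H))
            P[f"enc_U{gate}"] = _glorot(rng, H, H, (H, H))
            P[f"enc_b{gate}"] = np.zeros(H)
            P[f"dec_W{gate}"] = _glorot(rng, L, H, (L, H))
            P[f"dec_U{gate}"] = _glorot(rng, H, H, (H, H))
            P[f"dec_b{gate}"] = np.zeros(H)
        P["out_W"] = _glorot(rng, H, S, (H, S))
        P["out_b"] = np.zeros(S)
        self.params = {k: Tensor(v, requires_grad=True) for k, v in P.items()}

    def _gru_pass(self, prefix: str, xw, h0: Tensor, T: int):
        """Run T GRU steps given precomputed input projections.

        ``xw`` maps gate -> per-step input term: either a (B, T, H) tensor
        (sliced per step) or a single (B, H) tensor reused at every step
        (decoder fed the latent code throughout).
        """
        p = self.params
        h = h0
        outs = []
        for t in range(T):
            xz, xr, xh = (
                ad.slice_time(xw[g], t) if xw[g].data.ndim == 3 else xw[g]
                for g in "zrh"
            )
            z = (xz + h @ p[f"{prefix}_Uz"] + p[f"{prefix}_bz"]).sigmoid()
            r = (xr + h @ p[f"{prefix}_Ur"] + p[f"{prefix}_br"]).sigmoid()
            cand = (xh + (r * h) @ p[f"{prefix}_Uh"] + p[f"{prefix}_bh"]).tanh()
            h = (1.0 - z) * h + z * cand
            outs.append(h)
        return h, outs

    def loss(self, batch: np.ndarray) -> Tensor:
        """Mean reconstruction log loss of a (B, T, S) binary batch."""
        B, T, S = batch.shape
        p = self.params
        x = Tensor(batch)
        flat = x.reshape(B * T, S)
        # input projections for all steps at once: one matmul per gate
        enc_xw = {g: (flat @ p[f"enc_W{g}"]).reshape(B, T, self.cfg.hidden) for g in "zrh"}
        h0 = Tensor(np.zeros((B, self.cfg.hidden)))
        latent, _ = self._gru_pass("enc", enc_xw, h0, T)
        dec_xw = {g: latent @ p[f"dec_W{g}"] for g in "zrh"}
        _, dec_states = self._gru_pass("dec", dec_xw, Tensor(np.zeros((B, self.cfg.hidden))), T)
        total = None
        for t, h in enumerate(dec_states):
            logits = h @ self.params["out_W"] + self.params["out_b"]
            l_t = ad.bce_with_logits(logits, batch[:, t, :])
            total = l_t if total is None else total + l_t
        return total * (1.0 / T)

    def encode(self, days: np.ndarray) -> np.ndarray:
        """Latent vectors of (N, T, S) days via the plain-numpy GRU step."""
        cell = GRUCellParams(
            W_z=self.params["enc_Wz"].data, U_z=self.params["enc_Uz"].data,
            b_z=self.params["enc_bz"].data, W_r=self.params["enc_Wr"].data,
            U_r=self.params["enc_Ur"].data, b_r=self.params["enc_br"].data,
            W_h=self.params["enc_Wh"].data, U_h=self.params["enc_Uh"].data,
            b_h=self.params["enc_bh"].data,
        )
        N, T, S = days.shape
        h = np.zeros((N, self.cfg.hidden))
        for t in range(T):
            h = gru_cell_forward(cell, days[:, t, :], h)
        return h


class ConvAutoencoder:
    """Temporal-convolution encoder with a dense decoder."""

    def __init__(self, cfg: AEConfig):
        if cfg.arch != "conv1d":
            raise ValueError("config is not for the conv1d architecture")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        T, S, K = cfg.time_steps, cfg.n_sensors, cfg.kernel
        F1, F2 = cfg.conv_filters
        L = cfg.resolved_latent
        t1 = (T - K + 1) // cfg.pool
        t2 = (t1 - K + 1) // cfg.pool
        if t2 < 1:
            raise ValueError("input too short for the configured conv stack")
        self._flat = t2 * F2
        P = {
            "k1": _glorot(rng, K * S, F1, (K, S, F1)),
            "b1": np.zeros(F1),
            "k2": _glorot(rng, K * F1, F2, (K, F1, F2)),
            "b2": np.zeros(F2),
            "We": _glorot(rng, self._flat, L, (self._flat, L)),
            "be": np.zeros(L),
            "Wd1": _glorot(rng, L, self._flat, (L, self._flat)),
            "bd1": np.zeros(self._flat),
            "Wd2": _glorot(rng, self._flat, T * S, (self._flat, T * S)),
            "bd2": np.zeros(T * S),
        }
        self.params = {k: Tensor(v, requires_grad=True) for k, v in P.items()}

    def _encode_graph(self, x: Tensor) -> Tensor:
        p = self.params
        h = ad.maxpool1d(ad.conv1d(x, p["k1"], p["b1"]).relu(), self.cfg.pool)
        h = ad.maxpool1d(ad.conv1d(h, p["k2"], p["b2"]).relu(), self.cfg.pool)
        B = h.shape[0]
        return h.reshape(B, self._flat) @ p["We"] + p["be"]

    def loss(self, batch: np.ndarray) -> Tensor:
        B, T, S = batch.shape
        p = self.params
        latent = self._encode_graph(Tensor(batch))
        h = (latent @ p["Wd1"] + p["bd1"]).relu()
        logits = (h @ p["Wd2"] + p["bd2"]).reshape(B, T, S)
        return ad.bce_with_logits(logits, batch)

    def encode(self, days: np.ndarray) -> np.ndarray:
        l1 = Conv1DLayerParams(self.params["k1"].data, self.params["b1"].data, self.cfg.pool)
        l2 = Conv1DLayerParams(self.params["k2"].data, self.params["b2"].data, self.cfg.pool)
        h = conv1d_forward(l2, conv1d_forward(l1, days))
        flat = h.reshape(days.shape[0], self._flat)
        return flat @ self.params["We"].data + self.params["be"].data


def _as_day_array(days) -> tuple[np.ndarray, list]:
    """Accept an (N, T, S) array or a list of per-day 2-D arrays/frames."""
    if isinstance(days, np.ndarray):
        if days.ndim != 3:
            raise ValueError("days array must be (n_days, time_steps, n_sensors)")
        return days.astype(float), list(range(days.shape[0]))
    mats, dates = [], []
    for i, d in enumerate(days):
        arr = np.asarray(getattr(d, "data", d), dtype=float)
        mats.append(arr)
        dates.append(getattr(d, "date", i))
    return np.stack(mats), dates


def train_autoencoder(days, cfg: AEConfig):
    """Train an autoencoder on binary day matrices.

    Returns ``(model, curve)`` where ``curve`` is the per-epoch mean
    training loss (binary log loss).  Requires >= 30 days of binary input;
    raises on non-binary data or a diverging (NaN) loss.
    """
    X, _ = _as_day_array(days)
    if X.shape[0] < 30:
        raise ValueError("need at least 30 days to train")
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("binary log loss requires binary inputs (binarize upstream)")
    if X.shape[1] != cfg.time_steps or X.shape[2] != cfg.n_sensors:
        raise ValueError("day geometry does not match the configuration")

    model = GRUAutoencoder(cfg) if cfg.arch == "gru" else ConvAutoencoder(cfg)
    params = list(model.params.values())
    if cfg.optimizer == "adam":
        opt = ad.Adam(params, lr=cfg.lr)
    elif cfg.optimizer == "rmsprop":
        opt = ad.RMSProp(params, lr=cfg.lr)
    elif cfg.optimizer == "sgd":
        opt = ad.SGD(params, lr=cfg.lr)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")

    rng = np.random.default_rng(cfg.seed + 1)
    n = X.shape[0]
    curve: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            batch = X[order[i : i + cfg.batch_size]]
            loss = model.loss(batch)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged at epoch {epoch}: loss={loss.data}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        curve.append(float(np.mean(losses)))
    return model, curve


def encode_days(model, days) -> EmbeddingSet:
    """Map days through a trained encoder into an :class:`EmbeddingSet`."""
    X, dates = _as_day_array(days) if not _is_empty(days) else (None, [])
    if X is None or X.shape[0] == 0:
        latent = model.cfg.resolved_latent
        return EmbeddingSet(dates=[], vectors=np.empty((0, latent)))
    if X.shape[1] != model.cfg.time_steps or X.shape[2] != model.cfg.n_sensors:
        raise ValueError("day geometry does not match the trained encoder")
    return EmbeddingSet(dates=dates, vectors=model.encode(X))


def _is_empty(days) -> bool:
    if isinstance(days, np.ndarray):
        return days.shape[0] == 0
    return len(days) == 0
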