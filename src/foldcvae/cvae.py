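"""Convolutional variational autoencoder over contact maps.

The model compresses an M×M contact map through a stack of
convolutional layers and a dense layer into a d-dimensional Gaussian
latent (mean and log-variance heads), then mirrors the encoder with
transposed convolutions to emit per-pixel contact probabilities. The
training objective is

    L = E_r + E_l

with E_r the per-map summed binary cross entropy between the input X
and the decoded probability f(z) (averaged over the batch), and E_l the
closed-form KL divergence between the encoder's Gaussian and N(0, I)
(also batch-averaged). Sampling uses the reparameterization z = mu +
exp(log_var / 2) * eps during training; inference uses the
deterministic mean.

Spatial handling: the first two convolutional layers use stride 2 (total
downsampling 4, matching the pad-to-multiple-of-4 featurization rule);
any further layers are stride 1. All convolutions are 'same'-padded with
ReLU activations; the decoder output layer is a sigmoid.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .errors import (
    ConfigurationError,
    DataError,
    TrainingDivergedError,
)
from .featurize import ContactMapSeries, DatasetSplit

# Search-box bounds for every tunable hyperparameter.
HYPERPARAM_BOUNDS = {
    "n_conv_layers": (1, 4),
    "n_filters": (16, 125),
    "kernel": (2, 7),
    "n_dense": (32, 100),
    "latent_dim": (2, 16),
}

PROB_EPS = 1e-7  # decoded probabilities clipped to [PROB_EPS, 1 - PROB_EPS]

__all__ = [
    "CVAEHyperparams",
    "CVAEState",
    "LatentEmbedding",
    "LossTrace",
    "build_model",
    "reconstruction_loss",
    "latent_loss",
    "train",
    "encode",
    "decode",
    "save_model",
    "load_model",
    "hyperparameter_search",
    "transfer_project",
    "HYPERPARAM_BOUNDS",
]


@dataclass(frozen=True)
class CVAEHyperparams:
    n_conv_layers: int = 4
    n_filters: int = 100
    kernel: int = 5
    n_dense: int = 64
    latent_dim: int = 3
    optimizer: str = "rmsprop"
    epochs: int = 150
    learning_rate: float = 1e-3

    def __post_init__(self):
        for name, (lo, hi) in HYPERPARAM_BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigurationError(
                    f"{name}={v} outside allowed bounds [{lo}, {hi}]")
        if self.optimizer.lower() not in nn.OPTIMIZERS:
            raise ConfigurationError(
                f"optimizer must be one of {sorted(nn.OPTIMIZERS)}")
        if self.epochs < 0:
            raise ConfigurationError("epochs must be nonnegative")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")


@dataclass
class LossTrace:
    """Per-epoch loss records; total == reconstruction + latent."""

    epoch: list = field(default_factory=list)
    train_total: list = field(default_factory=list)
    train_recon: list = field(default_factory=list)
    train_latent: list = field(default_factory=list)
    val_total: list = field(default_factory=list)
    val_recon: list = field(default_factory=list)
    val_latent: list = field(default_factory=list)

    def append(self, epoch, tr, vl):
        self.epoch.append(epoch)
        self.train_total.append(tr[0]); self.train_recon.append(tr[1])
        self.train_latent.append(tr[2])
        self.val_total.append(vl[0]); self.val_recon.append(vl[1])
        self.val_latent.append(vl[2])

    def __len__(self):
        return len(self.epoch)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "epoch": self.epoch,
            "train_total": self.train_total, "train_recon": self.train_recon,
            "train_latent": self.train_latent,
            "val_total": self.val_total, "val_recon": self.val_recon,
            "val_latent": self.val_latent,
        })


@dataclass
class LatentEmbedding:
    mu: np.ndarray        # (frames, d)
    log_var: np.ndarray   # (frames, d)
    z: np.ndarray         # (frames, d), mu + exp(log_var/2) * eps

    @property
    def latent_dim(self) -> int:
        return self.mu.shape[1]


class CVAEState:
    """Architecture + weights + training trace of one CVAE."""

    def __init__(self, hyperparams: CVAEHyperparams, input_shape: tuple,
                 seed: int = 0, dtype=np.float32):
        m = input_shape[0]
        if input_shape[0] != input_shape[1]:
            raise ConfigurationError("input maps must be square")
        hp = hyperparams
        self.hyperparams = hp
        self.input_shape = tuple(input_shape)
        self.dtype = dtype
        self.trained_epochs = 0
        self.loss_trace = LossTrace()

        n_down = min(2, hp.n_conv_layers)
        factor = 2 ** n_down
        if m % factor != 0 or m < factor:
            smallest = -(-max(m, factor) // factor) * factor
            raise ConfigurationError(
                f"input size {m} incompatible with {n_down} stride-2 layers; "
                f"smallest compatible size is {smallest}")
        self.bottleneck = m // factor
        rng = np.random.default_rng(seed)

        enc: list[nn.Layer] = []
        c_in = 1
        strides = [2] * n_down + [1] * (hp.n_conv_layers - n_down)
        for s in strides:
            enc.append(nn.Conv2D(c_in, hp.n_filters, hp.kernel, s, rng, dtype))
            enc.append(nn.ReLU())
            c_in = hp.n_filters
        enc.append(nn.Flatten())
        flat = hp.n_filters * self.bottleneck ** 2
        enc.append(nn.Dense(flat, hp.n_dense, rng, dtype))
        enc.append(nn.ReLU())
        self.encoder = enc
        self.mu_head = nn.Dense(hp.n_dense, hp.latent_dim, rng, dtype)
        self.logvar_head = nn.Dense(hp.n_dense, hp.latent_dim, rng, dtype)

        dec: list[nn.Layer] = [
            nn.Dense(hp.latent_dim, hp.n_dense, rng, dtype), nn.ReLU(),
            nn.Dense(hp.n_dense, flat, rng, dtype), nn.ReLU(),
            nn.Reshape((hp.n_filters, self.bottleneck, self.bottleneck)),
        ]
        # mirror: reverse the encoder's spatial path
        out_sizes = []
        cur = self.bottleneck
        for s in reversed(strides):
            cur = cur * s
            out_sizes.append(cur)
        c = hp.n_filters
        for li, (s, osz) in enumerate(zip(reversed(strides), out_sizes)):
            last = li == hp.n_conv_layers - 1
            c_out = 1 if last else hp.n_filters
            dec.append(nn.ConvTranspose2D(c, c_out, hp.kernel, s, osz, rng, dtype))
            if not last:
                dec.append(nn.ReLU())
            c = c_out
        self.decoder = dec

    # --- plumbing -------------------------------------------------------
    @property
    def layers(self) -> list:
        return self.encoder + [self.mu_head, self.logvar_head] + self.decoder

    def _encode_batch(self, x: np.ndarray):
        h = x[:, None, :, :].astype(self.dtype)
        for layer in self.encoder:
            h = layer.forward(h)
        return self.mu_head.forward(h), self.logvar_head.forward(h)

    def _decode_batch(self, z: np.ndarray) -> np.ndarray:
        h = z.astype(self.dtype)
        for layer in self.decoder:
            h = layer.forward(h)
        return h[:, 0, :, :]  # logits

    def _backward(self, dlogits: np.ndarray, dmu_extra, dlogvar_extra, eps,
                  log_var):
        dh = dlogits[:, None, :, :].astype(self.dtype)
        for layer in reversed(self.decoder):
            dh = layer.backward(dh)
        dz = dh
        dmu = dz + dmu_extra.astype(self.dtype)
        dlv = (dz * eps * 0.5 * np.exp(0.5 * log_var)
               + dlogvar_extra).astype(self.dtype)
        dh_enc = (self.mu_head.backward(dmu)
                  + self.logvar_head.backward(dlv))
        for layer in reversed(self.encoder):
            dh_enc = layer.backward(dh_enc)


def build_model(hp: CVAEHyperparams, input_shape, seed: int = 0,
                dtype=np.float32) -> CVAEState:
    """Construct an untrained CVAE for square maps of ``input_shape``."""
    if isinstance(input_shape, int):
        input_shape = (input_shape, input_shape)
    return CVAEState(hp, tuple(input_shape), seed=seed, dtype=dtype)


def _sigmoid(x):
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def reconstruction_loss(x: np.ndarray, f_z: np.ndarray) -> float:
    """Binary cross entropy, summed per map and averaged over the batch."""
    x = np.asarray(x, dtype=np.float64)
    f = np.asarray(f_z, dtype=np.float64)
    if x.shape != f.shape:
        raise DataError(f"shape mismatch: X {x.shape} vs f(z) {f.shape}")
    f = np.clip(f, PROB_EPS, 1.0 - PROB_EPS)
    per_map = -(x * np.log(f) + (1.0 - x) * np.log(1.0 - f))
    batch = per_map.shape[0] if per_map.ndim >= 1 else 1
    return float(per_map.reshape(batch, -1).sum(axis=1).mean())


def latent_loss(mu: np.ndarray, log_var: np.ndarray) -> float:
    """KL( N(mu, exp(log_var)) || N(0, 1) ), summed over latent dims and
    averaged over the batch; zero iff mu == 0 and log_var == 0."""
    mu = np.atleast_2d(np.asarray(mu, dtype=np.float64))
    lv = np.atleast_2d(np.asarray(log_var, dtype=np.float64))
    if not (np.isfinite(mu).all() and np.isfinite(lv).all()):
        raise DataError("non-finite latent parameters")
    kl = -0.5 * (1.0 + lv - mu ** 2 - np.exp(lv)).sum(axis=1)
    return float(kl.mean())


def _check_maps(model: CVAEState, maps: ContactMapSeries):
    if (maps.size, maps.size) != model.input_shape:
        raise DataError(
            f"maps of size {maps.size}×{maps.size} do not match the model's "
            f"input shape {model.input_shape[0]}×{model.input_shape[1]}")


def _epoch_losses(model, x, rng, batch_size):
    """Forward-only pass (sampled z) returning (L, E_r, E_l)."""
    tot_r = tot_l = 0.0
    n = x.shape[0]
    for s in range(0, n, batch_size):
        xb = x[s:s + batch_size]
        mu, lv = model._encode_batch(xb)
        eps = rng.standard_normal(mu.shape).astype(model.dtype)
        z = mu + np.exp(0.5 * lv) * eps
        f = _sigmoid(model._decode_batch(z))
        tot_r += reconstruction_loss(xb, f) * xb.shape[0]
        tot_l += latent_loss(mu, lv) * xb.shape[0]
    er, el = tot_r / n, tot_l / n
    return er + el, er, el


def train(model: CVAEState, maps: ContactMapSeries, split: DatasetSplit,
          seed: int = 0, epochs: int | None = None,
          early_stop_patience: int | None = None,
          early_stop_tol: float = 1e-3,
          callback=None) -> CVAEState:
    """Minibatch training of L = E_r + E_l; modifies ``model`` in place.

    Batch size is ceil(|train| / 100). The per-epoch trace records
    training losses (running average over minibatches, sampled z) and
    validation losses. ``early_stop_patience`` (epochs without the
    validation total improving by more than ``early_stop_tol``) is off by
    default. Fully reproducible for a fixed seed.
    """
    _check_maps(model, maps)
    if split.n_frames != maps.n_frames:
        raise ConfigurationError("split does not cover the map series")
    if len(split.train_idx) == 0:
        raise ConfigurationError("empty training set")
    n_epochs = model.hyperparams.epochs if epochs is None else epochs
    if n_epochs < 0:
        raise ConfigurationError("epochs must be nonnegative")
    if n_epochs == 0:
        return model

    x_train = maps.as_float(model.dtype)[split.train_idx]
    x_val = maps.as_float(model.dtype)[split.val_idx]
    n_train = x_train.shape[0]
    batch_size = max(1, math.ceil(n_train / 100))
    rng = np.random.default_rng(seed)
    opt = nn.make_optimizer(model.hyperparams.optimizer,
                            model.hyperparams.learning_rate)

    best_val = np.inf
    stall = 0
    for epoch in range(1, n_epochs + 1):
        order = rng.permutation(n_train)
        tot_r = tot_l = 0.0
        for s in range(0, n_train, batch_size):
            idx = order[s:s + batch_size]
            xb = x_train[idx]
            b = xb.shape[0]
            mu, lv = model._encode_batch(xb)
            eps = rng.standard_normal(mu.shape).astype(model.dtype)
            z = mu + np.exp(0.5 * lv) * eps
            logits = model._decode_batch(z)
            f = _sigmoid(logits)
            er = reconstruction_loss(xb, f)
            el = latent_loss(mu, lv)
            if not np.isfinite(er + el):
                raise TrainingDivergedError(epoch)
            # gradients of the batch-mean objective
            dlogits = (f - xb).astype(np.float64) / b
            dmu_kl = mu.astype(np.float64) / b
            dlv_kl = 0.5 * (np.exp(lv.astype(np.float64)) - 1.0) / b
            model._backward(dlogits, dmu_kl, dlv_kl, eps, lv)
            opt.step(model.layers)
            tot_r += er * b
            tot_l += el * b
        tr = (tot_r / n_train + tot_l / n_train,
              tot_r / n_train, tot_l / n_train)
        val_rng = np.random.default_rng(rng.integers(2 ** 31))
        if len(x_val):
            vl = _epoch_losses(model, x_val, val_rng, max(batch_size, 64))
        else:
            vl = (np.nan, np.nan, np.nan)
        model.loss_trace.append(model.trained_epochs + epoch, tr, vl)
        if callback is not None:
            callback(epoch, tr, vl)
        if early_stop_patience is not None and len(x_val):
            if vl[0] < best_val - early_stop_tol:
                best_val = vl[0]
                stall = 0
            else:
                stall += 1
                if stall >= early_stop_patience:
                    break
    model.trained_epochs += epoch
    return model


def encode(model: CVAEState, maps, seed: int = 0,
           chunk: int = 512) -> LatentEmbedding:
    """Latent mean/log-variance plus one reparameterized sample per frame."""
    if isinstance(maps, ContactMapSeries):
        _check_maps(model, maps)
        x = maps.as_float(model.dtype)
    else:
        x = np.asarray(maps, dtype=model.dtype)
        if x.shape[1:] != model.input_shape:
            raise DataError(f"maps shape {x.shape[1:]} != {model.input_shape}")
    mus, lvs = [], []
    for s in range(0, x.shape[0], chunk):
        mu, lv = model._encode_batch(x[s:s + chunk])
        mus.append(mu)
        lvs.append(lv)
    mu = np.concatenate(mus).astype(np.float64)
    lv = np.concatenate(lvs).astype(np.float64)
    eps = np.random.default_rng(seed).standard_normal(mu.shape)
    return LatentEmbedding(mu=mu, log_var=lv, z=mu + np.exp(0.5 * lv) * eps)


def decode(model: CVAEState, z: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Per-pixel contact probabilities strictly inside (0, 1)."""
    z = np.asarray(z)
    if z.ndim == 1:
        z = z[None]
    if z.shape[1] != model.hyperparams.latent_dim:
        raise DataError(
            f"z has width {z.shape[1]}, expected {model.hyperparams.latent_dim}")
    out = []
    for s in range(0, z.shape[0], chunk):
        logits = model._decode_batch(z[s:s + chunk])
        out.append(_sigmoid(logits))
    return np.clip(np.concatenate(out), PROB_EPS, 1.0 - PROB_EPS)


# --- serialization ------------------------------------------------------

def save_model(model: CVAEState, path) -> None:
    """Single-file checkpoint: JSON hyperparameter header + weights."""
    header = {
        "hyperparams": asdict(model.hyperparams),
        "input_shape": list(model.input_shape),
        "trained_epochs": model.trained_epochs,
        "dtype": np.dtype(model.dtype).name,
        "trace": {k: list(map(float, v)) for k, v in
                  asdict(model.loss_trace).items()} if len(model.loss_trace)
                 else {},
    }
    arrays = {"__header__": np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8)}
    for li, layer in enumerate(model.layers):
        for name, p in layer.params.items():
            arrays[f"layer{li}:{name}"] = p
    np.savez_compressed(path, **arrays)


def load_model(path) -> CVAEState:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        hp = CVAEHyperparams(**header["hyperparams"])
        model = build_model(hp, tuple(header["input_shape"]),
                            dtype=np.dtype(header["dtype"]))
        for li, layer in enumerate(model.layers):
            for name in layer.params:
                layer.params[name] = data[f"layer{li}:{name}"].copy()
        model.trained_epochs = int(header["trained_epochs"])
        if header["trace"]:
            model.loss_trace = LossTrace(**header["trace"])
    return model


# --- transfer and hyperparameter search ---------------------------------

def misprediction_of(model: CVAEState, maps: ContactMapSeries,
                     idx=None, threshold: float = 0.1) -> float:
    """Fraction of unpadded pixels reconstructed more than ``threshold``
    from the true binary value, using the deterministic latent mean."""
    from .landscape import misprediction_fraction, reconstruction_difference

    diff = reconstruction_difference(model, maps, idx)
    return misprediction_fraction(diff)


def transfer_project(model: CVAEState, new_maps: ContactMapSeries,
                     seed: int = 0):
    """Embed an unseen trajectory with frozen weights.

    Returns (LatentEmbedding, misprediction fraction) so the transfer
    quality can be compared with the training trajectory's held-out
    misprediction fraction.
    """
    if (new_maps.size, new_maps.size) != model.input_shape:
        raise DataError(
            f"transfer maps are {new_maps.size}×{new_maps.size}; the model "
            f"requires {model.input_shape[0]}×{model.input_shape[1]}")
    emb = encode(model, new_maps, seed=seed)
    return emb, misprediction_of(model, new_maps)


def _hp_from_point(point, base: CVAEHyperparams) -> CVAEHyperparams:
    names = list(HYPERPARAM_BOUNDS)
    kwargs = {n: int(round(v)) for n, v in zip(names, point)}
    return CVAEHyperparams(optimizer=base.optimizer, epochs=base.epochs,
                           learning_rate=base.learning_rate, **kwargs)


def hyperparameter_search(maps: ContactMapSeries, split: DatasetSplit,
                          bounds: dict | None = None, budget: int = 8,
                          strategy: str = "random", seed: int = 0,
                          epochs: int = 5,
                          base: CVAEHyperparams | None = None,
                          max_seconds: float | None = None):
    """Search the hyperparameter box, ranking by validation E_r.

    ``random`` draws integer points uniformly from the box; ``bayesian``
    fits a Gaussian process to past (point, E_r) evaluations and picks
    the expected-improvement maximiser over a random candidate pool.
    Each evaluation trains a reduced-epoch model. Returns a list of
    (CVAEHyperparams, validation E_r) sorted ascending.
    """
    import time

    if budget < 1:
        raise ConfigurationError("budget must be >= 1")
    if strategy not in ("random", "bayesian"):
        raise ConfigurationError(f"unknown strategy {strategy!r}")
    bounds = dict(HYPERPARAM_BOUNDS if bounds is None else bounds)
    if set(bounds) != set(HYPERPARAM_BOUNDS):
        raise ConfigurationError(
            f"bounds must cover exactly {sorted(HYPERPARAM_BOUNDS)}")
    base = base or CVAEHyperparams()
    names = list(HYPERPARAM_BOUNDS)
    lo = np.array([bounds[n][0] for n in names], dtype=float)
    hi = np.array([bounds[n][1] for n in names], dtype=float)
    rng = np.random.default_rng(seed)
    t0 = time.time()

    def sample_points(k):
        return np.round(rng.uniform(lo, hi, size=(k, len(names))))

    evaluated: list[tuple[CVAEHyperparams, float]] = []
    points: list[np.ndarray] = []
    scores: list[float] = []
    for it in range(budget):
        if max_seconds is not None and time.time() - t0 > max_seconds and evaluated:
            import warnings
            warnings.warn(
                f"hyperparameter search hit the {max_seconds}s wall-clock cap "
                f"after {it} of {budget} evaluations; returning partial results",
                stacklevel=2)
            break
        if strategy == "random" or it < 3 or np.all(lo == hi):
            point = sample_points(1)[0]
        else:
            point = _ei_candidate(np.array(points), np.array(scores),
                                  lo, hi, rng)
        hp = _hp_from_point(point, base)
        model = build_model(hp, (maps.size, maps.size),
                            seed=int(rng.integers(2 ** 31)))
        train(model, maps, split, seed=int(rng.integers(2 ** 31)),
              epochs=epochs)
        val_er = model.loss_trace.val_recon[-1]
        evaluated.append((hp, float(val_er)))
        points.append(point)
        scores.append(float(val_er))
    return sorted(evaluated, key=lambda kv: kv[1])


def _ei_candidate(x, y, lo, hi, rng, pool: int = 256):
    """Expected-improvement maximiser over a random candidate pool."""
    from scipy.stats import norm
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern

    span = np.where(hi > lo, hi - lo, 1.0)
    xs = (x - lo) / span
    gp = GaussianProcessRegressor(kernel=Matern(nu=2.5), alpha=1e-6,
                                  normalize_y=True,
                                  random_state=int(rng.integers(2 ** 31)))
    gp.fit(xs, y)
    cand = np.round(rng.uniform(lo, hi, size=(pool, len(lo))))
    mu, sd = gp.predict((cand - lo) / span, return_std=True)
    best = y.min()
    sd = np.maximum(sd, 1e-12)
    gamma = (best - mu) / sd
    ei = sd * (gamma * norm.cdf(gamma) + norm.pdf(gamma))
    return cand[int(np.argmax(ei))]
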