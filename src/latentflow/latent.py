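"""Nonlinear low-dimensional embedding of BOLD-like frames.

The model is a fully-connected autoencoder: the encoder maps an n_roi
frame through dense ReLU layers into a d-dimensional code, and the
decoder mirrors the layer widths back to n_roi with a linear output.
Training minimizes mean-squared reconstruction error with Adam on
mini-batches, with a seeded 80/20 frame-wise train/validation split and
patience-based early stopping that restores the best validation weights.

The code layer itself is linear: a rectified code can saturate at zero
and produce degenerate (constant) latent time series, which the
downstream correlation-based analyses cannot tolerate.

The PCA baseline and the reconstruction-error/dimension curve used to
select the bottleneck dimension live here too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signals import SubjectSeries

__all__ = [
    "TrainConfig",
    "Autoencoder",
    "EmbeddingReport",
    "train_autoencoder",
    "encode",
    "decode",
    "reconstruction_curve",
    "pca_baseline",
]


@dataclass
class TrainConfig:
    batch: int = 256
    max_epochs: int = 100
    patience: int = 10
    learning_rate: float = 1e-3
    val_frac: float = 0.2
    hidden: tuple = (128, 64)


@dataclass
class EmbeddingReport:
    dims: list
    val_error: list                 # validation MSE per dimension (mean over seeds)
    correlation: list               # source-reconstruction Pearson r per dimension
    selected_d: int
    threshold: float
    per_seed: dict = field(default_factory=dict)


class DivergenceError(RuntimeError):
    pass


def _relu(x):
    return np.maximum(x, 0.0)


class Autoencoder:
    """Dense autoencoder with mirrored encoder/decoder widths.

    Build with the input width and bottleneck dimension, then call
    :meth:`fit` on an (n_roi, n_samples) frame matrix.  ``fit`` returns
    ``self`` with the trained parameters, per-epoch train/validation loss
    history and the recorded split indices.
    """

    def __init__(self, n_roi: int, d: int, config: TrainConfig | None = None,
                 seed: int = 0):
        if not 1 <= d <= n_roi:
            raise ValueError("require 1 <= d <= n_roi")
        self.n_roi = n_roi
        self.d = d
        self.config = config or TrainConfig()
        self.seed = seed
        hidden = [h for h in self.config.hidden if h > d] or []
        self.widths = [n_roi] + hidden + [d] + hidden[::-1] + [n_roi]
        self._code_layer = 1 + len(hidden)      # index in widths of the code
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        self.history: dict = {"train_loss": [], "val_loss": []}
        self.split_indices: dict = {}
        self.trained = False

        rng = np.random.default_rng(seed)
        for w_in, w_out in zip(self.widths[:-1], self.widths[1:]):
            scale = np.sqrt(2.0 / w_in)          # He initialization
            self.weights.append(rng.normal(0.0, scale, size=(w_out, w_in)))
            self.biases.append(np.zeros(w_out))

    # -- forward passes -----------------------------------------------------

    def _forward(self, x: np.ndarray, stop_layer: int | None = None,
                 start_layer: int = 0):
        """Propagate columns of ``x`` through layers [start, stop)."""
        stop = stop_layer if stop_layer is not None else len(self.weights)
        activations = [x]
        h = x
        for layer in range(start_layer, stop):
            z = self.weights[layer] @ h + self.biases[layer][:, None]
            is_code = (layer + 1) == self._code_layer
            is_output = (layer + 1) == len(self.widths) - 1
            h = z if (is_code or is_output) else _relu(z)
            activations.append(h)
        return h, activations

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Encode frames (columns) into the d-dimensional code."""
        self._require_trained()
        code, _ = self._forward(np.asarray(x, float), stop_layer=self._code_layer)
        return code

    def inverse_transform(self, code: np.ndarray) -> np.ndarray:
        self._require_trained()
        out, _ = self._forward(np.asarray(code, float),
                               start_layer=self._code_layer)
        return out

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        self._require_trained()
        out, _ = self._forward(np.asarray(x, float))
        return out

    def _require_trained(self):
        if not self.trained:
            raise RuntimeError("model is not trained; call fit() first")

    # -- training -----------------------------------------------------------

    def fit(self, frames: np.ndarray) -> "Autoencoder":
        """Train on an (n_roi, n_samples) matrix of frames."""
        x = np.asarray(frames, dtype=float)
        if x.shape[0] != self.n_roi:
            raise ValueError(f"expected {self.n_roi} rows, got {x.shape[0]}")
        cfg = self.config
        n = x.shape[1]
        if n <= cfg.batch:
            raise ValueError("need more samples than the batch size")

        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(n)
        n_val = max(1, int(round(cfg.val_frac * n)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        self.split_indices = {"train": np.sort(train_idx),
                              "validation": np.sort(val_idx)}
        xtr, xval = x[:, train_idx], x[:, val_idx]

        # Adam state
        mw = [np.zeros_like(w) for w in self.weights]
        vw = [np.zeros_like(w) for w in self.weights]
        mb = [np.zeros_like(b) for b in self.biases]
        vb = [np.zeros_like(b) for b in self.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        best_val = np.inf
        best_weights = None
        best_epoch = -1
        stall = 0

        for epoch in range(cfg.max_epochs):
            order = rng.permutation(xtr.shape[1])
            train_losses = []
            for start in range(0, order.size, cfg.batch):
                batch = xtr[:, order[start:start + cfg.batch]]
                loss, gw, gb = self._backprop(batch)
                if not np.isfinite(loss):
                    raise DivergenceError(f"non-finite loss at epoch {epoch}")
                train_losses.append(loss)
                step += 1
                for k in range(len(self.weights)):
                    mw[k] = beta1 * mw[k] + (1 - beta1) * gw[k]
                    vw[k] = beta2 * vw[k] + (1 - beta2) * gw[k] ** 2
                    mb[k] = beta1 * mb[k] + (1 - beta1) * gb[k]
                    vb[k] = beta2 * vb[k] + (1 - beta2) * gb[k] ** 2
                    mhat = mw[k] / (1 - beta1 ** step)
                    vhat = vw[k] / (1 - beta2 ** step)
                    self.weights[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
                    mhat = mb[k] / (1 - beta1 ** step)
                    vhat = vb[k] / (1 - beta2 ** step)
                    self.biases[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

            out, _ = self._forward(xval)
            val_loss = float(np.mean((out - xval) ** 2))
            self.history["train_loss"].append(float(np.mean(train_losses)))
            self.history["val_loss"].append(val_loss)

            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_epoch = epoch
                best_weights = ([w.copy() for w in self.weights],
                                [b.copy() for b in self.biases])
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break

        if best_weights is not None:
            self.weights, self.biases = best_weights
        self.history["best_epoch"] = best_epoch
        self.history["best_val_loss"] = float(best_val)
        self.trained = True
        return self

    def _backprop(self, x: np.ndarray):
        out, acts = self._forward(x)
        m = x.shape[1]
        diff = out - x
        loss = float(np.mean(diff ** 2))
        delta = 2.0 * diff / (m * x.shape[0])
        gw = [None] * len(self.weights)
        gb = [None] * len(self.weights)
        for layer in range(len(self.weights) - 1, -1, -1):
            a_prev = acts[layer]
            gw[layer] = delta @ a_prev.T
            gb[layer] = delta.sum(axis=1)
            if layer > 0:
                delta = self.weights[layer].T @ delta
                is_code = layer == self._code_layer
                if not is_code:                 # ReLU derivative
                    delta = delta * (acts[layer] > 0)
        return loss, gw, gb

    # -- diagnostics --------------------------------------------------------

    def validation_correlation(self, frames: np.ndarray) -> float:
        """Pearson r between held-out frames and their reconstruction."""
        self._require_trained()
        x = np.asarray(frames, float)[:, self.split_indices["validation"]]
        rec = self.reconstruct(x)
        return float(np.corrcoef(x.ravel(), rec.ravel())[0, 1])

    def summary(self) -> str:
        lines = [
            "Autoencoder",
            f"  layer widths : {' -> '.join(map(str, self.widths))}",
            f"  bottleneck d : {self.d}",
            f"  trained      : {self.trained}",
        ]
        if self.trained:
            lines += [
                f"  epochs run   : {len(self.history['train_loss'])}",
                f"  best epoch   : {self.history['best_epoch']}",
                f"  best val MSE : {self.history['best_val_loss']:.6f}",
            ]
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        arrays = {}
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"w{k}"] = w
            arrays[f"b{k}"] = b
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "n_roi": self.n_roi, "d": self.d, "seed": self.seed,
            "widths": self.widths, "trained": self.trained,
            "config": self.config.__dict__ | {"hidden": list(self.config.hidden)},
            "history": {k: v for k, v in self.history.items()},
            "split_indices": {k: np.asarray(v).tolist()
                              for k, v in self.split_indices.items()},
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "Autoencoder":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = dict(meta["config"])
        cfg["hidden"] = tuple(cfg["hidden"])
        model = cls(meta["n_roi"], meta["d"], TrainConfig(**cfg), meta["seed"])
        with np.load(path.with_suffix(".npz")) as arc:
            model.weights = [arc[f"w{k}"] for k in range(len(model.weights))]
            model.biases = [arc[f"b{k}"] for k in range(len(model.biases))]
        model.history = meta["history"]
        model.split_indices = {k: np.array(v)
                               for k, v in meta["split_indices"].items()}
        model.trained = meta["trained"]
        return model


def train_autoencoder(frames: np.ndarray, d: int,
                      config: TrainConfig | None = None,
                      seed: int = 0) -> Autoencoder:
    """Fit an autoencoder on an (n_roi, n_samples) frame matrix."""
    frames = np.asarray(frames, float)
    return Autoencoder(frames.shape[0], d, config, seed).fit(frames)


def encode(model: Autoencoder, series: SubjectSeries) -> SubjectSeries:
    """Map a source series frame-by-frame into the latent space."""
    if series.n_roi != model.n_roi:
        raise ValueError(
            f"series has {series.n_roi} rows, encoder expects {model.n_roi}")
    code = model.transform(series.data)
    return series.with_data(code, space="latent")


def decode(model: Autoencoder, series: SubjectSeries) -> SubjectSeries:
    """Map a latent series back to the source space."""
    if series.n_roi != model.d:
        raise ValueError(f"latent series has {series.n_roi} rows, expected {model.d}")
    return series.with_data(model.inverse_transform(series.data), space="source")


def reconstruction_curve(frames: np.ndarray, d_range,
                         config: TrainConfig | None = None,
                         seeds=(0,), threshold: float = 0.9) -> EmbeddingReport:
    """Validation error and source-reconstruction correlation per dimension.

    One model is trained per (d, seed); curves are averaged over seeds and
    the selected dimension is the smallest whose mean correlation reaches
    ``threshold``, or the best-correlating dimension if none does.
    """
    d_range = sorted(set(int(d) for d in d_range))
    if not d_range:
        raise ValueError("d_range must be nonempty")
    frames = np.asarray(frames, float)
    per_seed = {}
    val_err, corr = [], []
    for d in d_range:
        errs, rs = [], []
        for seed in seeds:
            try:
                model = train_autoencoder(frames, d, config, seed=seed)
            except Exception as exc:
                raise RuntimeError(f"training failed at d={d}") from exc
            errs.append(model.history["best_val_loss"])
            rs.append(model.validation_correlation(frames))
        per_seed[d] = {"val_error": errs, "correlation": rs}
        val_err.append(float(np.mean(errs)))
        corr.append(float(np.mean(rs)))
    reached = [d for d, r in zip(d_range, corr) if r >= threshold]
    selected = reached[0] if reached else d_range[int(np.argmax(corr))]
    return EmbeddingReport(d_range, val_err, corr, selected, threshold, per_seed)


def pca_baseline(frames: np.ndarray, d: int) -> dict:
    """Top-d principal-component reconstruction of the frame matrix.

    Frames are columns; components are eigenvectors of the frame
    covariance.  Returns components, the explained-variance fraction, the
    projected frames and the rank-d reconstruction.
    """
    from sklearn.decomposition import PCA

    frames = np.asarray(frames, float)
    if d > frames.shape[0]:
        raise ValueError("d cannot exceed the number of rows")
    pca = PCA(n_components=d, svd_solver="full")
    projected = pca.fit_transform(frames.T)          # (n_samples, d)
    reconstructed = pca.inverse_transform(projected).T
    frac = float(np.sum(pca.explained_variance_ratio_))
    corr = float(np.corrcoef(frames.ravel(), reconstructed.ravel())[0, 1])
    return {
        "components": pca.components_,
        "variance_explained_fraction": frac,
        "projected": projected.T,
        "reconstructed": reconstructed,
        "reconstruction_correlation": corr,
        "mse": float(np.mean((frames - reconstructed) ** 2)),
    }
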