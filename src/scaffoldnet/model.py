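"""Property-prediction model: a 3D CNN fitted to labelled voxel grids.

The public surface follows the model/results idiom of statistical
modelling packages: :class:`ScaffoldPropertyCNN` is constructed from
data (voxel grids plus property labels, or an
:class:`~scaffoldnet.augment.AugmentedDataset`), ``fit()`` trains the
network and returns a :class:`CNNTrainingResults` carrying the learned
parameters, the per-epoch loss history, the target scaler and a
``summary()`` table; prediction and evaluation hang off the results
object.

Targets (porosity %, relative compression modulus %, relative shear
modulus %) are min-max scaled to [0, 1] over the *training split*
before optimization; losses are mean squared errors on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .augment import AugmentedDataset
from .errors import DegenerateScaleError, ShapeError
from .nn import Adam, CNNConfig, Network, mse_loss


@dataclass
class TargetScaler:
    """Per-output min-max scaling fitted on the training labels."""

    minimum: np.ndarray
    maximum: np.ndarray

    @classmethod
    def fit(cls, labels: np.ndarray) -> "TargetScaler":
        y = np.asarray(labels, dtype=float)
        if y.ndim != 2:
            raise ShapeError("labels must be an (n, outputs) array")
        lo, hi = y.min(axis=0), y.max(axis=0)
        bad = np.nonzero(hi <= lo)[0]
        if bad.size:
            raise DegenerateScaleError(
                f"target column(s) {bad.tolist()} are constant; "
                "min-max scaling is undefined")
        return cls(lo, hi)

    def apply(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.minimum) / (self.maximum - self.minimum)

    def invert(self, y_scaled: np.ndarray) -> np.ndarray:
        return np.asarray(y_scaled, dtype=float) * (self.maximum - self.minimum) + self.minimum

    def to_dict(self):
        return {"minimum": self.minimum.tolist(), "maximum": self.maximum.tolist()}

    @classmethod
    def from_dict(cls, d):
        return cls(np.asarray(d["minimum"], float), np.asarray(d["maximum"], float))


def fit_scaler(labels) -> TargetScaler:
    """Fit a per-output min-max scaler (module-level convenience)."""
    return TargetScaler.fit(np.asarray(labels, dtype=float))


def build_model(config: Optional[CNNConfig] = None) -> Network:
    """Build the (untrained) network for a configuration.

    Layer shapes are walked at build time; a pooling chain incompatible
    with the input shape raises a shape error before any training.
    """
    return Network(config or CNNConfig())


class ScaffoldPropertyCNN:
    """3D CNN regression model mapping occupancy tensors to properties.

    Parameters
    ----------
    grids : array (n, nx, ny, nz)
        Binary occupancy tensors.
    labels : array (n, 3)
        Property vectors (porosity, e_rel, g_rel) in %.
    config : CNNConfig, optional
        Architecture; defaults to the reference bottleneck network.
    base_count : int, optional
        Number of distinct source lattices behind the records; used to
        size the default validation split (30 % of the base).
    """

    def __init__(self, grids, labels, config: Optional[CNNConfig] = None,
                 base_count: Optional[int] = None, provenances=None):
        self.grids = np.asarray(grids, dtype=np.uint8)
        self.labels = np.asarray(labels, dtype=float)
        if self.grids.ndim != 4:
            raise ShapeError("grids must be a (n, nx, ny, nz) array")
        if len(self.grids) != len(self.labels):
            raise ValueError("grids and labels differ in length")
        self.config = config or CNNConfig(input_shape=self.grids.shape[1:4])
        if self.grids.shape[1:4] != tuple(self.config.input_shape):
            raise ShapeError(
                f"grids have shape {self.grids.shape[1:4]}, model expects "
                f"{tuple(self.config.input_shape)}")
        self.base_count = base_count or len(self.grids)
        self.provenances = provenances

    @classmethod
    def from_dataset(cls, dataset: AugmentedDataset,
                     config: Optional[CNNConfig] = None) -> "ScaffoldPropertyCNN":
        return cls(dataset.grids(), dataset.labels(), config=config,
                   base_count=dataset.base_count,
                   provenances=dataset.provenances())

    # ------------------------------------------------------------------
    def fit(self, epochs: int = 200, batch_size: int = 8, lr: float = 1e-3,
            seed: int = 0, split_seed: Optional[int] = None,
            n_val: Optional[int] = None, checkpoint: str = "best_val",
            lr_schedule: Optional[dict] = None, leakage_free: bool = False,
            verbose: bool = False) -> "CNNTrainingResults":
        """Train the network, minimizing MSE on scaled targets.

        The validation records are drawn at random from the full record
        pool; by default ``round(0.3 * base_count)`` of them (six for a
        20-lattice base), reproducing a 70/30 split of the untransformed
        library.  That sampling frame permits augmented siblings of a
        validation record to sit in the training set;
        ``leakage_free=True`` instead holds out every record derived
        from 30 % of the source lattices (requires provenance tags).
        ``checkpoint='best_val'`` restores the weights of the epoch with
        the lowest validation MSE; ``'last'`` keeps the final epoch.
        ``lr_schedule`` maps epoch -> learning rate for step decays.
        Deterministic given ``(seed, split_seed)``.
        """
        n = len(self.grids)
        if n == 0:
            raise ValueError("cannot fit on an empty dataset")
        if split_seed is None:
            split_seed = seed

        split_rng = np.random.default_rng(split_seed)
        if leakage_free:
            if not self.provenances:
                raise ValueError("leakage_free split needs provenance tags")
            sources = [p.split("|")[0] for p in self.provenances]
            uniq = sorted(set(sources))
            k = max(1, int(round(0.3 * len(uniq))))
            held = set(split_rng.permutation(uniq)[:k])
            val_idx = np.array([i for i, s in enumerate(sources) if s in held])
            train_idx = np.array([i for i, s in enumerate(sources)
                                  if s not in held])
            n_val = len(val_idx)
            if n_val == 0 or len(train_idx) == 0:
                raise ValueError("leakage_free split left an empty partition")
        else:
            if n_val is None:
                n_val = int(round(0.3 * self.base_count))
                n_val = min(max(n_val, 1), n - 1) if n > 1 else 0
            if n_val >= n:
                raise ValueError(
                    f"n_val={n_val} leaves no training records (n={n})")
            perm = split_rng.permutation(n)
            val_idx = np.sort(perm[:n_val])
            train_idx = np.sort(perm[n_val:])

        scaler = TargetScaler.fit(self.labels[train_idx])
        y = scaler.apply(self.labels).astype(np.float32)
        x = self.grids.astype(np.float32)

        net = Network(self.config if self.config.seed == seed
                      else CNNConfig(**{**self.config.__dict__, "seed": seed}))
        opt = Adam(net.parameters(), lr=lr)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5caf]))

        history = {"epoch": [], "train_mse": [], "val_mse": []}
        best = (np.inf, None)
        xt, yt = x[train_idx], y[train_idx]
        for epoch in range(epochs):
            if lr_schedule and epoch in lr_schedule:
                opt.lr = lr_schedule[epoch]
            order = rng.permutation(len(train_idx))
            for s in range(0, len(order), batch_size):
                sel = order[s:s + batch_size]
                pred = net.forward(xt[sel], training=True, rng=rng)
                _, grad = mse_loss(pred, yt[sel])
                net.backward(grad)
                opt.step()
            train_mse = self._mse(net, xt, yt, batch_size)
            val_mse = (self._mse(net, x[val_idx], y[val_idx], batch_size)
                       if n_val else train_mse)
            history["epoch"].append(epoch)
            history["train_mse"].append(train_mse)
            history["val_mse"].append(val_mse)
            if val_mse < best[0]:
                best = (val_mse, net.get_weights())
            if verbose:  # pragma: no cover
                print(f"epoch {epoch:4d}  train {train_mse:.5f}  val {val_mse:.5f}")
        if checkpoint == "best_val" and best[1] is not None:
            net.set_weights(best[1])
        elif checkpoint not in ("best_val", "last"):
            raise ValueError(f"unknown checkpoint policy {checkpoint!r}")
        return CNNTrainingResults(
            model=self, network=net, scaler=scaler,
            history=pd.DataFrame(history).set_index("epoch"),
            train_idx=train_idx, val_idx=val_idx,
            seed=seed, split_seed=split_seed, checkpoint=checkpoint)

    @staticmethod
    def _mse(net, x, y, batch_size=32):
        if len(x) == 0:
            return np.nan
        total = 0.0
        for s in range(0, len(x), batch_size):
            pred = net.forward(x[s:s + batch_size], training=False)
            total += float(((pred - y[s:s + batch_size])**2).sum())
        return total / y.size


class CNNTrainingResults:
    """Fitted-model results: parameters, history, scaler, diagnostics."""

    def __init__(self, model, network, scaler, history, train_idx, val_idx,
                 seed, split_seed, checkpoint):
        self.model = model
        self.network = network
        self.scaler = scaler
        self.history = history
        self.train_idx = train_idx
        self.val_idx = val_idx
        self.seed = seed
        self.split_seed = split_seed
        self.checkpoint = checkpoint

    # -- diagnostics ----------------------------------------------------
    @property
    def n_train(self):
        return len(self.train_idx)

    @property
    def n_val(self):
        return len(self.val_idx)

    @property
    def final_train_mse(self):
        return float(self.history["train_mse"].iloc[-1])

    @property
    def final_val_mse(self):
        return float(self.history["val_mse"].iloc[-1])

    @property
    def best_val_mse(self):
        return float(self.history["val_mse"].min())

    def train_mse_scaled(self):
        """Scaled-output train MSE of the stored (checkpointed) weights."""
        x = self.model.grids[self.train_idx].astype(np.float32)
        y = self.scaler.apply(self.model.labels[self.train_idx]).astype(np.float32)
        return ScaffoldPropertyCNN._mse(self.network, x, y)

    # -- prediction -----------------------------------------------------
    def predict(self, grids) -> np.ndarray:
        """Predicted property vectors, in %, clipped to [0, 100]."""
        g = np.asarray(grids, dtype=np.float32)
        single = g.ndim == 3
        if single:
            g = g[None]
        if g.shape[1:4] != tuple(self.model.config.input_shape):
            raise ShapeError(
                f"grid shape {g.shape[1:4]} does not match model input "
                f"{tuple(self.model.config.input_shape)}")
        out = []
        for s in range(0, len(g), 32):
            pred = self.network.forward(g[s:s + 32], training=False)
            out.append(self.scaler.invert(pred))
        res = np.clip(np.concatenate(out), 0.0, 100.0)
        return res[0] if single else res

    # -- presentation ---------------------------------------------------
    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Scaffold property CNN — training results",
            "=" * 46,
            f"records: {len(self.model.grids)} "
            f"(train {self.n_train} / validation {self.n_val})",
            f"input shape: {tuple(cfg.input_shape)}  "
            f"parameters: {self.network.n_parameters}",
            f"conv filters: {cfg.conv_filters}  pools: {cfg.pools}",
            f"dense units: {cfg.dense_units}  dropout: {cfg.dropout_rate}",
            f"epochs: {len(self.history)}  seed: {self.seed}  "
            f"split seed: {self.split_seed}  checkpoint: {self.checkpoint}",
            "-" * 46,
            f"final train MSE (scaled): {self.final_train_mse:.5f}",
            f"final validation MSE (scaled): {self.final_val_mse:.5f}",
            f"best validation MSE (scaled): {self.best_val_mse:.5f}",
            "-" * 46,
            "target scaling (min / max, %):",
        ]
        names = ("porosity", "e_rel", "g_rel")
        for name, lo, hi in zip(names, self.scaler.minimum, self.scaler.maximum):
            lines.append(f"  {name:9s} {lo:8.3f} / {hi:8.3f}")
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Plot per-epoch train/validation MSE (scaled outputs)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        self.history["train_mse"].plot(ax=ax, label="train")
        self.history["val_mse"].plot(ax=ax, label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("MSE (scaled outputs)")
        ax.set_yscale("log")
        ax.legend()
        return ax

    def __repr__(self):
        return (f"<CNNTrainingResults n={len(self.model.grids)} "
                f"val_mse={self.final_val_mse:.4f}>")
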