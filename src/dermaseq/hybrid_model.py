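"""The hybrid LSTM -> time-distributed CNN lesion classifier.

Pipeline (``order="lstm_first"``, the default): the image is cut into N
non-overlapping patches, linearly embedded with positional terms, and
the token sequence is run through an LSTM that returns all N hidden
states.  Each hidden state h_t (of length d^2) is reshaped into a
(d, d, 1) "frame", and the same convolution + ReLU + max-pool stack is
applied to every frame (time-distributed).  The per-frame features are
flattened over time and space, passed through dense layers with dropout
and L2 weight decay, and a softmax head yields the class distribution.

The alternative wiring ``order="cnn_first"`` applies the
time-distributed CNN to the raw P x P x C patches and feeds the
resulting per-patch feature vectors to the LSTM, classifying from the
final hidden state.

Regularization recipe: dropout (rate 0.3-0.5) after the embedding and
after each dense activation, data augmentation (rotation, flips,
scaling, brightness), L2 penalty (factor 0.001) on all weight matrices,
early stopping on validation loss with best-weight restoration, and a
learning-rate schedule that halves the rate on a validation-loss
plateau.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import rotate as _sk_rotate, rescale as _sk_rescale
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import train_test_split

from . import _autodiff as ad
from .patch_encoder import extract_patches

__all__ = [
    "ModelConfig",
    "AugmentPolicy",
    "TrainingHistory",
    "HybridNet",
    "TrainedModel",
    "build_model",
    "augment",
    "hflip",
    "vflip",
    "train",
    "predict_proba",
]


@dataclass
class ModelConfig:
    """Architecture and training hyper-parameters of the hybrid model."""

    image_size: tuple = (100, 100)
    n_channels: int = 3
    patch_size_P: int = 10
    embed_dim_D: int = 64
    include_cls: bool = False
    lstm_hidden: int = 64               # must be a perfect square (frame reshape)
    conv_filters: tuple = ((16, 3), (32, 3))   # (n_kernels, kernel_size) per block
    pool_window: tuple = (2, 2)
    pool_stride: int = 2
    dense_units: tuple = (64,)
    n_classes: int = 2
    order: str = "lstm_first"           # or "cnn_first"
    use_dropout: bool = True            # master switch; rate stays in band
    dropout_rate: float = 0.4
    l2_factor: float = 0.001
    learning_rate: float = 0.001
    lr_plateau_patience: int = 5
    lr_decay_factor: float = 0.5
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 10
    val_fraction: float = 0.2
    val_accuracy_threshold: float = 0.99
    augment_data: bool = False
    seed: int = 0

    @property
    def frame_side(self) -> int:
        return int(round(np.sqrt(self.lstm_hidden)))

    @property
    def n_patches(self) -> int:
        h, w = self.image_size
        return (h * w) // (self.patch_size_P ** 2)

    def validate(self) -> None:
        h, w = self.image_size
        if h % self.patch_size_P or w % self.patch_size_P:
            raise ValueError(
                f"patch_size_P={self.patch_size_P} must divide image_size {self.image_size}")
        if self.frame_side ** 2 != self.lstm_hidden:
            raise ValueError(
                f"lstm_hidden={self.lstm_hidden} must be a perfect square "
                "(hidden states are reshaped into square frames)")
        if not (0.3 <= self.dropout_rate <= 0.5):
            raise ValueError(
                f"dropout_rate must be in [0.3, 0.5], got {self.dropout_rate}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.order not in ("lstm_first", "cnn_first"):
            raise ValueError(f"unknown order {self.order!r}")
        if self.include_cls and self.order != "lstm_first":
            raise ValueError(
                "include_cls requires order='lstm_first' (the CLS token lives "
                "in the embedded token sequence)")


@dataclass
class AugmentPolicy:
    """Which augmentation transforms :func:`augment` may apply."""

    rotate: bool = True
    flip: bool = True
    scale: bool = True
    brightness: bool = True

    @classmethod
    def none(cls) -> "AugmentPolicy":
        return cls(rotate=False, flip=False, scale=False, brightness=False)


def hflip(image: np.ndarray) -> np.ndarray:
    return image[:, ::-1].copy()


def vflip(image: np.ndarray) -> np.ndarray:
    return image[::-1].copy()


def augment(image: np.ndarray, rng_seed: int,
            policy: AugmentPolicy = AugmentPolicy()) -> np.ndarray:
    """Seeded random augmentation of one image; output has the same shape.

    Rotation +-20 deg, horizontal/vertical flip (each with prob. 1/2),
    isotropic scale 0.9-1.1 (center crop/pad back to size), brightness
    shift +-10%.  Each transform is independently switchable; with all
    flags off the input is returned bit-identically.
    """
    rng = np.random.default_rng(rng_seed)
    out = image.copy()
    is_uint8 = out.dtype == np.uint8
    if policy.rotate:
        angle = rng.uniform(-20.0, 20.0)
        rot = _sk_rotate(out.astype(float), angle, mode="edge",
                         preserve_range=True, order=1)
        out = rot
    if policy.flip:
        if rng.random() < 0.5:
            out = hflip(np.asarray(out))
        if rng.random() < 0.5:
            out = vflip(np.asarray(out))
    if policy.scale:
        factor = rng.uniform(0.9, 1.1)
        h, w = image.shape[:2]
        scaled = _sk_rescale(np.asarray(out, dtype=float), factor,
                             channel_axis=-1 if out.ndim == 3 else None,
                             preserve_range=True, order=1)
        sh, sw = scaled.shape[:2]
        if sh >= h:                       # center crop
            r0, c0 = (sh - h) // 2, (sw - w) // 2
            out = scaled[r0:r0 + h, c0:c0 + w]
        else:                             # center pad with edge values
            pr, pc = h - sh, w - sw
            pad = [(pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2)]
            if scaled.ndim == 3:
                pad.append((0, 0))
            out = np.pad(scaled, pad, mode="edge")
    if policy.brightness:
        out = np.asarray(out, dtype=float) * rng.uniform(0.9, 1.1)
    if is_uint8:
        out = np.clip(np.rint(np.asarray(out, dtype=float)), 0, 255).astype(np.uint8)
    return out


@dataclass
class TrainingHistory:
    """Per-epoch train/validation loss, accuracy, F1 and AUC records."""

    records: list = field(default_factory=list)   # dicts keyed epoch/split/...
    best_epoch: int = -1
    stop_reason: str = ""

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        cols = ["epoch", "split", "loss", "accuracy", "f1", "auc"]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            for rec in self.records:
                writer.writerow({k: rec[k] for k in cols})
        return path

    def metric(self, epoch: int, split: str, key: str) -> float:
        for rec in self.records:
            if rec["epoch"] == epoch and rec["split"] == split:
                return rec[key]
        raise KeyError(f"no record for epoch={epoch} split={split}")


class HybridNet:
    """Parameter container + differentiable forward pass of the hybrid net."""

    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        P, D, C = cfg.patch_size_P, cfg.embed_dim_D, cfg.n_channels
        in_dim = P * P * C
        N = cfg.n_patches
        hid = cfg.lstm_hidden
        self.params: dict[str, ad.Tensor] = {}

        def uniform(name, shape, lim):
            self.params[name] = ad.Tensor(
                rng.uniform(-lim, lim, size=shape), requires_grad=True)

        lim_e = 1.0 / np.sqrt(D)
        uniform("E", (in_dim, D), lim_e)          # token_i = x_i @ E
        n_tokens = N + (1 if cfg.include_cls else 0)
        uniform("E_pos", (n_tokens, D), lim_e)
        if cfg.include_cls:
            uniform("z_cls", (D,), lim_e)

        lstm_in = D if cfg.order == "lstm_first" else self._cnn_out_dim(P, C)
        lim_l = 1.0 / np.sqrt(hid + lstm_in)
        for gate in "fico":
            uniform(f"W_{gate}", (hid + lstm_in, hid), lim_l)
            self.params[f"b_{gate}"] = ad.Tensor(
                np.zeros(hid), requires_grad=True)
        # open forget gate at init: standard recurrent-training aid
        self.params["b_f"].data += 1.0

        frame_c = 1 if cfg.order == "lstm_first" else C
        side = cfg.frame_side if cfg.order == "lstm_first" else P
        ch, s = frame_c, side
        for bi, (nk, ks) in enumerate(cfg.conv_filters):
            lim_c = np.sqrt(6.0 / (ks * ks * ch + nk))
            uniform(f"conv{bi}_w", (ks, ks, ch, nk), lim_c)
            self.params[f"conv{bi}_b"] = ad.Tensor(
                np.zeros(nk), requires_grad=True)
            s = s - ks + 1
            if s >= cfg.pool_window[0]:
                s = (s - cfg.pool_window[0]) // cfg.pool_stride + 1
            ch = nk
        self._feat_per_frame = s * s * ch

        flat = (n_tokens * self._feat_per_frame
                if cfg.order == "lstm_first" else hid)
        dims = [flat, *cfg.dense_units, cfg.n_classes]
        for di, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            lim_d = np.sqrt(6.0 / (a + b))
            uniform(f"dense{di}_w", (a, b), lim_d)
            self.params[f"dense{di}_b"] = ad.Tensor(
                np.zeros(b), requires_grad=True)
        self._n_dense = len(dims) - 1

    def _cnn_out_dim(self, side: int, ch: int) -> int:
        s, c = side, ch
        for nk, ks in self.cfg.conv_filters:
            s = s - ks + 1
            if s >= self.cfg.pool_window[0]:
                s = (s - self.cfg.pool_window[0]) // self.cfg.pool_stride + 1
            c = nk
        return s * s * c

    # ---- forward ---------------------------------------------------------

    def _encode(self, images: np.ndarray) -> np.ndarray:
        """(B, H, W, C) uint8/float -> (B, N, P*P*C) patch array in [0, 1]."""
        B = images.shape[0]
        out = np.empty((B, self.cfg.n_patches,
                        self.cfg.patch_size_P ** 2 * self.cfg.n_channels))
        for i in range(B):
            out[i] = extract_patches(images[i], self.cfg.patch_size_P).patches
        return out / 255.0

    def _td_cnn(self, frames: ad.Tensor, B: int, N: int) -> ad.Tensor:
        """Apply the conv stack to every frame; frames (B*N, s, s, ch)."""
        cfg = self.cfg
        h = frames
        for bi in range(len(cfg.conv_filters)):
            h = ad.conv2d(h, self.params[f"conv{bi}_w"], self.params[f"conv{bi}_b"])
            h = h.relu()
            if h.shape[1] >= cfg.pool_window[0]:
                h = ad.max_pool2d(h, cfg.pool_window, cfg.pool_stride)
        return h.reshape(B, N, self._feat_per_frame)

    def _lstm(self, tokens: ad.Tensor, B: int, T: int,
              return_all: bool) -> ad.Tensor:
        hid = self.cfg.lstm_hidden
        h = ad.Tensor(np.zeros((B, hid)))
        c = ad.Tensor(np.zeros((B, hid)))
        hs = []
        for t in range(T):
            x_t = tokens[:, t, :]
            hx = ad.concat([h, x_t], axis=1)
            f = (hx @ self.params["W_f"] + self.params["b_f"]).sigmoid()
            i = (hx @ self.params["W_i"] + self.params["b_i"]).sigmoid()
            g = (hx @ self.params["W_c"] + self.params["b_c"]).tanh()
            o = (hx @ self.params["W_o"] + self.params["b_o"]).sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            if return_all:
                hs.append(h.reshape(B, 1, hid))
        return ad.concat(hs, axis=1) if return_all else h

    def forward(self, images: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> ad.Tensor:
        """Logits (B, K) for a batch of (B, H, W, C) images."""
        cfg = self.cfg
        if images.shape[1:3] != tuple(cfg.image_size):
            raise ValueError(
                f"images of size {images.shape[1:3]} do not match configured "
                f"image_size {cfg.image_size} (no silent resize)")
        if rng is None:
            rng = np.random.default_rng(0)
        B = images.shape[0]
        x = ad.Tensor(self._encode(images))           # (B, N, in_dim)
        rate = cfg.dropout_rate if cfg.use_dropout else 0.0

        if cfg.order == "lstm_first":
            tokens = x @ self.params["E"]             # (B, N, D)
            N = cfg.n_patches
            if cfg.include_cls:
                cls = self.params["z_cls"].reshape(1, 1, cfg.embed_dim_D)
                cls_b = cls + ad.Tensor(np.zeros((B, 1, cfg.embed_dim_D)))
                tokens = ad.concat([cls_b, tokens], axis=1)
                N += 1
            tokens = tokens + self.params["E_pos"]
            tokens = ad.dropout(tokens, rate, rng, train)
            hseq = self._lstm(tokens, B, N, return_all=True)   # (B, N, hid)
            d = cfg.frame_side
            frames = hseq.reshape(B * N, d, d, 1)
            feats = self._td_cnn(frames, B, N)                 # (B, N, feat)
            h = feats.reshape(B, N * self._feat_per_frame)
        else:
            P, C = cfg.patch_size_P, cfg.n_channels
            frames = x.reshape(B * cfg.n_patches, P, P, C)
            feats = self._td_cnn(frames, B, cfg.n_patches)     # (B, N, feat)
            feats = ad.dropout(feats, rate, rng, train)        # before the LSTM
            h = self._lstm(feats, B, cfg.n_patches, return_all=False)

        for di in range(self._n_dense):
            h = h @ self.params[f"dense{di}_w"] + self.params[f"dense{di}_b"]
            if di < self._n_dense - 1:
                h = h.relu()
                h = ad.dropout(h, rate, rng, train)
        return h                                               # logits

    # ---- parameter plumbing ---------------------------------------------

    def parameter_list(self) -> list[ad.Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def weight_matrices(self) -> list[ad.Tensor]:
        """Parameters subject to the L2 penalty (matrices, not biases)."""
        return [t for k, t in sorted(self.params.items())
                if not k.startswith("b_") and not k.endswith("_b")]

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = weights[k].copy()


def build_model(cfg: ModelConfig) -> HybridNet:
    """Assemble an untrained hybrid network from a configuration."""
    return HybridNet(cfg)


@dataclass
class TrainedModel:
    """A fitted hybrid network plus its config and label vocabulary."""

    net: HybridNet
    cfg: ModelConfig
    classes: list

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "weights.npz", **self.net.get_weights())
        sidecar = {"config": asdict(self.cfg), "classes": list(self.classes)}
        (out / "model.json").write_text(json.dumps(sidecar, indent=1))
        return out

    @classmethod
    def load(cls, out_dir: str | Path) -> "TrainedModel":
        out = Path(out_dir)
        sidecar = json.loads((out / "model.json").read_text())
        raw = sidecar["config"]
        for key in ("image_size", "pool_window"):
            raw[key] = tuple(raw[key])
        raw["conv_filters"] = tuple(tuple(p) for p in raw["conv_filters"])
        raw["dense_units"] = tuple(raw["dense_units"])
        cfg = ModelConfig(**raw)
        net = HybridNet(cfg)
        with np.load(out / "weights.npz") as npz:
            net.set_weights({k: npz[k] for k in npz.files})
        return cls(net=net, cfg=cfg, classes=sidecar["classes"])


def _one_hot(y: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(y), k))
    out[np.arange(len(y)), y] = 1.0
    return out


def _eval_split(net: HybridNet, X: np.ndarray, y: np.ndarray,
                k: int, batch: int = 64) -> dict:
    """Eval-mode loss/accuracy/F1/AUC of one split."""
    probs = _predict_probs(net, X, batch)
    onehot = _one_hot(y, k)
    loss = float(-np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=1)))
    pred = probs.argmax(axis=1)
    acc = float(np.mean(pred == y))
    f1 = float(f1_score(y, pred, average="macro", zero_division=0))
    try:
        if k == 2:
            auc = float(roc_auc_score(y, probs[:, 1]))
        else:
            auc = float(roc_auc_score(y, probs, multi_class="ovr",
                                      average="macro", labels=np.arange(k)))
    except ValueError:
        auc = float("nan")
    return {"loss": loss, "accuracy": acc, "f1": f1, "auc": auc}


def _predict_probs(net: HybridNet, X: np.ndarray, batch: int = 64) -> np.ndarray:
    out = []
    for i in range(0, len(X), batch):
        logits = net.forward(X[i:i + batch], train=False)
        out.append(ad.softmax_probs(logits.data))
    return np.vstack(out)


def train(model: HybridNet, dataset: tuple, cfg: ModelConfig | None = None,
          ) -> tuple[TrainedModel, TrainingHistory]:
    """Fit the hybrid network on (images, labels).

    ``dataset`` is a tuple ``(X, y)`` with X an (n, H, W, C) uint8 array
    and y a sequence of class labels (any hashable).  A stratified
    validation split (``cfg.val_fraction``) is carved out internally;
    training minimizes categorical cross-entropy plus the L2 penalty,
    monitors validation loss, halves the learning rate on plateau,
    stops early on patience exhaustion or when validation accuracy
    exceeds the configured threshold, and restores the best-epoch
    weights.
    """
    cfg = cfg or model.cfg
    X, y_raw = dataset
    X = np.asarray(X)
    classes = sorted(set(y_raw))
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    index = {c: i for i, c in enumerate(classes)}
    y = np.array([index[c] for c in y_raw])
    k = len(classes)

    Xtr, Xva, ytr, yva = train_test_split(
        X, y, test_size=cfg.val_fraction, random_state=cfg.seed, stratify=y)
    if len(Xva) == 0:
        raise ValueError("validation split is empty")

    opt = ad.Adam(model.parameter_list(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    history = TrainingHistory()
    best_loss, best_weights, best_epoch = np.inf, model.get_weights(), 0
    since_best = 0
    stop_reason = "max_epochs"

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(Xtr))
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = Xtr[idx]
            if cfg.augment_data:
                aug_seeds = rng.integers(0, 2 ** 31, size=len(idx))
                xb = np.stack([augment(im, int(s))
                               for im, s in zip(xb, aug_seeds)])
            logits = model.forward(xb, train=True, rng=rng)
            loss = ad.softmax_cross_entropy(logits, _one_hot(ytr[idx], k))
            if cfg.l2_factor > 0:
                for w in model.weight_matrices():
                    loss = loss + cfg.l2_factor * (w * w).sum()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}; aborting training")
            opt.zero_grad()
            loss.backward()
            opt.step()

        tr = _eval_split(model, Xtr, ytr, k)
        va = _eval_split(model, Xva, yva, k)
        history.records.append({"epoch": epoch, "split": "train", **tr})
        history.records.append({"epoch": epoch, "split": "val", **va})

        if va["loss"] < best_loss - 1e-6:
            best_loss, best_epoch, since_best = va["loss"], epoch, 0
            best_weights = model.get_weights()
        else:
            since_best += 1
            if since_best > 0 and since_best % cfg.lr_plateau_patience == 0:
                opt.lr *= cfg.lr_decay_factor
        if va["accuracy"] >= cfg.val_accuracy_threshold:
            stop_reason = "threshold"
            break
        if since_best >= cfg.early_stop_patience:
            stop_reason = "early_stop"
            break

    model.set_weights(best_weights)
    history.best_epoch = best_epoch
    history.stop_reason = stop_reason
    return TrainedModel(net=model, cfg=cfg, classes=classes), history


def predict_proba(model: TrainedModel, images: np.ndarray) -> np.ndarray:
    """Per-image class probability rows (deterministic, dropout off)."""
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    return _predict_probs(model.net, images)
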