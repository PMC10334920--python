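"""Four-regime augmentation experiment for malignant/benign classification.

Training sets are built under four regimes: (a) originals only,
(b) originals plus their generated darker-skin counterparts (tan, brown,
dark), (c) originals plus geometric transforms (flips, rotations, additive
noise), and (d) both. A transfer-learning classifier — frozen convolutional
feature stages, one trainable convolutional stage plus a global-average-pool
softmax head — is trained with Adam (default 30 epochs, learning rate 0.001,
halved after 5 stagnant validation epochs) and evaluated by accuracy with an
exact binomial CI and AUC with a DeLong CI.

The classifier is a scikit-learn-style estimator (fit / predict /
predict_proba, get_params / set_params, trailing-underscore fitted
attributes) so it composes with sklearn model selection. Pretrained deep
backbones are supported only through user-supplied weight files loaded into
the convolutional extractor; every test runs the seeded fixture backbone.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import transform as _transform
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from . import evalstats
from .features import Conv3x3, FeatureExtractor, fixture_extractor
from .fixtures import Manifest
from .generation import _Adam

REGIMES = ("a_none", "b_generated", "c_geometric", "d_both")
DEFAULT_GEOMETRIC_OPS = (
    ("hflip", None),
    ("vflip", None),
    ("rotate", 90.0),
    ("rotate", 180.0),
    ("rotate", 270.0),
    ("noise", 0.02),
)
GENERATED_STYLES = ("tan", "brown", "dark")


# ---------------------------------------------------------------------------
# Dataset splitting and augmentation
# ---------------------------------------------------------------------------


def split_dataset(
    manifest: Manifest, fraction: float = 0.8, seed: int = 0, stratify: bool = True
) -> tuple[Manifest, Manifest]:
    """Random (by default class-stratified) train/validation split.

    Train size is floor(fraction * n); the two parts are disjoint and
    exhaustive, and identical seeds give identical partitions.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    df = manifest.frame
    if len(df) == 0:
        raise ValueError("empty manifest")
    strat = df["class_label"] if stratify else None
    tr, va = train_test_split(
        df, train_size=fraction, random_state=seed, stratify=strat, shuffle=True
    )
    return Manifest(tr.reset_index(drop=True)), Manifest(va.reset_index(drop=True))


def geometric_augment(image: np.ndarray, ops, seed: int = 0) -> list[np.ndarray]:
    """Apply each geometric op to the image (one output per op).

    Ops are (name, param) pairs: ("hflip"/"vflip", None),
    ("rotate", degrees) with reflective border fill, ("noise", sd) with
    seeded Gaussian noise clipped to [0, 1].
    """
    image = np.asarray(image, dtype=float)
    outputs = []
    rng = np.random.default_rng(seed)
    for name, param in ops:
        if name == "hflip":
            outputs.append(image[:, ::-1].copy())
        elif name == "vflip":
            outputs.append(image[::-1].copy())
        elif name == "rotate":
            if param is None or not math.isfinite(float(param)):
                raise ValueError("rotation angle must be finite")
            out = _transform.rotate(image, float(param), mode="reflect", preserve_range=True)
            outputs.append(np.clip(out, 0.0, 1.0))
        elif name == "noise":
            sd = float(param)
            noisy = image + rng.normal(0.0, sd, size=image.shape) if sd > 0 else image.copy()
            outputs.append(np.clip(noisy, 0.0, 1.0))
        else:
            raise ValueError(f"unknown geometric op {name!r}")
    return outputs


@dataclass
class RegimeSpec:
    """One training-set construction regime."""

    regime: str
    geometric_ops: tuple = DEFAULT_GEOMETRIC_OPS
    generated_manifest: pd.DataFrame | None = None

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")


def build_regime(train_manifest: Manifest, spec: RegimeSpec) -> pd.DataFrame:
    """Assemble the training rows for one regime.

    Regime sizes: a = n; b = n + 3 * n_eligible; c = n * (1 + |ops|);
    d = n + 3 * n_eligible + n * |ops|. Augmented and generated rows inherit
    the source image's class label. Rows carry ``source`` (original /
    generated / geometric), ``parent_id`` and ``augment_op`` columns so the
    images can be materialized lazily.
    """
    base = train_manifest.frame.copy()
    base["source"] = "original"
    base["parent_id"] = base["image_id"]
    base["augment_op"] = None
    parts = [base]

    if spec.regime in ("b_generated", "d_both"):
        gen = spec.generated_manifest
        if gen is None:
            raise ValueError("regime b/d requires a generated-image manifest")
        eligible = base[base["tone_category"].isin(("light", "intermediate"))]
        rows = []
        for _, row in eligible.iterrows():
            triple = gen[gen["content_id"] == row.image_id]
            if set(triple["style"]) != set(GENERATED_STYLES):
                raise ValueError(
                    f"missing generated triple for eligible image {row.image_id}"
                )
            for _, g in triple.iterrows():
                rows.append(
                    {
                        "image_id": g.image_id,
                        "path": g.path,
                        "class_label": row.class_label,
                        "disease": row.disease,
                        "dataset_tag": "generated",
                        "tone_category": g.style,
                        "source": "generated",
                        "parent_id": row.image_id,
                        "augment_op": None,
                    }
                )
        if rows:
            parts.append(pd.DataFrame(rows))

    if spec.regime in ("c_geometric", "d_both"):
        rows = []
        for _, row in base.iterrows():
            for name, param in spec.geometric_ops:
                op = name if param is None else f"{name}_{param:g}"
                rows.append(
                    {
                        "image_id": f"{row.image_id}__{op}",
                        "path": row.path,
                        "class_label": row.class_label,
                        "disease": row.disease,
                        "dataset_tag": row.dataset_tag,
                        "tone_category": row.tone_category,
                        "source": "geometric",
                        "parent_id": row.image_id,
                        "augment_op": op,
                    }
                )
        if rows:
            parts.append(pd.DataFrame(rows))

    return pd.concat(parts, ignore_index=True)


def materialize(
    regime_frame: pd.DataFrame,
    image_loader,
    generated_loader=None,
    ops=DEFAULT_GEOMETRIC_OPS,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Load/compute the image array and label vector for a regime frame.

    ``image_loader(image_id)`` yields original images; ``generated_loader``
    yields generated ones. Geometric rows are computed from their parent.
    """
    op_map = {name if p is None else f"{name}_{p:g}": (name, p) for name, p in ops}
    X, y = [], []
    for _, row in regime_frame.iterrows():
        if row.source == "original":
            img = image_loader(row.image_id)
        elif row.source == "generated":
            loader = generated_loader or image_loader
            img = loader(row.image_id)
        else:
            name, param = op_map[row.augment_op]
            img = geometric_augment(image_loader(row.parent_id), [(name, param)], seed=seed)[0]
        X.append(np.asarray(img, dtype=float))
        y.append(row.class_label)
    return np.stack(X), np.asarray(y)


def check_no_leakage(*frames: pd.DataFrame) -> None:
    """Raise if any image (or its augmented descendants) spans partitions."""
    roots = []
    for f in frames:
        col = f["parent_id"] if "parent_id" in f.columns else f["image_id"]
        roots.append(set(col))
    for i in range(len(roots)):
        for j in range(i + 1, len(roots)):
            overlap = roots[i] & roots[j]
            if overlap:
                raise ValueError(f"partition leakage: {sorted(overlap)[:5]}")


# ---------------------------------------------------------------------------
# Transfer-learning classifier
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Training hyperparameters (Adam, plateau-halved learning rate)."""

    backbone: str = "fixture_cnn"
    epochs: int = 30
    learning_rate: float = 0.001
    patience: int = 5
    lr_factor: float = 0.5
    lr_floor: float = 1e-6
    split_fraction: float = 0.8
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split fraction must be in (0, 1)")


class LesionClassifier(BaseEstimator, ClassifierMixin):
    """Malignant/benign classifier with a frozen convolutional backbone.

    The backbone's early stages are frozen feature extractors; the final
    convolutional stage and a global-average-pool + fully connected softmax
    head are trained. With the default fixture backbone the frozen part is
    conv1_1/pool1/conv2_1/pool2 of the seeded extractor and the trainable
    stage is a fresh 3x3 convolution.

    Fitted attributes: ``classes_``, ``history_`` (per-epoch loss/accuracy/
    learning rate), ``conv_``, ``fc_weight_``, ``fc_bias_``.
    """

    def __init__(
        self,
        backbone: str = "fixture_cnn",
        epochs: int = 30,
        learning_rate: float = 0.001,
        patience: int = 5,
        lr_factor: float = 0.5,
        lr_floor: float = 1e-6,
        batch_size: int = 16,
        head_channels: int = 16,
        seed: int = 0,
        extractor: FeatureExtractor | None = None,
    ):
        self.backbone = backbone
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.patience = patience
        self.lr_factor = lr_factor
        self.lr_floor = lr_floor
        self.batch_size = batch_size
        self.head_channels = head_channels
        self.seed = seed
        self.extractor = extractor

    # -- internals ----------------------------------------------------------

    def _build_backbone(self) -> FeatureExtractor:
        if self.extractor is not None:
            return self.extractor
        if self.backbone != "fixture_cnn":
            raise ValueError(
                "only the fixture backbone is built in; supply a FeatureExtractor "
                "loaded from user weights for pretrained backbones"
            )
        return fixture_extractor(seed=self.seed)

    def _frozen_features(self, X: np.ndarray) -> np.ndarray:
        """Frozen-stage features for a batch of (H, W, 3) images."""
        out = []
        for img in X:
            acts, _ = self.backbone_.forward_all(img, upto=self._frozen_top_)
            out.append(acts[self._frozen_top_])
        return np.stack(out)

    def _standardize(self, feats: np.ndarray) -> np.ndarray:
        """Per-channel standardization with statistics frozen at fit time."""
        return (feats - self.feature_mean_[:, None, None]) / self.feature_std_[:, None, None]

    def frozen_checksum(self) -> str:
        """Digest of all frozen-stage weights (stable across training)."""
        h = hashlib.sha256()
        for layer in self.backbone_.layers:
            if isinstance(layer, Conv3x3):
                h.update(layer.weight.tobytes())
                h.update(layer.bias.tobytes())
        return h.hexdigest()

    def _head_forward(self, feats: np.ndarray):
        outs, caches, pooled = [], [], []
        for f in feats:
            y, cache = self.conv_.forward(f)
            outs.append(y)
            caches.append(cache)
            pooled.append(y.mean(axis=(1, 2)))
        pooled = np.stack(pooled)
        logits = pooled @ self.fc_weight_.T + self.fc_bias_
        return logits, pooled, outs, caches

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Train the head on images X (n, H, W, 3) with labels y.

        Validation accuracy (training loss if no validation set is given)
        drives the plateau schedule: the learning rate is halved when the
        metric fails to improve for ``patience`` consecutive epochs.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("training data must contain both classes")
        y_idx = (y == self.classes_[1]).astype(int)

        self.backbone_ = self._build_backbone()
        convs = [l.name for l in self.backbone_.layers if isinstance(l, Conv3x3)]
        pools = [l.name for l in self.backbone_.layers if not isinstance(l, Conv3x3)]
        # freeze everything up to the last pooling stage
        self._frozen_top_ = pools[-1] if pools else convs[-2]
        frozen_channels = next(
            l.out_channels
            for l in reversed(self.backbone_.layers[: self.backbone_.layer_names.index(self._frozen_top_) + 1])
            if isinstance(l, Conv3x3)
        )

        rng = np.random.default_rng(self.seed)
        cw = rng.normal(0, np.sqrt(2.0 / (frozen_channels * 9)),
                        size=(self.head_channels, frozen_channels, 3, 3))
        self.conv_ = Conv3x3("head_conv", cw, np.zeros(self.head_channels))
        self.fc_weight_ = rng.normal(0, 0.01, size=(2, self.head_channels))
        self.fc_bias_ = np.zeros(2)

        feats = self._frozen_features(X)
        # standardize the frozen features per channel (statistics frozen at
        # fit time) so head optimization is well conditioned regardless of
        # backbone activation scale
        self.feature_mean_ = feats.mean(axis=(0, 2, 3))
        self.feature_std_ = np.maximum(feats.std(axis=(0, 2, 3)), 1e-6)
        feats = self._standardize(feats)
        feats_val = (
            self._standardize(self._frozen_features(np.asarray(X_val, dtype=float)))
            if X_val is not None
            else None
        )
        y_val_idx = (np.asarray(y_val) == self.classes_[1]).astype(int) if y_val is not None else None

        opts = {
            "cw": _Adam(self.conv_.weight.shape, self.learning_rate),
            "cb": _Adam(self.conv_.bias.shape, self.learning_rate),
            "fw": _Adam(self.fc_weight_.shape, self.learning_rate),
            "fb": _Adam(self.fc_bias_.shape, self.learning_rate),
        }
        lr = self.learning_rate
        best_metric, stagnant = -np.inf, 0
        history = []
        n = len(X)

        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                fb = feats[idx]
                yb = y_idx[idx]
                logits, pooled, outs, caches = self._head_forward(fb)
                probs = self._softmax(logits)
                eps = 1e-12
                loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + eps))
                epoch_loss += loss * len(yb)

                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                dfw = dlogits.T @ pooled
                dfb = dlogits.sum(axis=0)
                dpooled = dlogits @ self.fc_weight_
                dcw = np.zeros_like(self.conv_.weight)
                dcb = np.zeros_like(self.conv_.bias)
                for i in range(len(yb)):
                    hsp = outs[i].shape[1] * outs[i].shape[2]
                    dy = np.broadcast_to(
                        dpooled[i][:, None, None] / hsp, outs[i].shape
                    )
                    _, dW_i, db_i = self.conv_.backward(dy, caches[i], weight_grads=True)
                    dcw += dW_i
                    dcb += db_i

                for opt in opts.values():
                    opt.lr = lr
                self.conv_.weight = opts["cw"].step(self.conv_.weight, dcw)
                self.conv_.bias = opts["cb"].step(self.conv_.bias, dcb)
                self.fc_weight_ = opts["fw"].step(self.fc_weight_, dfw)
                self.fc_bias_ = opts["fb"].step(self.fc_bias_, dfb)

            train_acc = float(np.mean(self._predict_idx_from_feats(feats) == y_idx))
            if feats_val is not None:
                metric = float(np.mean(self._predict_idx_from_feats(feats_val) == y_val_idx))
            else:
                # no validation set: track training loss (continuous) instead
                # of accuracy (a step function that stalls the schedule)
                metric = -epoch_loss / n
            history.append(
                {
                    "epoch": epoch,
                    "loss": epoch_loss / n,
                    "train_accuracy": train_acc,
                    "val_accuracy": metric if feats_val is not None else np.nan,
                    "lr": lr,
                }
            )
            if metric > best_metric:
                best_metric, stagnant = metric, 0
            else:
                stagnant += 1
                if stagnant >= self.patience:
                    lr = max(lr * self.lr_factor, self.lr_floor)
                    stagnant = 0

        self.history_ = pd.DataFrame(history)
        return self

    def _predict_idx_from_feats(self, feats: np.ndarray) -> np.ndarray:
        logits, _, _, _ = self._head_forward(feats)
        return logits.argmax(axis=1)

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "history_"):
            raise RuntimeError("classifier is not fitted")
        feats = self._standardize(self._frozen_features(np.asarray(X, dtype=float)))
        logits, _, _, _ = self._head_forward(feats)
        return self._softmax(logits)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]

    def decision_scores(self, X) -> np.ndarray:
        """Softmax probability of the positive (second) class."""
        return self.predict_proba(X)[:, 1]


def evaluate(model: LesionClassifier, X_test, y_test, level: float = 0.95) -> dict:
    """Held-out evaluation: accuracy (exact binomial CI), AUC (DeLong CI),
    ROC points and per-case scores."""
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    scores = model.decision_scores(X_test)
    y_bin = (y_test == model.classes_[1]).astype(int)
    pred = (scores >= 0.5).astype(int)
    correct = int((pred == y_bin).sum())
    acc_ci = evalstats.clopper_pearson(correct, len(y_test), level)
    auc, var = evalstats.delong_variance(scores, y_bin)
    from scipy import stats as _st

    half = float(_st.norm.ppf(1 - (1 - level) / 2) * np.sqrt(var))
    return {
        "accuracy": acc_ci,
        "auc": auc,
        "auc_ci": (max(auc - half, 0.0), min(auc + half, 1.0)),
        "roc": evalstats.roc_points(scores, y_bin),
        "scores": pd.DataFrame({"score": scores, "label": y_bin}),
    }
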