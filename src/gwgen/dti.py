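"""Drug--target interaction prediction.

Pairs are represented by the concatenation of a drug descriptor vector
(default 363 features) and a target descriptor vector (default 996),
standardized and reduced by PCA (default 1000 components at full scale).
The classifier is a feed-forward network with ReLU hidden layers
(default widths 512/256/128/64 with per-layer dropout 0.5/0.4/0.3/0.1),
a single sigmoid output unit, binary cross-entropy loss and the Adam
optimizer (learning rate 0.003).  Data are split 70/30 train/test with
10% of all data carved out of the train share for validation; class
balance is enforced by down-sampling unknown pairs to the number of
known interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler


@dataclass
class DTIModelConfig:
    pca_components: int = 1000
    hidden_widths: tuple[int, ...] = (512, 256, 128, 64)
    dropout: tuple[float, ...] = (0.5, 0.4, 0.3, 0.1)
    learning_rate: float = 0.003
    epochs: int = 100
    batch_size: int = 128
    patience: int = 10              # early stopping on validation loss
    test_fraction: float = 0.30
    validation_fraction: float = 0.10   # of ALL data, taken from train share
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_widths) != len(self.dropout):
            raise ValueError("hidden_widths and dropout must have equal length")


def assemble_feature_vector(D: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Concatenate drug and target descriptors, drug block first."""
    D = np.asarray(D, dtype=float).ravel()
    T = np.asarray(T, dtype=float).ravel()
    if D.size == 0 or T.size == 0:
        raise ValueError("descriptor blocks must be non-empty")
    if not (np.all(np.isfinite(D)) and np.all(np.isfinite(T))):
        raise ValueError("descriptors must be finite")
    return np.concatenate([D, T])


def balance_classes(known_pairs: list[tuple[str, str]],
                    all_pairs: list[tuple[str, str]],
                    seed: int = 0) -> pd.DataFrame:
    """Balanced labeled pair set: all known interactions plus an equal-size
    uniform sample (without replacement) of unknown pairs."""
    known = set(known_pairs)
    unknown = [p for p in all_pairs if p not in known]
    if len(unknown) < len(known):
        raise ValueError("not enough unknown pairs to balance the classes")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(unknown), size=len(known), replace=False)
    rows = [(d, t, 1) for d, t in sorted(known)]
    rows += [(*unknown[i], 0) for i in sorted(picks)]
    return pd.DataFrame(rows, columns=["drug_id", "target_id", "label"])


class Preprocessor:
    """Standardization + PCA fitted on the training split only."""

    def __init__(self, pca_components: int, seed: int = 0):
        self.pca_components = pca_components
        self.seed = seed
        self.scaler: StandardScaler | None = None
        self.pca: PCA | None = None

    def fit(self, X: np.ndarray) -> "Preprocessor":
        if X.shape[0] < 2:
            raise ValueError("need >= 2 training rows")
        self.scaler = StandardScaler().fit(X)
        zero_var = self.scaler.var_ <= 1e-12
        if np.any(zero_var):
            warnings.warn(f"{int(zero_var.sum())} zero-variance features; "
                          "variance floored")
            self.scaler.var_ = np.maximum(self.scaler.var_, 1e-12)
            self.scaler.scale_ = np.sqrt(self.scaler.var_)
        n_comp = min(self.pca_components, X.shape[1], X.shape[0])
        self.pca = PCA(n_components=n_comp, svd_solver="full",
                       random_state=self.seed)
        self.pca.fit(self.scaler.transform(X))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.scaler is None or self.pca is None:
            raise RuntimeError("preprocessor not fitted")
        return self.pca.transform(self.scaler.transform(X))


def fit_preprocessor(train: np.ndarray, cfg: DTIModelConfig) -> Preprocessor:
    return Preprocessor(cfg.pca_components, cfg.seed).fit(train)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MLP:
    """Feed-forward binary classifier: ReLU hidden layers with inverted
    dropout, sigmoid output, binary cross-entropy loss, Adam updates."""

    def __init__(self, n_inputs: int, hidden_widths: tuple[int, ...],
                 dropout: tuple[float, ...], seed: int = 0):
        rng = np.random.default_rng(seed)
        sizes = [n_inputs, *hidden_widths, 1]
        self.W = [rng.normal(0.0, np.sqrt(2.0 / sizes[i]),
                             size=(sizes[i], sizes[i + 1]))
                  for i in range(len(sizes) - 1)]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.dropout = dropout
        self._rng = rng
        # Adam state
        self._mW = [np.zeros_like(w) for w in self.W]
        self._vW = [np.zeros_like(w) for w in self.W]
        self._mb = [np.zeros_like(b) for b in self.b]
        self._vb = [np.zeros_like(b) for b in self.b]
        self._t = 0

    def _forward(self, X: np.ndarray, train: bool):
        acts = [X]
        masks = []
        h = X
        for li, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if li < len(self.W) - 1:
                h = np.maximum(z, 0.0)
                if train and self.dropout[li] > 0:
                    keep = 1.0 - self.dropout[li]
                    mask = (self._rng.random(h.shape) < keep) / keep
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                acts.append(h)
            else:
                h = _sigmoid(z.ravel())
        return h, acts, masks

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p, _, _ = self._forward(np.asarray(X, dtype=float), train=False)
        return p

    def _adam_step(self, gW, gb, lr: float):
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._t += 1
        for i in range(len(self.W)):
            self._mW[i] = b1 * self._mW[i] + (1 - b1) * gW[i]
            self._vW[i] = b2 * self._vW[i] + (1 - b2) * gW[i] ** 2
            self._mb[i] = b1 * self._mb[i] + (1 - b1) * gb[i]
            self._vb[i] = b2 * self._vb[i] + (1 - b2) * gb[i] ** 2
            mW = self._mW[i] / (1 - b1 ** self._t)
            vW = self._vW[i] / (1 - b2 ** self._t)
            mb = self._mb[i] / (1 - b1 ** self._t)
            vb = self._vb[i] / (1 - b2 ** self._t)
            self.W[i] -= lr * mW / (np.sqrt(vW) + eps)
            self.b[i] -= lr * mb / (np.sqrt(vb) + eps)

    def train_batch(self, X: np.ndarray, y: np.ndarray, lr: float) -> float:
        n = X.shape[0]
        p, acts, masks = self._forward(X, train=True)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        # BCE + sigmoid: delta at the output is (p - y) / n
        delta = ((p - y) / n)[:, None]
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for li in range(len(self.W) - 1, -1, -1):
            h_in = acts[li]
            gW[li] = h_in.T @ delta
            gb[li] = delta.sum(axis=0)
            if li > 0:
                delta = delta @ self.W[li].T
                delta = delta * (acts[li] > 0)
                if masks[li - 1] is not None:
                    delta = delta * masks[li - 1]
        self._adam_step(gW, gb, lr)
        return loss


@dataclass
class TrainedDTIModel:
    preprocessor: Preprocessor
    net: MLP
    config: DTIModelConfig
    metrics: dict[str, float] = field(default_factory=dict)

    def predict_proba(self, X_raw: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self.preprocessor.transform(X_raw))


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _accuracy(p: np.ndarray, y: np.ndarray, thr: float) -> float:
    return float(np.mean((p >= thr).astype(int) == y))


def train_dti_network(X: np.ndarray, y: np.ndarray,
                      cfg: DTIModelConfig) -> TrainedDTIModel:
    """Split, preprocess (fit on train only), train with early stopping,
    and report train/validation/test accuracy at the 0.5 threshold."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    order = rng.permutation(n)
    n_test = int(round(cfg.test_fraction * n))
    n_val = int(round(cfg.validation_fraction * n))
    test_idx = order[:n_test]
    val_idx = order[n_test:n_test + n_val]
    train_idx = order[n_test + n_val:]

    pre = fit_preprocessor(X[train_idx], cfg)
    Xtr, ytr = pre.transform(X[train_idx]), y[train_idx]
    Xva, yva = pre.transform(X[val_idx]), y[val_idx]
    Xte, yte = pre.transform(X[test_idx]), y[test_idx]

    net = MLP(Xtr.shape[1], cfg.hidden_widths, cfg.dropout, seed=cfg.seed)
    best_val = np.inf
    best_state = None
    stall = 0
    for _ in range(cfg.epochs):
        perm = rng.permutation(Xtr.shape[0])
        for start in range(0, Xtr.shape[0], cfg.batch_size):
            sel = perm[start:start + cfg.batch_size]
            net.train_batch(Xtr[sel], ytr[sel], cfg.learning_rate)
        val_loss = _bce(net.predict_proba(Xva), yva) if len(yva) else _bce(
            net.predict_proba(Xtr), ytr)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = ([w.copy() for w in net.W], [b.copy() for b in net.b])
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    if best_state is not None:
        net.W, net.b = best_state

    metrics = {
        "train_accuracy": _accuracy(net.predict_proba(Xtr), ytr, cfg.threshold),
        "validation_accuracy": _accuracy(net.predict_proba(Xva), yva,
                                         cfg.threshold) if len(yva) else np.nan,
        "test_accuracy": _accuracy(net.predict_proba(Xte), yte, cfg.threshold),
    }
    return TrainedDTIModel(pre, net, cfg, metrics)


def predict_interaction(model: TrainedDTIModel,
                        biomarker_targets: list[str],
                        drug_library: list[str],
                        drug_descriptors: pd.DataFrame,
                        target_descriptors: pd.DataFrame,
                        threshold: float | None = None) -> pd.DataFrame:
    """Interaction probability for every (drug, biomarker target) pair with
    available descriptors, ranked descending; ``candidate`` marks pairs
    above the decision threshold."""
    thr = model.config.threshold if threshold is None else threshold
    rows = []
    feats = []
    for d in drug_library:
        if d not in drug_descriptors.index:
            warnings.warn(f"no descriptor for drug {d!r}; skipped")
            continue
        for t in biomarker_targets:
            if t not in target_descriptors.index:
                warnings.warn(f"no descriptor for target {t!r}; skipped")
                continue
            rows.append((d, t))
            feats.append(assemble_feature_vector(
                drug_descriptors.loc[d].to_numpy(),
                target_descriptors.loc[t].to_numpy()))
    if not rows:
        return pd.DataFrame(columns=["drug_id", "target_id", "probability",
                                     "candidate"])
    probs = model.predict_proba(np.vstack(feats))
    out = pd.DataFrame(rows, columns=["drug_id", "target_id"])
    out["probability"] = probs
    out["candidate"] = out["probability"] >= thr
    return out.sort_values(["probability", "drug_id", "target_id"],
                           ascending=[False, True, True],
                           kind="stable").reset_index(drop=True)
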