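"""Model facade: fit a rhythm classifier to a labeled ISI dataset.

`RhythmClassifier` is constructed from data (arrays or a
:class:`~spikerhythm.datasets.LabeledDataset`); ``fit`` runs the full
procedure — greedy unsupervised pretraining of the two sparse auto-encoder
layers, computation of the two scalar time-series features, and supervised
fine-tuning of a softmax head on the fused feature vector — and returns a
`RhythmClassifierResults` carrying the trained parameters, the optimization
trajectories and evaluation helpers.  ``pretrain`` exposes the intermediate
stage so several fusion configurations can be fine-tuned from one
pretraining run (the feature-ablation experiment).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .evaluation import ConfusionMatrix, confusion_matrix, overall_accuracy
from .features import FeatureScaler, feature_table
from .optimize import minimize
from .sae import SAEConfig, SAELayer, encode, sigmoid, stack_pretrain
from .softmax import softmax_probs

__all__ = ["RhythmClassifier", "PretrainedStack", "RhythmClassifierResults",
           "finetune_cost_and_grad"]


def finetune_cost_and_grad(flat: np.ndarray, H1: np.ndarray, extras: np.ndarray,
                           y: np.ndarray, k: int, h1: int, h2: int,
                           scope: str = "top", l2_theta: float = 0.0):
    """Cross-entropy cost/gradient of the softmax head, optionally
    backpropagated into the top encoder layer.

    ``flat`` packs θ (k × (h2 + n_extra + 1), intercept last) and, when
    ``scope == 'top'``, the second-layer encoder weights W (h2 × h1) and
    bias (h2,).  ``H1`` is the (fixed) first-layer code, ``extras`` the
    scaled scalar features.
    """
    m = H1.shape[0]
    n_extra = extras.shape[1]
    D = h2 + n_extra
    n_theta = k * (D + 1)
    theta = flat[:n_theta].reshape(k, D + 1)
    if scope == "top":
        W = flat[n_theta:n_theta + h2 * h1].reshape(h2, h1)
        b = flat[n_theta + h2 * h1:]
    else:
        W, b = None, None

    code = sigmoid(H1 @ W.T + b) if scope == "top" else H1  # H1 is code in head mode
    F = np.hstack([code, extras, np.ones((m, 1))])
    P = softmax_probs(theta, F)
    cost = -np.mean(np.log(np.clip(P[np.arange(m), y], 1e-300, None)))
    cost += 0.5 * l2_theta * np.sum(theta[:, :-1] ** 2)

    Y = np.zeros_like(P)
    Y[np.arange(m), y] = 1.0
    dlogits = (P - Y) / m
    gtheta = dlogits.T @ F
    gtheta[:, :-1] += l2_theta * theta[:, :-1]
    if scope == "top":
        dcode = (dlogits @ theta[:, :h2]) * code * (1.0 - code)
        gW = dcode.T @ H1
        gb = dcode.sum(axis=0)
        grad = np.concatenate([gtheta.ravel(), gW.ravel(), gb])
    else:
        grad = gtheta.ravel()
    return cost, grad


@dataclass
class RhythmClassifier:
    """Rhythm classification model bound to training data.

    Parameters
    ----------
    X, y : training matrix of normalized length-1024 ISI vectors in [0, 1]
        and integer class labels 0..3.
    config : auto-encoder/classifier hyper-parameters (Table-style defaults:
        1024 → 1224 → 824, λ = 0.01, β = 0.1, SCG).
    cov_mode, apen_m, apen_r_frac : settings of the two scalar features.
    """

    X: np.ndarray
    y: np.ndarray
    config: SAEConfig = field(default_factory=SAEConfig)
    cov_mode: str = "cv"
    apen_m: int = 2
    apen_r_frac: float = 0.2
    softmax_l2: float = 1e-4

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=int)
        if len(self.y) != self.X.shape[0]:
            raise ValueError("X and y length mismatch")
        if len(self.y) and (self.y.min() < 0 or self.y.max() > 3):
            raise ValueError("labels must lie in {0,1,2,3}")
        if self.X.shape[1] != self.config.layer_sizes[0]:
            self.config = self.config.with_sizes(
                (self.X.shape[1],) + tuple(self.config.layer_sizes[1:]))

    @classmethod
    def from_dataset(cls, dataset, config: Optional[SAEConfig] = None, **kwargs
                     ) -> "RhythmClassifier":
        X, y = dataset.train_arrays
        return cls(X=X, y=y, config=config or SAEConfig(), **kwargs)

    @classmethod
    def from_dataframe(cls, df, label_col: str = "label",
                       config: Optional[SAEConfig] = None, **kwargs
                       ) -> "RhythmClassifier":
        y = df[label_col].to_numpy(dtype=int)
        X = df.drop(columns=[label_col]).to_numpy(dtype=float)
        return cls(X=X, y=y, config=config or SAEConfig(), **kwargs)

    # -- fitting ------------------------------------------------------------

    def pretrain(self, seed: Optional[int] = None) -> "PretrainedStack":
        """Greedy unsupervised pretraining plus scalar-feature extraction."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        layer1, layer2 = stack_pretrain(self.X, cfg, rng=rng)
        scalars = feature_table(self.X, m=self.apen_m, r_frac=self.apen_r_frac,
                                cov_mode=self.cov_mode)
        scaler = FeatureScaler(kind="minmax").fit(scalars)
        return PretrainedStack(model=self, layer1=layer1, layer2=layer2,
                               train_scalars=scalars, scaler=scaler, rng=rng)

    def fit(self, seed: Optional[int] = None, use_cov: bool = True,
            use_apen: bool = True) -> "RhythmClassifierResults":
        """Pretrain and fine-tune in one call; returns the fitted results."""
        return self.pretrain(seed=seed).fine_tune(use_cov=use_cov, use_apen=use_apen)


@dataclass
class PretrainedStack:
    """Intermediate state after unsupervised pretraining; fine-tune one or
    more fusion configurations from here."""

    model: RhythmClassifier
    layer1: SAELayer
    layer2: SAELayer
    train_scalars: np.ndarray
    scaler: FeatureScaler
    rng: np.random.Generator

    def fine_tune(self, use_cov: bool = True, use_apen: bool = True
                  ) -> "RhythmClassifierResults":
        """Supervised stage: optimize the softmax head (and, by default, the
        top encoder layer) on the fused features for ``sup_epochs``."""
        m = self.model
        cfg = m.config
        k = 4
        scope = "top" if cfg.finetune_scope == "top" else "head"
        H1 = encode(m.X, self.layer1)
        if scope == "head":
            # encoder frozen: precompute the code once
            H1 = encode(H1, self.layer2)
        scaled = self.scaler.transform(self.train_scalars)
        cols = ([0] if use_cov else []) + ([1] if use_apen else [])
        extras = scaled[:, cols] if cols else np.empty((H1.shape[0], 0))
        h1, h2 = cfg.layer_sizes[1], cfg.layer_sizes[2]
        D = h2 + extras.shape[1]
        theta0 = np.zeros((k, D + 1))
        flat0 = theta0.ravel()
        # fine-tuning starts from the pretrained encoder weights
        layer2 = self.layer2
        if scope == "top":
            flat0 = np.concatenate([flat0, layer2.W1.ravel(), layer2.b1])

        y = m.y

        def fun(flat):
            return finetune_cost_and_grad(flat, H1, extras, y, k, h1, h2,
                                          scope=scope, l2_theta=m.softmax_l2)

        res = minimize(fun, flat0, method=cfg.optimizer, max_iter=cfg.sup_epochs)
        n_theta = k * (D + 1)
        theta = res.x[:n_theta].reshape(k, D + 1)
        if scope == "top":
            W = res.x[n_theta:n_theta + h2 * h1].reshape(h2, h1)
            b = res.x[n_theta + h2 * h1:]
            layer2 = SAELayer(W1=W, b1=b, W2=self.layer2.W2.copy(),
                              b2=self.layer2.b2.copy())
        return RhythmClassifierResults(
            model=m, layer1=self.layer1, layer2=layer2, theta=theta,
            scaler=self.scaler, use_cov=use_cov, use_apen=use_apen,
            finetune_history=res.cost_history,
            pretrain_histories=(list(self.layer1.cost_history),
                                list(self.layer2.cost_history)),
        )


@dataclass
class RhythmClassifierResults:
    """Fitted classifier: trained stack, softmax parameters, diagnostics."""

    model: RhythmClassifier
    layer1: SAELayer
    layer2: SAELayer
    theta: np.ndarray
    scaler: FeatureScaler
    use_cov: bool
    use_apen: bool
    finetune_history: list = field(default_factory=list)
    pretrain_histories: Tuple[list, list] = (None, None)

    # -- prediction ---------------------------------------------------------

    def _fused(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        code = encode(encode(X, self.layer1), self.layer2)
        scalars = feature_table(X, m=self.model.apen_m,
                                r_frac=self.model.apen_r_frac,
                                cov_mode=self.model.cov_mode)
        scaled = self.scaler.transform(scalars)
        cols = ([0] if self.use_cov else []) + ([1] if self.use_apen else [])
        extras = scaled[:, cols] if cols else np.empty((X.shape[0], 0))
        return np.hstack([code, extras, np.ones((X.shape[0], 1))])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax_probs(self.theta, self._fused(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def evaluate(self, X: np.ndarray, y: np.ndarray) -> ConfusionMatrix:
        return confusion_matrix(np.asarray(y, dtype=int), self.predict(X))

    # -- reporting ----------------------------------------------------------

    @property
    def train_accuracy(self) -> float:
        return overall_accuracy(self.evaluate(self.model.X, self.model.y))

    def summary(self, X_test: Optional[np.ndarray] = None,
                y_test: Optional[np.ndarray] = None) -> str:
        cfg = self.model.config
        feats = "code"
        if self.use_cov:
            feats += " + dispersion"
        if self.use_apen:
            feats += " + ApEn"
        lines = [
            "Rhythm classifier (stacked sparse auto-encoder + softmax)",
            "=" * 58,
            f"layers: {cfg.layer_sizes[0]} -> {cfg.layer_sizes[1]} -> "
            f"{cfg.layer_sizes[2]} -> 4   features: {feats}",
            f"l2 weight: {cfg.l2_weight}   sparsity beta: {cfg.sparsity_weight}"
            f"   target rho: {cfg.sparsity_target}   optimizer: {cfg.optimizer}",
            f"pretrain cost (layer1): {self.pretrain_histories[0][0]:.4f} -> "
            f"{self.pretrain_histories[0][-1]:.4f}"
            if self.pretrain_histories[0] else "",
            f"pretrain cost (layer2): {self.pretrain_histories[1][0]:.4f} -> "
            f"{self.pretrain_histories[1][-1]:.4f}"
            if self.pretrain_histories[1] else "",
            f"fine-tune cross-entropy: {self.finetune_history[0]:.4f} -> "
            f"{self.finetune_history[-1]:.4f}",
            f"training accuracy: {self.train_accuracy:.2f}%",
        ]
        if X_test is not None and y_test is not None:
            cm = self.evaluate(X_test, y_test)
            lines += ["", "test confusion matrix:", str(cm)]
        return "\n".join(s for s in lines if s != "")

    def plot_confusion(self, X: np.ndarray, y: np.ndarray, ax=None):
        import matplotlib.pyplot as plt

        cm = self.evaluate(X, y)
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(cm.counts, cmap="Blues")
        names = list(cm.class_names)
        ax.set_xticks(range(cm.k), [f"{n}_p" for n in names])
        ax.set_yticks(range(cm.k), [f"{n}_t" for n in names])
        for i in range(cm.k):
            for j in range(cm.k):
                ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center")
        ax.figure.colorbar(im, ax=ax)
        return ax

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Bit-exact persistence: arrays in .npz with a JSON manifest."""
        cfg = self.model.config
        manifest = {
            "layer_sizes": list(cfg.layer_sizes),
            "l2_weight": cfg.l2_weight,
            "sparsity_weight": cfg.sparsity_weight,
            "sparsity_target": cfg.sparsity_target,
            "unsup_epochs": cfg.unsup_epochs,
            "sup_epochs": cfg.sup_epochs,
            "optimizer": cfg.optimizer,
            "finetune_scope": cfg.finetune_scope,
            "use_cov": self.use_cov,
            "use_apen": self.use_apen,
            "cov_mode": self.model.cov_mode,
            "apen_m": self.model.apen_m,
            "apen_r_frac": self.model.apen_r_frac,
            "scaler_kind": self.scaler.kind,
        }
        np.savez(
            path,
            manifest=json.dumps(manifest),
            l1_W1=self.layer1.W1, l1_b1=self.layer1.b1,
            l1_W2=self.layer1.W2, l1_b2=self.layer1.b2,
            l2_W1=self.layer2.W1, l2_b1=self.layer2.b1,
            l2_W2=self.layer2.W2, l2_b2=self.layer2.b2,
            theta=self.theta,
            scaler_lo=self.scaler.lo_, scaler_hi=self.scaler.hi_,
            scaler_mean=self.scaler.mean_, scaler_sd=self.scaler.sd_,
            finetune_history=np.asarray(self.finetune_history),
        )

    @classmethod
    def load(cls, path) -> "RhythmClassifierResults":
        with np.load(path, allow_pickle=False) as z:
            manifest = json.loads(str(z["manifest"]))
            layer1 = SAELayer(W1=z["l1_W1"], b1=z["l1_b1"], W2=z["l1_W2"], b2=z["l1_b2"])
            layer2 = SAELayer(W1=z["l2_W1"], b1=z["l2_b1"], W2=z["l2_W2"], b2=z["l2_b2"])
            theta = z["theta"]
            scaler = FeatureScaler(kind=manifest["scaler_kind"], lo_=z["scaler_lo"],
                                   hi_=z["scaler_hi"], mean_=z["scaler_mean"],
                                   sd_=z["scaler_sd"])
            history = z["finetune_history"].tolist()
        cfg = SAEConfig(layer_sizes=tuple(manifest["layer_sizes"]),
                        l2_weight=manifest["l2_weight"],
                        sparsity_weight=manifest["sparsity_weight"],
                        sparsity_target=manifest["sparsity_target"],
                        unsup_epochs=manifest["unsup_epochs"],
                        sup_epochs=manifest["sup_epochs"],
                        optimizer=manifest["optimizer"],
                        finetune_scope=manifest["finetune_scope"])
        stub = RhythmClassifier(X=np.zeros((1, cfg.layer_sizes[0])), y=np.zeros(1, int),
                                config=cfg, cov_mode=manifest["cov_mode"],
                                apen_m=manifest["apen_m"],
                                apen_r_frac=manifest["apen_r_frac"])
        return cls(model=stub, layer1=layer1, layer2=layer2, theta=theta,
                   scaler=scaler, use_cov=manifest["use_cov"],
                   use_apen=manifest["use_apen"], finetune_history=history)
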