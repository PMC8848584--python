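"""Confusion matrices, overall accuracy and the feature-ablation experiment.

The confusion matrix follows the convention rows = true class, columns =
predicted class; overall accuracy is 100 · trace / total.  The module also
carries the published reference confusion matrices of the four-way feature
ablation (code only / +dispersion / +ApEn / +both) as worked-example data,
and `run_ablation`, which re-runs that experiment on a dataset across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .spikes import CLASS_NAMES

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "overall_accuracy",
    "REFERENCE_TABLES",
    "AblationReport",
    "run_ablation",
    "ABLATION_CONFIGS",
]

# Published reference confusion matrices of the feature-ablation experiment
# (rows = true class PD/RD/CD/IMD, columns = predicted), used as
# worked-example inputs for the accuracy computation.
REFERENCE_TABLES: Dict[str, list] = {
    "code_only": [[15, 3, 2, 0],
                  [4, 2, 11, 3],
                  [2, 0, 18, 0],
                  [0, 0, 0, 20]],
    "code_cov": [[15, 3, 2, 0],
                 [5, 8, 7, 0],
                 [2, 0, 18, 0],
                 [0, 0, 0, 20]],
    "code_apen": [[16, 2, 2, 0],
                  [5, 5, 10, 0],
                  [2, 1, 17, 0],
                  [0, 0, 0, 20]],
    "code_both": [[17, 1, 2, 0],
                  [2, 17, 1, 0],
                  [1, 3, 16, 0],
                  [0, 0, 0, 20]],
}

# Published overall accuracies of the comparison methods on the same task.
REFERENCE_BASELINES = {"KNN": 65.00, "SVM": 68.75, "SAE": 68.75, "proposed": 87.50}

# the four fusion configurations: (name, use_cov, use_apen)
ABLATION_CONFIGS = (
    ("code_only", False, False),
    ("code_cov", True, False),
    ("code_apen", False, True),
    ("code_both", True, True),
)


@dataclass
class ConfusionMatrix:
    """k×k counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: Sequence[str] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __str__(self) -> str:
        names = list(self.class_names)[: self.k]
        width = max(7, max(len(n) for n in names) + 3)
        head = " " * width + "".join(f"{n + '_p':>{width}}" for n in names)
        rows = [head]
        for i, n in enumerate(names):
            rows.append(f"{n + '_t':<{width}}"
                        + "".join(f"{c:>{width}d}" for c in self.counts[i]))
        rows.append(f"overall accuracy: {overall_accuracy(self):.2f}%")
        return "\n".join(rows)


def confusion_matrix(y_true, y_pred, k: int = 4) -> ConfusionMatrix:
    """counts[i, j] = number of sequences of true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if len(arr) and (arr.min() < 0 or arr.max() >= k):
            raise ValueError(f"{name} contains labels outside 0..{k - 1}")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts=counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """100 · Σᵢ Nᵢᵢ / Σᵢⱼ Nᵢⱼ (percentage)."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / total


@dataclass
class AblationReport:
    """Per-configuration confusion matrices and accuracies across seeds."""

    matrices: Dict[str, List[ConfusionMatrix]]
    accuracies: Dict[str, List[float]]
    baseline_accuracies: Dict[str, float]
    seeds: List[int]
    config: dict = field(default_factory=dict)

    def mean_accuracy(self, name: str) -> float:
        return float(np.mean(self.accuracies[name]))

    def sd_accuracy(self, name: str) -> float:
        return float(np.std(self.accuracies[name]))

    def summary(self) -> str:
        lines = [f"Feature-ablation report over seeds {self.seeds}"]
        for name, _, _ in ABLATION_CONFIGS:
            accs = self.accuracies[name]
            lines.append(f"  {name:>10}: mean {np.mean(accs):6.2f}%  "
                         f"sd {np.std(accs):5.2f}  runs {np.round(accs, 2).tolist()}")
        for name, acc in self.baseline_accuracies.items():
            lines.append(f"  {name:>10}: {acc:6.2f}% (baseline)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "seeds": self.seeds,
            "accuracies": {k: list(map(float, v)) for k, v in self.accuracies.items()},
            "mean_accuracies": {k: self.mean_accuracy(k) for k in self.accuracies},
            "baseline_accuracies": self.baseline_accuracies,
            "matrices": {k: [m.counts.tolist() for m in v]
                         for k, v in self.matrices.items()},
            "config": self.config,
        }


def run_ablation(dataset, config=None, seeds: Sequence[int] = (0, 1, 2, 3, 4),
                 with_baselines: bool = True) -> AblationReport:
    """Train the stack once per seed and evaluate the four fusion
    configurations (code only, +dispersion, +ApEn, +both) on the test split.

    ``config`` is an :class:`~spikerhythm.sae.SAEConfig` or None for defaults.
    """
    from .model import RhythmClassifier  # deferred: model builds on this module

    Xte, yte = dataset.test_arrays
    matrices: Dict[str, List[ConfusionMatrix]] = {n: [] for n, _, _ in ABLATION_CONFIGS}
    accs: Dict[str, List[float]] = {n: [] for n, _, _ in ABLATION_CONFIGS}
    for seed in seeds:
        model = RhythmClassifier.from_dataset(dataset, config=config)
        pretrained = model.pretrain(seed=seed)
        for name, use_cov, use_apen in ABLATION_CONFIGS:
            res = pretrained.fine_tune(use_cov=use_cov, use_apen=use_apen)
            cm = res.evaluate(Xte, yte)
            matrices[name].append(cm)
            accs[name].append(overall_accuracy(cm))
    baseline_accs: Dict[str, float] = {}
    if with_baselines:
        from .baselines import knn_baseline, svm_baseline

        Xtr, ytr = dataset.train_arrays
        baseline_accs["KNN"] = overall_accuracy(
            confusion_matrix(yte, knn_baseline(Xtr, ytr, Xte)))
        baseline_accs["SVM"] = overall_accuracy(
            confusion_matrix(yte, svm_baseline(Xtr, ytr, Xte)))
    cfg_dict = {} if config is None else {
        "layer_sizes": list(config.layer_sizes),
        "l2_weight": config.l2_weight,
        "sparsity_weight": config.sparsity_weight,
        "sparsity_target": config.sparsity_target,
        "unsup_epochs": config.unsup_epochs,
        "sup_epochs": config.sup_epochs,
        "optimizer": config.optimizer,
        "finetune_scope": config.finetune_scope,
    }
    return AblationReport(matrices=matrices, accuracies=accs,
                          baseline_accuracies=baseline_accs,
                          seeds=list(seeds), config=cfg_dict)
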