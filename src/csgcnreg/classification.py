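"""Biomarker-set validation by MLP sample classification.

Condition-specific gene sets are validated by asking whether a small
multilayer perceptron (three hidden layers of 512, 256 and 128 ReLU
units, softmax output) can recover sample condition labels from the
sub-GEM restricted to those genes.  70% of samples train the model
(stratified by class so no class is empty at small n), the held-out 30%
yield the confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from .gem_io import GEM, SampleAnnotation

__all__ = [
    "ClassifierConfig",
    "ClassificationReport",
    "subset_gem",
    "train_evaluate",
]


@dataclass
class ClassifierConfig:
    hidden_sizes: tuple[int, ...] = (512, 256, 128)
    activation: str = "relu"
    train_fraction: float = 0.70
    seed: int = 0
    max_epochs: int = 300
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class ClassificationReport:
    confusion: pd.DataFrame  # true condition (rows) x predicted (cols)
    per_class_accuracy: pd.Series
    overall_accuracy: float
    classes: list[str] = field(default_factory=list)
    imputed_missing: int = 0


def subset_gem(gem: GEM, gene_set: Sequence[str]) -> tuple[GEM, list[str]]:
    """Row-subset the GEM to ``gene_set`` (in that order); absent genes
    are reported, zero overlap is an error.  Returns (subGEM, absent)."""
    present = [g for g in gene_set if g in gem.gene_ids]
    absent = [g for g in gene_set if g not in gem.gene_ids]
    if not present:
        raise ValueError("no gene of the requested set is present in the GEM")
    return gem.subset_genes(present), absent


def train_evaluate(
    subgem: GEM, annot: SampleAnnotation, cfg: ClassifierConfig | None = None
) -> ClassificationReport:
    """Train the MLP on a stratified split and report the held-out
    confusion matrix; deterministic for a fixed (seed, data)."""
    cfg = cfg or ClassifierConfig()
    annot.validate_against(subgem)
    samples = [s for s in annot.sample_ids if s in set(subgem.sample_ids)]
    y = annot.condition.loc[samples]
    class_counts = y.value_counts()
    if len(class_counts) < 2 or (class_counts < 5).any():
        raise ValueError("need >= 2 classes with >= 5 samples each")
    X = subgem.values.loc[:, samples].T.to_numpy(dtype=float)
    n_missing = int(np.isnan(X).sum())
    X = np.nan_to_num(X, nan=0.0)  # classifier-only zero imputation

    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y.to_numpy(),
        train_size=cfg.train_fraction,
        stratify=y.to_numpy(),
        random_state=cfg.seed,
    )
    classes = sorted(set(y))
    if set(y_tr) != set(classes):
        raise ValueError(
            "a class is absent from the train split; change seed or stratify"
        )
    clf = MLPClassifier(
        hidden_layer_sizes=cfg.hidden_sizes,
        activation=cfg.activation,
        learning_rate_init=cfg.learning_rate,
        max_iter=cfg.max_epochs,
        random_state=cfg.seed,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X_tr, y_tr)
    pred = clf.predict(X_te)
    cm = confusion_matrix(y_te, pred, labels=classes)
    cm_df = pd.DataFrame(cm, index=classes, columns=classes)
    row_sums = cm_df.sum(axis=1)
    per_class = pd.Series(np.diag(cm), index=classes) / row_sums.replace(0, 1)
    overall = float(np.trace(cm) / cm.sum())
    return ClassificationReport(
        confusion=cm_df,
        per_class_accuracy=per_class,
        overall_accuracy=overall,
        classes=classes,
        imputed_missing=n_missing,
    )
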