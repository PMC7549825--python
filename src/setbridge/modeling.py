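"""Cross-platform subtype classification on enrichment scores.

Multinomial logistic models (with a mild ridge penalty) are trained on one
platform's enrichment-score matrix with repeated random stratified train/test
splits; the resulting model ensemble can then predict another platform's
scores — optionally Procrustes-aligned first — and is evaluated through pooled
confusion tables and their trace/total accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .enrichment import EnrichmentMatrix

__all__ = [
    "ConfusionMatrix",
    "FittedModel",
    "train_repeated",
    "predict",
    "confusion",
    "accuracy",
]


@dataclass
class ConfusionMatrix:
    """Counts of (true class, predicted class) pairs; rows true, columns predicted."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the label axis")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("label axes differ")
        return ConfusionMatrix(list(self.labels), self.counts + other.counts)


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    labels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Tally a confusion matrix.

    The label axis defaults to the sorted classes seen in the true labels;
    predicted classes never seen as true labels are appended with a warning so
    that no prediction is silently discarded.
    """
    t = [str(x) for x in true_labels]
    p = [str(x) for x in predicted_labels]
    if len(t) != len(p):
        raise ValueError("true and predicted label lists differ in length")
    if labels is None:
        labels = sorted(set(t))
        unseen = sorted(set(p) - set(labels))
        if unseen:
            import warnings

            warnings.warn(f"predicted labels never observed as true classes: {unseen}")
            labels = labels + unseen
    labels = [str(x) for x in labels]
    idx = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for ti, pi in zip(t, p):
        counts[idx[ti], idx[pi]] += 1
    return ConfusionMatrix(labels, counts)


def accuracy(cm: ConfusionMatrix, digits: int | None = None) -> float:
    """Trace over grand total; optionally rounded for reporting."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = float(np.trace(cm.counts)) / cm.total
    return round(acc, digits) if digits is not None else acc


@dataclass
class FittedModel:
    """One trained multiclass linear model over named enrichment-score variables."""

    classes: list[str]
    coef: np.ndarray
    intercept: np.ndarray
    var_names: list[str]
    repeat: int = 0
    split_seed: int = 0

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef.T + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision(X)
        if len(self.classes) == 2 and self.coef.shape[0] == 1:
            return np.where(scores[:, 0] > 0, self.classes[1], self.classes[0])
        return np.asarray(self.classes, dtype=object)[np.argmax(scores, axis=1)]

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "var_names": self.var_names,
            "repeat": self.repeat,
            "split_seed": self.split_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            list(d["classes"]),
            np.array(d["coef"]),
            np.array(d["intercept"]),
            list(d["var_names"]),
            int(d.get("repeat", 0)),
            int(d.get("split_seed", 0)),
        )


def save_models(models: Sequence[FittedModel], path: str | Path) -> None:
    Path(path).write_text(json.dumps([m.to_dict() for m in models], indent=2) + "\n")


def load_models(path: str | Path) -> list[FittedModel]:
    return [FittedModel.from_dict(d) for d in json.loads(Path(path).read_text())]


def _as_sample_matrix(es: EnrichmentMatrix | pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Samples x variables array plus variable names, from either orientation."""
    if isinstance(es, EnrichmentMatrix):
        return es.scores.T.copy(), list(es.set_names)
    return es.to_numpy(float), es.columns.astype(str).tolist()


def train_repeated(
    es: EnrichmentMatrix | pd.DataFrame,
    labels: Sequence[str],
    n_repeats: int = 10,
    seed: int = 0,
    train_fraction: float = 0.5,
    C: float = 1.0,
    max_retries: int = 20,
) -> tuple[list[FittedModel], ConfusionMatrix]:
    """Repeatedly split, fit and score multinomial logistic models.

    For each repeat a random stratified split reserves ``train_fraction`` of
    samples for fitting (ridge-regularized maximum likelihood, inverse
    penalty ``C``); the held-out portion is predicted and its confusion counts
    pooled across repeats, so the pooled grand total is ``n_repeats`` times
    the per-repeat test size.  Reproducible given ``seed``.
    """
    X, var_names = _as_sample_matrix(es)
    y = np.asarray([str(l) for l in labels], dtype=object)
    if X.shape[0] != y.size:
        raise ValueError("labels length must match sample count")
    classes, class_counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if class_counts.min() < 2:
        small = classes[class_counts < 2].tolist()
        raise ValueError(f"each class needs >= 2 samples; too small: {small}")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    rng = np.random.default_rng(seed)
    label_axis = sorted(classes.tolist())
    models: list[FittedModel] = []
    pooled = ConfusionMatrix(label_axis, np.zeros((len(label_axis),) * 2, dtype=np.int64))
    for rep in range(n_repeats):
        for attempt in range(max_retries):
            split_seed = int(rng.integers(0, 2**31 - 1))
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, train_size=train_fraction, stratify=y, random_state=split_seed
            )
            if set(y_tr) == set(classes):
                break
        else:
            raise RuntimeError("could not draw a split containing every class in training")
        clf = LogisticRegression(C=C, max_iter=2000, random_state=0)
        clf.fit(X_tr, y_tr)
        model = FittedModel(
            classes=[str(c) for c in clf.classes_],
            coef=clf.coef_.copy(),
            intercept=clf.intercept_.copy(),
            var_names=var_names,
            repeat=rep,
            split_seed=split_seed,
        )
        models.append(model)
        pooled = pooled + confusion(y_te, model.predict(X_te), labels=label_axis)
    return models, pooled


def predict(
    models: Sequence[FittedModel],
    es: EnrichmentMatrix | pd.DataFrame,
) -> np.ndarray:
    """Pooled predictions: every model predicts every sample.

    The score variables must match the training variables by name and order;
    a mismatch raises an error naming the missing/extra sets.  Returns a flat
    array of ``n_models * n_samples`` labels (model-major), suitable for
    :func:`confusion` against the true labels tiled ``n_models`` times.
    """
    X, var_names = _as_sample_matrix(es)
    if not models:
        raise ValueError("no models given")
    trained = models[0].var_names
    if var_names != trained:
        missing = sorted(set(trained) - set(var_names))
        extra = sorted(set(var_names) - set(trained))
        raise ValueError(
            f"enrichment-score variables do not match training: missing {missing}, extra {extra}"
        )
    return np.concatenate([m.predict(X) for m in models])
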