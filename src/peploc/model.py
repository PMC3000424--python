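"""RBF-kernel SVM classification with nested 10-fold cross-validation.

The nested protocol: the dataset is split into ``n_outer`` folds; for each
outer fold, an inner ``n_inner``-fold grid search on the outer-training
part selects (C, gamma), the model is refit on the full outer-training
part, and the held-out fold is evaluated.  Feature scaling is always fitted
on training data only.

The quadratic-program solution is delegated to scikit-learn's libsvm
binding; this module owns vectorization of sparse feature maps, per-
dimension [0, 1] scaling, class ordering, seeding and serialization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from peploc.evaluation import (
    MetricsReport,
    aggregate_folds,
    confusion_counts,
    report_from_counts,
)
from peploc.features import FeatureVector
from peploc.sequence_io import PeptideRecord

logger = logging.getLogger(__name__)

ARCHIVE_FORMAT_VERSION = "peploc-model-1"


@dataclass(frozen=True)
class KernelParams:
    """RBF kernel hyperparameters: penalty C and kernel width gamma."""

    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be strictly positive")


def default_grid(
    log2_c: Sequence[int] = range(-5, 16, 2),
    log2_gamma: Sequence[int] = range(-15, 4, 2),
) -> list[KernelParams]:
    """Conventional log2 grid: C in 2^-5..2^15, gamma in 2^-15..2^3."""
    return [KernelParams(C=2.0 ** c, gamma=2.0 ** g)
            for c in log2_c for g in log2_gamma]


def small_grid() -> list[KernelParams]:
    """Coarse grid for quick runs and tests."""
    return default_grid(log2_c=(-1, 3, 7), log2_gamma=(-7, -3, 1))


@dataclass
class ClassProbabilities:
    """Probability per compartment code; sums to 1."""

    probs: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"probabilities sum to {total}, not 1")
        if any(p < -1e-12 or p > 1 + 1e-12 for p in self.probs.values()):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def argmax(self) -> str:
        return max(self.probs, key=self.probs.get)

    def as_vector(self, classes: Sequence[str]) -> list[float]:
        return [self.probs[c] for c in classes]


@dataclass
class TrainedModel:
    """A fitted per-feature classifier with its preprocessing state."""

    spec_name: str
    params: KernelParams
    classes: tuple[str, ...]
    vectorizer: DictVectorizer
    scaler: MinMaxScaler
    svc: SVC
    format_version: str = ARCHIVE_FORMAT_VERSION


def _as_dicts(vectors: Sequence[FeatureVector | dict]) -> list[dict]:
    return [v.values if isinstance(v, FeatureVector) else dict(v) for v in vectors]


def _spec_name(vectors: Sequence[FeatureVector | dict]) -> str:
    for v in vectors:
        if isinstance(v, FeatureVector):
            return v.spec.name
    return "raw"


def train_svm(
    vectors: Sequence[FeatureVector | dict],
    labels: Sequence[str],
    params: KernelParams,
    seed: int = 0,
) -> TrainedModel:
    """Fit scaler + one-vs-one RBF SVM with probability estimates.

    The vectorizer's vocabulary and the per-dimension [0, 1] scaler are
    fitted on the given (training) data only.
    """
    if len(vectors) != len(labels):
        raise ValueError("vectors and labels must have equal length")
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    specs = {v.spec.name for v in vectors if isinstance(v, FeatureVector)}
    if len(specs) > 1:
        raise ValueError(f"vectors mix feature specs: {sorted(specs)}")

    vectorizer = DictVectorizer(sparse=False, sort=True)
    X = vectorizer.fit_transform(_as_dicts(vectors))
    scaler = MinMaxScaler()
    X = scaler.fit_transform(X)

    svc = SVC(
        kernel="rbf",
        C=params.C,
        gamma=params.gamma,
        probability=True,
        random_state=seed,
        decision_function_shape="ovo",
    )
    svc.fit(X, list(labels))
    return TrainedModel(
        spec_name=_spec_name(vectors),
        params=params,
        classes=classes,
        vectorizer=vectorizer,
        scaler=scaler,
        svc=svc,
    )


def _transform(model: TrainedModel, vectors: Sequence[FeatureVector | dict]) -> np.ndarray:
    X = model.vectorizer.transform(_as_dicts(vectors))
    return model.scaler.transform(X)


def predict_proba(model: TrainedModel, vector: FeatureVector | dict) -> ClassProbabilities:
    """Class probabilities for one feature vector."""
    if isinstance(vector, FeatureVector) and model.spec_name != "raw":
        if vector.spec.name != model.spec_name:
            raise ValueError(
                f"feature mismatch: model was trained on {model.spec_name!r}, "
                f"got {vector.spec.name!r}"
            )
    X = _transform(model, [vector])
    raw = model.svc.predict_proba(X)[0]
    probs = {c: float(p) for c, p in zip(model.svc.classes_, raw)}
    total = sum(probs.values())
    return ClassProbabilities({c: p / total for c, p in probs.items()})


def predict_proba_many(
    model: TrainedModel, vectors: Sequence[FeatureVector | dict]
) -> list[ClassProbabilities]:
    """Vectorized :func:`predict_proba`."""
    X = _transform(model, vectors)
    raw = model.svc.predict_proba(X)
    out = []
    for row in raw:
        probs = {c: float(p) for c, p in zip(model.svc.classes_, row)}
        total = sum(probs.values())
        out.append(ClassProbabilities({c: p / total for c, p in probs.items()}))
    return out


def predict_labels(model: TrainedModel, vectors: Sequence[FeatureVector | dict]) -> list[str]:
    """Argmax-of-probability labels (consistent with predict_proba)."""
    return [p.argmax for p in predict_proba_many(model, vectors)]


def make_folds(
    records: Sequence,
    n: int,
    seed: int = 0,
    stratified: bool = True,
) -> np.ndarray:
    """Deterministic fold assignment; fold sizes differ by at most one.

    In stratified mode members of each class are dealt round-robin into the
    folds (with a running offset, so overall sizes stay balanced even for
    tiny classes).  Plain mode shuffles all records and deals them out.
    """
    size = len(records)
    if n < 2:
        raise ValueError("need at least 2 folds")
    if n > size:
        raise ValueError(f"cannot make {n} folds from {size} records")
    rng = np.random.default_rng(seed)
    folds = np.empty(size, dtype=int)
    if not stratified:
        order = rng.permutation(size)
        for pos, idx in enumerate(order):
            folds[idx] = pos % n
        return folds

    labels = [getattr(r, "label", None) for r in records]
    if any(lab is None for lab in labels):
        raise ValueError("stratified folding requires labeled records")
    counter = 0
    for lab in sorted(set(labels)):
        members = [i for i, l in enumerate(labels) if l == lab]
        rng.shuffle(members)
        for idx in members:
            folds[idx] = counter % n
            counter += 1
    return folds


def grid_search(
    vectors: Sequence[FeatureVector | dict],
    labels: Sequence[str],
    inner_folds: np.ndarray,
    grid: Sequence[KernelParams],
    seed: int = 0,
) -> tuple[KernelParams, dict[KernelParams, float]]:
    """Mean inner-fold validation accuracy per grid point; return the maximizer.

    Ties are broken by smaller C, then smaller gamma.  Inner folds whose
    training part contains a single class are skipped with a warning.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    labels = list(labels)
    classes = sorted(set(labels))
    table: dict[KernelParams, float] = {}
    fold_ids = sorted(set(int(f) for f in inner_folds))
    for params in grid:
        accs = []
        for f in fold_ids:
            train_idx = [i for i in range(len(labels)) if inner_folds[i] != f]
            val_idx = [i for i in range(len(labels)) if inner_folds[i] == f]
            if not val_idx:
                continue
            train_labels = [labels[i] for i in train_idx]
            if len(set(train_labels)) < 2:
                logger.warning("inner fold %d skipped: single-class training part", f)
                continue
            model = train_svm([vectors[i] for i in train_idx], train_labels,
                              params, seed=seed)
            predicted = predict_labels(model, [vectors[i] for i in val_idx])
            correct = sum(p == labels[i] for p, i in zip(predicted, val_idx))
            accs.append(correct / len(val_idx) * 100.0)
        table[params] = float(np.mean(accs)) if accs else 0.0
    best = max(table, key=lambda p: (table[p], -p.C, -p.gamma))
    return best, table


def nested_evaluate(
    records: Sequence[PeptideRecord],
    extract_fn: Callable[[PeptideRecord], FeatureVector | dict],
    grid: Sequence[KernelParams],
    seed: int = 0,
    n_outer: int = 10,
    n_inner: int = 10,
    stratified: bool = True,
) -> MetricsReport:
    """Nested cross-validated evaluation of one feature representation.

    For each outer fold: grid-search (C, gamma) by inner cross-validation on
    the outer-training part, refit on the full outer-training part, evaluate
    on the held-out fold.  Returns per-class metrics aggregated over outer
    folds as mean(SD).
    """
    records = list(records)
    labels = [r.label for r in records]
    if any(lab is None for lab in labels):
        raise ValueError("nested evaluation requires labeled records")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")

    vectors = [extract_fn(r) for r in records]
    outer_folds = make_folds(records, n_outer, seed=seed, stratified=stratified)

    fold_reports: list[MetricsReport] = []
    chosen: list[KernelParams] = []
    for f in range(n_outer):
        train_idx = [i for i in range(len(records)) if outer_folds[i] != f]
        test_idx = [i for i in range(len(records)) if outer_folds[i] == f]
        train_records = [records[i] for i in train_idx]
        train_vectors = [vectors[i] for i in train_idx]
        train_labels = [labels[i] for i in train_idx]
        if len(set(train_labels)) < len(classes):
            logger.warning("outer fold %d: some class absent from training part", f)

        inner = make_folds(train_records, n_inner, seed=seed + 1 + f,
                           stratified=stratified)
        best, _ = grid_search(train_vectors, train_labels, inner, grid, seed=seed)
        chosen.append(best)
        model = train_svm(train_vectors, train_labels, best, seed=seed)
        predicted = predict_labels(model, [vectors[i] for i in test_idx])
        counts = confusion_counts([labels[i] for i in test_idx], predicted, classes)
        fold_reports.append(report_from_counts(counts))
        logger.info("outer fold %d: C=%g gamma=%g accuracy=%.1f",
                    f, best.C, best.gamma, fold_reports[-1].accuracy)
    return aggregate_folds(fold_reports)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model bundle to a single file."""
    joblib.dump(
        {
            "format_version": ARCHIVE_FORMAT_VERSION,
            "spec_name": model.spec_name,
            "params": model.params,
            "classes": model.classes,
            "vectorizer": model.vectorizer,
            "scaler": model.scaler,
            "svc": model.svc,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    """Load a model bundle written by :func:`save_model`."""
    blob = joblib.load(path)
    if blob.get("format_version") != ARCHIVE_FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version {blob.get('format_version')!r}")
    return TrainedModel(
        spec_name=blob["spec_name"],
        params=blob["params"],
        classes=tuple(blob["classes"]),
        vectorizer=blob["vectorizer"],
        scaler=blob["scaler"],
        svc=blob["svc"],
    )
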