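"""Feature integration: single-feature models, attribute concatenation, and
two-layer probability stacking.

Stacking trains one first-layer classifier per member feature; their class
probabilities are concatenated (member order x class order) into a meta
vector — size ``|members| x n_classes``, i.e. 369 for all 41 features and 9
classes — which feeds the second-layer classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from peploc.features import AAIndexTable, FeatureSpec, FeatureVector, extract
from peploc.model import (
    KernelParams,
    TrainedModel,
    ClassProbabilities,
    grid_search,
    make_folds,
    predict_proba_many,
    train_svm,
)
from peploc.sequence_io import PeptideRecord

logger = logging.getLogger(__name__)

SCHEME_KINDS = ("single_feature", "concat_attributes", "stacked_predictions")

#: Registry names of the three best-performing member features.
TOP3_MEMBERS = ("ungrouped_k4", "groupC_k6", "groupD_k7")


@dataclass
class SchemeSpec:
    """How to combine member features into one predictor."""

    kind: str
    members: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        if self.kind not in SCHEME_KINDS:
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if not self.members:
            raise ValueError("scheme needs at least one member feature")
        if self.kind == "single_feature" and len(self.members) != 1:
            raise ValueError("single_feature scheme must have exactly one member")
        names = [m.name for m in self.members]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate member feature(s): {names}")


def concat_attributes(
    seq: str,
    members: Sequence[FeatureSpec],
    table: Optional[AAIndexTable] = None,
) -> FeatureVector:
    """Concatenate member feature vectors (keys prefixed by member name).

    Dimension is the sum of member dimensions; the result stays sparse.
    """
    names = [m.name for m in members]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate member feature(s): {names}")
    if len(members) == 1:
        # single member: identical to that member's vector (un-prefixed keys)
        return extract(seq, members[0], table)
    values: dict[str, float] = {}
    total_dim = 0
    for member in members:
        vec = extract(seq, member, table)
        total_dim += member.dimension
        for key, val in vec.values.items():
            values[f"{member.name}:{key}"] = val
    combined_spec = FeatureSpec("concat", dimension=total_dim)
    return FeatureVector(combined_spec, values)


@dataclass
class CompositeModel:
    """A trained integration scheme."""

    scheme: SchemeSpec
    classes: tuple[str, ...]
    first_layer: dict[str, TrainedModel] = field(default_factory=dict)
    second_layer: Optional[TrainedModel] = None
    attribute_model: Optional[TrainedModel] = None


def stack_first_layer(
    seq: str,
    first_layer_models: dict[str, TrainedModel],
    members: Sequence[FeatureSpec],
    table: Optional[AAIndexTable] = None,
) -> dict[str, float]:
    """Meta feature map: member-order-major concatenated class probabilities."""
    class_orders = {tuple(m.classes) for m in first_layer_models.values()}
    if len(class_orders) != 1:
        raise ValueError("inconsistent class orders across first-layer models")
    values: dict[str, float] = {}
    for member in members:
        model = first_layer_models[member.name]
        vec = extract(seq, member, table)
        probs = predict_proba_many(model, [vec])[0]
        for cls in model.classes:
            values[f"{member.name}|{cls}"] = probs.probs[cls]
    return values


def _stack_meta_vectors(
    records: Sequence[PeptideRecord],
    first_layer_models: dict[str, TrainedModel],
    members: Sequence[FeatureSpec],
    table: Optional[AAIndexTable],
) -> list[dict[str, float]]:
    metas: list[dict[str, float]] = [dict() for _ in records]
    for member in members:
        model = first_layer_models[member.name]
        vecs = [extract(r.sequence, member, table) for r in records]
        probs = predict_proba_many(model, vecs)
        for meta, p in zip(metas, probs):
            for cls in model.classes:
                meta[f"{member.name}|{cls}"] = p.probs[cls]
    return metas


def _select_params(
    vectors: Sequence[FeatureVector | dict],
    labels: Sequence[str],
    grid: Sequence[KernelParams],
    seed: int,
    n_inner: int,
) -> KernelParams:
    if len(grid) == 1:
        return grid[0]
    class _Rec:
        def __init__(self, label):
            self.label = label
    inner = make_folds([_Rec(l) for l in labels], min(n_inner, len(labels)),
                       seed=seed, stratified=True)
    best, _ = grid_search(vectors, labels, inner, grid, seed=seed)
    return best


def train_scheme(
    records: Sequence[PeptideRecord],
    scheme: SchemeSpec,
    grid: Sequence[KernelParams],
    table: Optional[AAIndexTable] = None,
    seed: int = 0,
    n_inner: int = 10,
) -> CompositeModel:
    """Train a composite predictor on labeled records.

    Single-feature and concatenation schemes train one classifier on the
    (concatenated) attributes.  Stacking trains a first-layer model per
    member, then the second-layer classifier on the first layer's
    probabilities for the same training records (in-sample stacking).
    Hyperparameters are grid-searched by inner cross-validation.
    """
    records = list(records)
    labels = [r.label for r in records]
    if any(lab is None for lab in labels):
        raise ValueError("training a scheme requires labeled records")
    classes = tuple(sorted(set(labels)))

    if scheme.kind in ("single_feature", "concat_attributes"):
        vectors = [concat_attributes(r.sequence, scheme.members, table) for r in records]
        params = _select_params(vectors, labels, grid, seed, n_inner)
        attribute_model = train_svm(vectors, labels, params, seed=seed)
        return CompositeModel(scheme=scheme, classes=classes,
                              attribute_model=attribute_model)

    # stacked_predictions
    first_layer: dict[str, TrainedModel] = {}
    for member in scheme.members:
        vecs = [extract(r.sequence, member, table) for r in records]
        params = _select_params(vecs, labels, grid, seed, n_inner)
        first_layer[member.name] = train_svm(vecs, labels, params, seed=seed)
        logger.info("first-layer model for %s: C=%g gamma=%g",
                    member.name, params.C, params.gamma)
    metas = _stack_meta_vectors(records, first_layer, scheme.members, table)
    meta_params = _select_params(metas, labels, grid, seed, n_inner)
    second = train_svm(metas, labels, meta_params, seed=seed)
    return CompositeModel(scheme=scheme, classes=classes,
                          first_layer=first_layer, second_layer=second)


def predict_scheme(
    composite: CompositeModel,
    seq: str,
    table: Optional[AAIndexTable] = None,
) -> ClassProbabilities:
    """Scheme-appropriate forward pass for one cleaned sequence."""
    scheme = composite.scheme
    if scheme.kind in ("single_feature", "concat_attributes"):
        if composite.attribute_model is None:
            raise ValueError("composite model is not trained")
        vec = concat_attributes(seq, scheme.members, table)
        return predict_proba_many(composite.attribute_model, [vec])[0]
    if composite.second_layer is None or not composite.first_layer:
        raise ValueError("composite model is not trained")
    meta = stack_first_layer(seq, composite.first_layer, scheme.members, table)
    return predict_proba_many(composite.second_layer, [meta])[0]


def predict_scheme_many(
    composite: CompositeModel,
    records: Sequence[PeptideRecord],
    table: Optional[AAIndexTable] = None,
) -> list[ClassProbabilities]:
    """Batch forward pass."""
    scheme = composite.scheme
    if scheme.kind in ("single_feature", "concat_attributes"):
        if composite.attribute_model is None:
            raise ValueError("composite model is not trained")
        vecs = [concat_attributes(r.sequence, scheme.members, table) for r in records]
        return predict_proba_many(composite.attribute_model, vecs)
    if composite.second_layer is None or not composite.first_layer:
        raise ValueError("composite model is not trained")
    metas = _stack_meta_vectors(records, composite.first_layer, scheme.members, table)
    return predict_proba_many(composite.second_layer, metas)
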