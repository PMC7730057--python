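"""End-to-end experiment orchestration.

A feature *recipe* names the families entering the classifier, joined
with ``+`` and concatenated in the fixed order deep, texture,
morphology.  Deep tokens name one of the six extraction levels:

    deep:CF1:<layer>   one conv layer's max/avg summary
    deep:CF2:<block>   one conv block
    deep:CF3           all conv blocks (the CONV set)
    deep:FCF1:<fc>     one fc layer
    deep:FCF2          both fc layers
    deep:CF_FCF        everything combined

``texture`` and ``morphology`` add the 800 GLCM features and the 18
contour features.  Every family vector is l2-normalized, and the
concatenated per-sample vector is l2-normalized again before
classification, so no family dominates through raw scale.

Two protocols are provided: stratified 10-fold cross-validation on one
dataset (optionally with mRMR + backward-elimination feature selection
before the SVM grid search) and a train-on-A/test-on-B generalization
run where selection and tuning see the training set only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import backbone as bb
from .classify_eval import (
    METRIC_NAMES,
    ConfusionCounts,
    CvReport,
    SvmConfig,
    build_folds,
    grid_search_cv,
    make_mcc_evaluator,
    metrics as compute_metrics,
    predict,
    roc_auc,
    train_final,
    _as_binary,
    _counts_from_predictions,
)
from .deep_features import build_level, l2_normalize
from .io_roi import AnnotatedImage, compute_roi, load_dataset
from .morphology import morphology_feature_set
from .selection import SelectionResult, select_features, selection_provenance
from .texture import GlcmParams, texture_feature_set

__all__ = ["ExperimentConfig", "extract_features", "run_cv_experiment", "run_generalization"]

_DEEP_LEVELS = ("CF1", "CF2", "CF3", "FCF1", "FCF2", "CF_FCF")


@dataclass(frozen=True)
class ExperimentConfig:
    recipe: str = "deep:CF3+morphology"
    backbone: str = "fixture"
    weights_path: str | None = None
    roi_pad: int = 30
    glcm: GlcmParams = field(default_factory=GlcmParams)
    selection: bool = True
    selection_mode: str = "fast"  # 'fast' | 'full' evaluator during selection
    selection_scope: str = "global"  # 'global' | 'nested'
    svm: SvmConfig = field(default_factory=SvmConfig)
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for token in self.recipe.split("+"):
            parts = token.split(":")
            if parts[0] == "deep":
                if len(parts) < 2 or parts[1] not in _DEEP_LEVELS:
                    raise ValueError(f"bad deep token {token!r}")
            elif token not in ("texture", "morphology"):
                raise ValueError(f"unknown recipe token {token!r}")
        if self.selection_scope not in ("global", "nested"):
            raise ValueError("selection_scope must be 'global' or 'nested'")


def _deep_layer_names(spec: bb.BackboneSpec, level: str, member: str | None) -> list[str]:
    if level in ("CF2",) and member:
        return [n for n, _ in spec.block_layers(member)]
    if level == "CF1":
        return [member]
    if level == "FCF1":
        return [member]
    if level == "CF3":
        return spec.conv_layer_names
    if level == "FCF2":
        return spec.fc_layer_names
    return spec.conv_layer_names + spec.fc_layer_names  # CF_FCF


def _deep_vector(roi, spec: bb.BackboneSpec, level: str, member: str | None, weights):
    tensor = bb.preprocess_roi(roi, spec)
    layers = _deep_layer_names(spec, level, member)
    bundle = bb.forward_activations(tensor, spec, layers, weights)
    built = build_level(bundle, spec, level)
    if isinstance(built, list):
        tag = f"{level}:{member}"
        for fs in built:
            if fs.level_tag == tag:
                return fs
        raise KeyError(f"level member {member!r} not produced at {level}")
    return built


def extract_features(
    images: list[AnnotatedImage], config: ExperimentConfig
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample feature matrix (rows = samples, named columns) and labels."""
    spec = bb.get_spec(config.backbone)
    weights = None
    if config.weights_path:
        weights = bb.load_weights_npz(config.weights_path)
    elif config.backbone == "fixture":
        weights = bb.fixture_weights(spec)
    tokens = config.recipe.split("+")
    rows, names_ref = [], None
    labels = []
    for img in images:
        roi = compute_roi(img, pad=config.roi_pad)
        parts_values, parts_names = [], []
        for token in tokens:
            parts = token.split(":")
            if parts[0] == "deep":
                level = parts[1]
                member = ":".join(parts[2:]) if len(parts) > 2 else None
                fs = _deep_vector(roi, spec, level, member, weights)
            elif token == "texture":
                fs = texture_feature_set(roi.pixels, config.glcm, normalize=True)
            else:  # morphology
                fs = morphology_feature_set(img.mask, normalize=True)
            parts_values.append(fs.values)
            parts_names.extend(fs.names)
        combined = np.concatenate(parts_values)
        if len(tokens) > 1:
            combined, _ = l2_normalize(combined)
        if names_ref is None:
            names_ref = parts_names
        elif parts_names != names_ref:
            raise ValueError(f"inconsistent feature names for sample {img.id}")
        rows.append(combined)
        labels.append(img.label)
    features = pd.DataFrame(np.vstack(rows), columns=names_ref, index=[i.id for i in images])
    return features, np.asarray(labels)


@dataclass
class ExperimentResult:
    report: CvReport
    selection: SelectionResult | None
    features: pd.DataFrame
    labels: np.ndarray
    provenance: dict[str, int] | None = None


def _select(features: pd.DataFrame, labels, config: ExperimentConfig, seed: int) -> SelectionResult:
    evaluator = make_mcc_evaluator(
        features, labels, folds=config.folds, seed=seed, mode=config.selection_mode,
        config=config.svm,
    )
    return select_features(features, labels, evaluator)


def run_cv_experiment(
    source: list[AnnotatedImage] | str, config: ExperimentConfig
) -> ExperimentResult:
    """Feature extraction, optional selection, and grid-search CV.

    ``source`` is a list of annotated images or a manifest CSV path.
    With ``selection_scope='global'`` the selection is performed once on
    the full dataset (the protocol matched by the reference results);
    ``'nested'`` repeats selection and tuning inside each training fold,
    the leakage-free variant, at extra cost.
    """
    images = load_dataset(source) if isinstance(source, str) else source
    features, labels = extract_features(images, config)
    if not config.selection:
        report = grid_search_cv(features, labels, config.svm, config.folds, config.seed)
        return ExperimentResult(report, None, features, labels)
    if config.selection_scope == "nested":
        return _run_nested_cv(features, labels, config)
    sel = _select(features, labels, config, config.seed)
    report = grid_search_cv(
        features[sel.final_names], labels, config.svm, config.folds, config.seed
    )
    return ExperimentResult(
        report, sel, features, labels, provenance=selection_provenance(sel.final_names)
    )


def _run_nested_cv(features: pd.DataFrame, labels, config: ExperimentConfig) -> ExperimentResult:
    """Per-fold selection + tuning; outer folds scored on untouched test sets."""
    y = _as_binary(labels)
    folds = build_folds(y, config.folds, config.seed)
    inner_folds = min(5, config.folds)
    pred = np.empty(len(y), dtype=int)
    score = np.empty(len(y), dtype=float)
    fold_counts, fold_metrics = [], []
    last_sel = None
    for k, (tr, te) in enumerate(folds):
        f_tr = features.iloc[tr]
        l_tr = labels[tr]
        sel = _select(f_tr, l_tr, replace(config, folds=inner_folds), config.seed + k)
        last_sel = sel
        inner = grid_search_cv(
            f_tr[sel.final_names], l_tr, config.svm, inner_folds, config.seed + k
        )
        model = train_final(f_tr[sel.final_names], l_tr, inner.best_c, inner.best_sigma)
        p, s = predict(model, features.iloc[te][sel.final_names])
        pred[te], score[te] = p, s
    for tr, te in folds:
        cc = _counts_from_predictions(y[te], pred[te])
        fold_counts.append(cc)
        fold_metrics.append(compute_metrics(cc))
    mean_m = {k: float(np.mean([m[k] for m in fold_metrics])) for k in METRIC_NAMES}
    std_m = {k: float(np.std([m[k] for m in fold_metrics])) for k in METRIC_NAMES}
    points, auc = roc_auc(score, y)
    pooled = compute_metrics(_counts_from_predictions(y, pred))["mcc"]
    report = CvReport(
        fold_counts=fold_counts,
        fold_metrics=fold_metrics,
        mean_metrics=mean_m,
        std_metrics=std_m,
        best_c=float("nan"),
        best_sigma=float("nan"),
        pooled_mcc=pooled,
        roc_points=points,
        auc=auc,
        fold_assignment=[te.tolist() for _tr, te in folds],
        seed=config.seed,
        n_pairs_evaluated=config.svm.n_pairs,
    )
    return ExperimentResult(report, last_sel, features, labels)


@dataclass
class GeneralizationResult:
    metrics: dict[str, float]
    counts: ConfusionCounts
    selection: SelectionResult | None
    best_c: float
    best_sigma: float


def run_generalization(
    train_source: list[AnnotatedImage] | str,
    test_source: list[AnnotatedImage] | str,
    config: ExperimentConfig,
) -> GeneralizationResult:
    """Train (selection + tuning) on one dataset, evaluate once on another.

    The two datasets must have disjoint sample ids.
    """
    train = load_dataset(train_source) if isinstance(train_source, str) else train_source
    test = load_dataset(test_source) if isinstance(test_source, str) else test_source
    train_ids = {i.id for i in train}
    overlap = train_ids & {i.id for i in test}
    if overlap:
        raise ValueError(f"train/test manifests share ids: {sorted(overlap)[:5]}")
    f_train, l_train = extract_features(train, config)
    f_test, l_test = extract_features(test, config)
    sel = None
    if config.selection:
        sel = _select(f_train, l_train, config, config.seed)
        f_train = f_train[sel.final_names]
        f_test = f_test[sel.final_names]
    tuned = grid_search_cv(f_train, l_train, config.svm, config.folds, config.seed)
    model = train_final(f_train, l_train, tuned.best_c, tuned.best_sigma)
    pred, _score = predict(model, f_test)
    counts = _counts_from_predictions(_as_binary(l_test), pred)
    return GeneralizationResult(
        metrics=compute_metrics(counts),
        counts=counts,
        selection=sel,
        best_c=tuned.best_c,
        best_sigma=tuned.best_sigma,
    )
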