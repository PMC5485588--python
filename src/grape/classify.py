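"""Nearest-template tissue classification and cross-validation protocols.

Three template methods share one protocol: per class, a template is built
from the training samples; a test sample is assigned to the class whose
template it is closest to.

* ``grape``  -- rank-pair template, weighted reversal distance;
* ``dirac``  -- rank-pair template, uniform-weight reversal distance;
* ``centroid`` -- per-gene mean vector, Euclidean distance (an
  absolute-expression baseline; unlike the rank methods it is *not*
  invariant to per-sample monotone transforms).

Distance ties are broken towards the lexicographically first class label
and flagged.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from ._utils import as_label_series, as_rng, as_sample_frame
from .rank import (
    CONSTANT,
    PairIndex,
    PathwayTemplate,
    binarize_matrix,
    build_template,
    dirac_distance,
    grape_distance,
    resolve_weight,
)

__all__ = [
    "ClassTemplateSet",
    "fit_class_templates",
    "predict_labels",
    "NearestTemplateClassifier",
    "CVResult",
    "cross_validate",
    "enumerate_dataset_splits",
    "balance_classes",
]

METHODS = ("grape", "dirac", "centroid")


@dataclass
class ClassTemplateSet:
    """Per-class templates for one pathway.

    For rank methods ``templates`` maps label -> :class:`PathwayTemplate`;
    for the centroid method it maps label -> per-gene mean vector.
    """

    method: str
    genes: tuple[str, ...]
    templates: dict
    weight: object = None
    pair_index: PairIndex | None = None


def fit_class_templates(train: pd.DataFrame, labels, pathway: Sequence[str],
                        method: str = "grape", weight="quadratic",
                        rng=None, classes=None) -> ClassTemplateSet:
    """Build one template per class from training data.

    ``train`` is genes x samples; ``labels`` maps each training sample to
    its class.  ``classes`` may fix the expected label set; a requested
    class with no training samples is an error.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    rng = as_rng(rng)
    labels = as_label_series(labels, train.columns)
    genes = [str(g) for g in pathway]
    missing = [g for g in genes if g not in train.index]
    if missing:
        raise ValueError(f"training matrix is missing pathway genes: {missing[:5]}")
    if classes is None:
        classes = sorted(labels.unique())
    else:
        classes = sorted(str(c) for c in classes)
    templates: dict = {}
    pi = PairIndex(genes) if method in ("grape", "dirac") else None
    sub = train.loc[genes]
    for c in classes:
        cols = labels.index[labels == c]
        if len(cols) == 0:
            raise ValueError(f"class {c!r} has no training samples")
        values = sub[cols].to_numpy(dtype=float)
        if method == "centroid":
            templates[c] = values.mean(axis=1)
        else:
            bits = binarize_matrix(values, pi, rng)
            templates[c] = build_template(bits, pi, rng)
    w = None
    if method == "grape":
        w = resolve_weight(weight)
    elif method == "dirac":
        w = CONSTANT
    return ClassTemplateSet(method, tuple(genes), templates, w, pi)


def predict_labels(samples: pd.DataFrame, template_set: ClassTemplateSet,
                   rng=None):
    """Assign each sample (column) to its nearest class template.

    Returns ``(labels, ties)``: predicted labels and a boolean flag per
    sample marking exact distance ties (resolved lexicographically).
    """
    rng = as_rng(rng)
    genes = list(template_set.genes)
    missing = [g for g in genes if g not in samples.index]
    if missing:
        raise ValueError(f"samples are missing pathway genes: {missing[:5]}")
    values = samples.loc[genes].to_numpy(dtype=float)
    classes = sorted(template_set.templates)
    n = values.shape[1]
    D = np.empty((n, len(classes)))
    if template_set.method == "centroid":
        for k, c in enumerate(classes):
            D[:, k] = np.linalg.norm(values.T - template_set.templates[c], axis=1)
    else:
        bits = binarize_matrix(values, template_set.pair_index, rng)
        for k, c in enumerate(classes):
            tpl = template_set.templates[c]
            if template_set.method == "grape":
                d = grape_distance(bits, tpl, template_set.weight)
            else:
                d = dirac_distance(bits, tpl)
            D[:, k] = np.atleast_1d(d)
    best = D.argmin(axis=1)  # first minimum = lexicographically first class
    ties = (D == D[np.arange(n), best][:, None]).sum(axis=1) > 1
    labels = np.asarray([classes[k] for k in best], dtype=object)
    return labels, ties


class NearestTemplateClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style nearest-template classifier for one pathway.

    ``X`` is samples x genes (DataFrame with gene-id columns, or array);
    ``genes`` restricts to a pathway's genes (default: all columns).

    Parameters
    ----------
    genes : pathway gene list, or None for all features.
    method : "grape", "dirac" or "centroid".
    weight : weight function for the grape method.
    random_state : seed for tie coin flips; ``None`` = deterministic mode.

    Attributes
    ----------
    classes_ : sorted class labels.
    template_set_ : fitted :class:`ClassTemplateSet`.
    tie_flags_ : per-sample tie flags from the most recent ``predict``.
    """

    def __init__(self, genes=None, method="grape", weight="quadratic",
                 random_state=None):
        self.genes = genes
        self.method = method
        self.weight = weight
        self.random_state = random_state

    def _rng(self):
        return None if self.random_state is None else np.random.default_rng(self.random_state)

    def fit(self, X, y):
        df = as_sample_frame(X)
        y = np.asarray([str(v) for v in np.asarray(y).ravel()], dtype=object)
        if y.shape[0] != df.shape[0]:
            raise ValueError("X and y have inconsistent numbers of samples")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        genes = [str(g) for g in self.genes] if self.genes is not None else list(df.columns)
        labels = pd.Series(y, index=df.index)
        self.template_set_ = fit_class_templates(
            df.T, labels, genes, self.method, self.weight, self._rng()
        )
        self.genes_ = genes
        self.n_features_in_ = df.shape[1]
        self.feature_names_in_ = np.asarray(df.columns)
        return self

    def predict(self, X):
        if not hasattr(self, "template_set_"):
            raise ValueError("NearestTemplateClassifier is not fitted")
        df = as_sample_frame(X)
        labels, ties = predict_labels(df.T, self.template_set_, self._rng())
        self.tie_flags_ = ties
        return labels


@dataclass
class CVResult:
    """Repeated stratified cross-validation outcome.

    ``accuracy`` is the per-pathway mean over all repeats x folds;
    ``fold_accuracy`` keeps the individual fold values and ``assignments``
    the per-sample predictions (with tie flags).
    """

    accuracy: pd.Series
    fold_accuracy: pd.DataFrame
    assignments: pd.DataFrame = field(repr=False)
    seed: int | None = None


def cross_validate(data: pd.DataFrame, labels, gene_sets: Mapping[str, Sequence[str]],
                   method: str = "grape", weight="quadratic",
                   repeats: int = 10, folds: int = 5, seed: int = 0,
                   deterministic_ties: bool = False) -> CVResult:
    """Per-pathway accuracy under repeated stratified k-fold CV.

    Templates are rebuilt from each training fold; tie bits and
    0.5-roundings come from a fold-specific child seed, so repeats are
    independent but the whole protocol is reproducible from ``seed``.
    Defaults: 10 repeats of 5-fold CV.
    """
    labels = as_label_series(labels, data.columns)
    counts = labels.value_counts()
    if (counts < folds).any():
        small = counts[counts < folds].index.tolist()
        raise ValueError(f"class(es) smaller than fold count {folds}: {small}")
    pathways: dict[str, list[str]] = {}
    for name in gene_sets:
        covered = [g for g in gene_sets[name] if g in data.index]
        if len(covered) < 2:
            warnings.warn(f"pathway {name!r} covers <2 genes; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        pathways[name] = covered
    if not pathways:
        raise ValueError("no pathway with >=2 covered genes")
    y = labels.to_numpy()
    n = data.shape[1]
    root = np.random.SeedSequence(seed)
    repeat_seeds = root.spawn(repeats)
    fold_acc: dict[str, list[float]] = {p: [] for p in pathways}
    fold_cols: list[tuple[int, int]] = []
    records: list[dict] = []
    for r, rseed in enumerate(repeat_seeds):
        kf_state = int(rseed.generate_state(1)[0] % (2**31))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=kf_state)
        fold_seeds = rseed.spawn(folds)
        for f, (tr, te) in enumerate(skf.split(np.zeros(n), y)):
            fold_cols.append((r, f))
            rng = None if deterministic_ties else np.random.default_rng(fold_seeds[f])
            train = data.iloc[:, tr]
            test = data.iloc[:, te]
            y_tr = labels.iloc[tr]
            y_te = labels.iloc[te].to_numpy()
            for name, genes in pathways.items():
                cts = fit_class_templates(train, y_tr, genes, method, weight, rng)
                pred, ties = predict_labels(test, cts, rng)
                fold_acc[name].append(float(np.mean(pred == y_te)))
                for s, p_lab, t_lab, tie in zip(test.columns, pred, y_te, ties):
                    records.append({
                        "repeat": r, "fold": f, "pathway": name,
                        "sample": s, "true": t_lab, "pred": p_lab,
                        "tie": bool(tie),
                    })
    fold_df = pd.DataFrame(
        fold_acc, index=pd.MultiIndex.from_tuples(fold_cols, names=["repeat", "fold"])
    ).T
    accuracy = fold_df.mean(axis=1)
    accuracy.name = "accuracy"
    return CVResult(accuracy, fold_df, pd.DataFrame.from_records(records), seed)


def enumerate_dataset_splits(tissue_of: Mapping[str, str]):
    """All train/test splits placing one dataset per tissue on each side.

    ``tissue_of`` maps dataset name -> tissue label; every tissue must
    have exactly two datasets.  With t tissues there are 2**t splits,
    returned as ``(train_datasets, test_datasets)`` tuples.
    """
    groups: dict[str, list[str]] = {}
    for ds in sorted(tissue_of):
        groups.setdefault(str(tissue_of[ds]), []).append(str(ds))
    for tissue, members in groups.items():
        if len(members) != 2:
            raise ValueError(
                f"tissue {tissue!r} has {len(members)} dataset(s); exactly 2 required"
            )
    tissues = sorted(groups)
    splits = []
    for choice in product((0, 1), repeat=len(tissues)):
        train = tuple(groups[t][c] for t, c in zip(tissues, choice))
        test = tuple(groups[t][1 - c] for t, c in zip(tissues, choice))
        splits.append((train, test))
    return splits


def balance_classes(data: pd.DataFrame, labels, per_class_n: int, rng=None):
    """Subsample each class to ``per_class_n`` samples without replacement."""
    labels = as_label_series(labels, data.columns)
    rng = as_rng(rng)
    if rng is None:
        rng = np.random.default_rng()
    chosen: list[str] = []
    for c in sorted(labels.unique()):
        members = list(labels.index[labels == c])
        if len(members) < per_class_n:
            raise ValueError(
                f"class {c!r} has {len(members)} samples; cannot draw {per_class_n}"
            )
        take = rng.choice(len(members), size=per_class_n, replace=False)
        chosen.extend(members[k] for k in np.sort(take))
    return data[chosen], labels.loc[chosen]
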