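"""Single-sample pathway scores calibrated on a reference collection.

For a pathway, the reference collection (e.g. healthy tissue) defines a
template; each reference sample's weighted reversal distance to it yields a
distribution whose median ``theta`` and inter-quartile range ``delta0``
calibrate the score of any new sample:

    f(d_new) = 0                      if d_new <= theta
             = (d_new - theta)/delta  otherwise,

with ``delta = max(delta0, w(0.75)/S)`` -- the spread is floored at the
distance of a single reversal of a pair with template probability 0.75, so
the score never divides by a (near-)zero inter-quartile range.  A score of
1 means the sample is one calibrated spread beyond the reference median;
at least half of the reference samples score exactly 0 by construction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import as_rng, as_sample_frame
from .io import GeneSetCollection
from .rank import (
    PairIndex,
    PathwayTemplate,
    WeightFunction,
    binarize,
    binarize_matrix,
    build_template,
    grape_distance,
    resolve_weight,
    single_reversal_distance,
)

__all__ = [
    "ScoreReference",
    "fit_reference",
    "fit_references",
    "score_sample",
    "score_matrix",
    "GrapeScorer",
]


@dataclass
class ScoreReference:
    """Per-pathway score calibration.

    Holds the template, the weight function, the reference distance
    distribution and the derived calibration constants ``theta`` (median),
    ``delta0`` (IQR, linear-interpolation quantiles) and
    ``delta = max(delta0, w(0.75)/S)``.
    """

    template: PathwayTemplate
    weight: WeightFunction
    theta: float
    delta0: float
    delta: float
    reference_distances: np.ndarray = field(repr=False)

    @property
    def degenerate(self) -> bool:
        """True when the template has no informative pairs (S = 0)."""
        return not np.isfinite(self.delta)

    def score(self, d_new: float) -> float:
        """Apply the calibrated score function to a distance."""
        if self.degenerate:
            raise ValueError("cannot score against a degenerate reference")
        if d_new <= self.theta:
            return 0.0
        return (d_new - self.theta) / self.delta


def fit_reference(reference: pd.DataFrame, pathway: Sequence[str],
                  weight="quadratic", rng=None,
                  leave_one_out: bool = False) -> ScoreReference:
    """Build the template and score calibration for one pathway.

    Parameters
    ----------
    reference : genes x samples DataFrame of the reference collection.
    pathway : ordered gene list; genes absent from ``reference`` are
        dropped (>=2 must remain).
    weight : weight-function name, WeightFunction, or callable.
    rng : seed/Generator for tie coin flips and 0.5-roundings; ``None``
        selects the deterministic mode.
    leave_one_out : when True, each reference distance is computed against
        a template rebuilt without that sample.  Default False: reference
        samples are included in their own template.
    """
    rng = as_rng(rng)
    weight = resolve_weight(weight)
    genes = [g for g in pathway if g in reference.index]
    if len(genes) < 2:
        raise ValueError(
            f"pathway covers only {len(genes)} gene(s) of the reference matrix"
        )
    pi = PairIndex(genes)
    values = reference.loc[genes].to_numpy(dtype=float)
    bits = binarize_matrix(values, pi, rng)
    template = build_template(bits, pi, rng)
    S = template.normalizer(weight)
    if S <= 0.0:
        warnings.warn(
            "degenerate reference template (no informative pairs); "
            "pathway flagged unusable for scoring",
            RuntimeWarning,
            stacklevel=2,
        )
        zeros = np.zeros(bits.shape[0])
        return ScoreReference(template, weight, 0.0, 0.0, float("nan"), zeros)
    if leave_one_out:
        if bits.shape[0] < 2:
            raise ValueError("leave-one-out calibration needs >=2 reference samples")
        dists = np.array([
            grape_distance(bits[k], build_template(np.delete(bits, k, axis=0), pi, rng), weight)
            for k in range(bits.shape[0])
        ])
    else:
        dists = np.atleast_1d(grape_distance(bits, template, weight))
    theta = float(np.median(dists))
    q25, q75 = np.quantile(dists, [0.25, 0.75])  # linear interpolation (type 7)
    delta0 = float(q75 - q25)
    delta = max(delta0, single_reversal_distance(template, weight, 0.75))
    return ScoreReference(template, weight, theta, delta0, delta, dists)


def fit_references(reference: pd.DataFrame, gene_sets: Mapping[str, Sequence[str]],
                   weight="quadratic", rng=None,
                   leave_one_out: bool = False) -> dict[str, ScoreReference]:
    """Fit a :class:`ScoreReference` per gene set; skip uncoverable sets."""
    rng = as_rng(rng)
    refs: dict[str, ScoreReference] = {}
    for name in gene_sets:
        genes = gene_sets[name]
        covered = [g for g in genes if g in reference.index]
        if len(covered) < 2:
            warnings.warn(
                f"pathway {name!r} covers {len(covered)} gene(s); skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        refs[name] = fit_reference(reference, covered, weight, rng, leave_one_out)
    return refs


def score_sample(sample, ref: ScoreReference, rng=None) -> float:
    """Score one sample against a fitted reference.

    ``sample`` is a pandas Series indexed by gene id, or an array aligned
    to the reference's pathway gene order.
    """
    rng = as_rng(rng)
    genes = list(ref.template.pair_index.genes)
    if isinstance(sample, pd.Series):
        missing = [g for g in genes if g not in sample.index]
        if missing:
            raise ValueError(f"sample is missing pathway genes: {missing}")
        values = sample.loc[genes].to_numpy(dtype=float)
    else:
        values = np.asarray(sample, dtype=float)
    profile = binarize(values, ref.template.pair_index, rng)
    d = grape_distance(profile, ref.template, ref.weight)
    return ref.score(d)


def score_matrix(samples: pd.DataFrame, references: Mapping[str, ScoreReference],
                 rng=None) -> pd.DataFrame:
    """Score every sample against every reference pathway.

    Returns a pathways x samples DataFrame of nonnegative scores.
    Degenerate references are omitted with a warning.  Scoring the
    reference collection itself is supported (and by construction at
    least half of each pathway's reference scores are 0).
    """
    rng = as_rng(rng)
    rows: dict[str, np.ndarray] = {}
    for name, ref in references.items():
        if ref.degenerate:
            warnings.warn(
                f"pathway {name!r} has a degenerate reference; omitted from scores",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        genes = list(ref.template.pair_index.genes)
        missing = [g for g in genes if g not in samples.index]
        if missing:
            raise ValueError(
                f"pathway {name!r}: samples are missing genes {missing[:5]}"
            )
        values = samples.loc[genes].to_numpy(dtype=float)
        if values.shape[1] == 0:
            rows[name] = np.zeros(0)
            continue
        bits = binarize_matrix(values, ref.template.pair_index, rng)
        d = np.atleast_1d(grape_distance(bits, ref.template, ref.weight))
        rows[name] = np.where(d <= ref.theta, 0.0, (d - ref.theta) / ref.delta)
    out = pd.DataFrame(rows, index=samples.columns).T
    out.index.name = "pathway"
    return out


class GrapeScorer(TransformerMixin, BaseEstimator):
    """Transform samples into per-pathway deviation scores (sklearn-style).

    ``fit(X)`` treats the rows of ``X`` (samples x genes) as the reference
    collection: it builds one rank-pair template per gene set and
    calibrates the score function on the reference distance distribution.
    ``transform(X)`` returns a samples x pathways array of nonnegative
    scores (0 = within reference behaviour).

    Parameters
    ----------
    gene_sets : mapping pathway name -> gene list (e.g. a
        :class:`~grape.io.GeneSetCollection`).
    weight : "quadratic" (default), "constant", or a callable on [0, 1].
    min_size, max_size : inclusive bounds on covered pathway size; sets
        outside the bounds are dropped at fit time.
    leave_one_out : calibrate each reference distance against a template
        rebuilt without that sample.
    random_state : seed for tie coin flips and 0.5-roundings; ``None``
        selects the deterministic tie mode.
    """

    def __init__(self, gene_sets=None, weight="quadratic", min_size=2,
                 max_size=250, leave_one_out=False, random_state=None):
        self.gene_sets = gene_sets
        self.weight = weight
        self.min_size = min_size
        self.max_size = max_size
        self.leave_one_out = leave_one_out
        self.random_state = random_state

    def _rng(self):
        return None if self.random_state is None else np.random.default_rng(self.random_state)

    def fit(self, X, y=None):
        if self.gene_sets is None:
            raise ValueError("GrapeScorer requires gene_sets")
        df = as_sample_frame(X)
        expr = df.T
        from .io import filter_pathways  # local import avoids a cycle at module load

        sets = self.gene_sets
        if not isinstance(sets, GeneSetCollection):
            sets = GeneSetCollection(sets)
        kept, _ = filter_pathways(sets, expr, max(2, int(self.min_size)),
                                  int(self.max_size))
        refs = fit_references(expr, kept, self.weight, self._rng(),
                              self.leave_one_out)
        self.references_ = {n: r for n, r in refs.items() if not r.degenerate}
        n_deg = len(refs) - len(self.references_)
        if n_deg:
            warnings.warn(
                f"{n_deg} pathway(s) with degenerate templates dropped",
                RuntimeWarning,
                stacklevel=2,
            )
        self.pathway_names_ = list(self.references_)
        self.n_features_in_ = df.shape[1]
        self.feature_names_in_ = np.asarray(df.columns)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "references_"):
            raise ValueError("GrapeScorer is not fitted")
        df = as_sample_frame(X)
        scores = score_matrix(df.T, self.references_, self._rng())
        return scores.reindex(self.pathway_names_).T.to_numpy()

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.pathway_names_, dtype=object)
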