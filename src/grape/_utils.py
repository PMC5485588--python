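"""Small shared helpers: random-source normalisation and input coercion."""
from __future__ import annotations

import numpy as np
import pandas as pd

RandomLike = "np.random.Generator | np.random.SeedSequence | int | None"


def as_rng(rng):
    """Normalise a random source.

    ``None`` is passed through and selects the deterministic tie mode
    (ties binarize to 0, template probabilities of exactly 0.5 round to 1).
    Integers and :class:`numpy.random.SeedSequence` seed a fresh generator;
    an existing :class:`numpy.random.Generator` is returned unchanged.
    """
    if rng is None:
        return None
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def require_rng(rng):
    """Like :func:`as_rng` but ``None`` seeds a non-reproducible generator.

    Used where randomness is structural (subsampling, simulation) rather
    than a tie-breaking detail.
    """
    if rng is None:
        return np.random.default_rng()
    return as_rng(rng)


def as_sample_frame(X) -> pd.DataFrame:
    """Coerce estimator input to a samples x genes DataFrame.

    Arrays get positional feature names ``x0, x1, ...`` so that gene-set
    definitions can still refer to them.
    """
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D samples x genes array, got shape {arr.shape}")
    return pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])


def as_label_series(labels, sample_ids) -> pd.Series:
    """Align class labels to a sequence of sample identifiers."""
    if isinstance(labels, pd.DataFrame):
        if "label" not in labels.columns:
            raise ValueError("annotation table has no 'label' column")
        labels = labels["label"]
    if isinstance(labels, pd.Series):
        aligned = labels.reindex(sample_ids)
        if aligned.isna().any():
            missing = list(aligned.index[aligned.isna()])[:5]
            raise ValueError(f"samples without a class label: {missing}")
        return aligned.astype(str)
    labels = list(labels)
    if len(labels) != len(sample_ids):
        raise ValueError(
            f"{len(labels)} labels for {len(sample_ids)} samples"
        )
    return pd.Series([str(x) for x in labels], index=sample_ids)
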