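"""Differential pathway analysis and batch-effect rate statistics.

Two families of statistics live here.

Differential pathways: per pathway, a two-sided t-test (Welch by default)
compares the pathway scores of two sample groups, with Bonferroni control
over the pathways tested.

Batch-effect rates, for a pair of expression datasets sharing a gene set:

* ARDE -- absolute rate of differential expression: the fraction of genes
  whose two-sided t-test across the datasets has p below the threshold
  (default 0.01); computed on the matrices as given (ARDE-N) or after
  per-sample standardization of each full profile (ARDE-S).
* RRDE -- relative rate of differential expression: the fraction of gene
  pairs whose *ordering proportions* differ between the datasets, judged
  by an exact test of two binomial proportions (Fisher's exact test on the
  2x2 ordering-by-dataset table).  Exhaustive pair testing is quadratic in
  genes, so RRDE is estimated by averaging over random gene subsets
  (default 10 draws of 200 genes).
* DOM -- differential ordering measure of a gene: its count of
  significantly differentially ordered pairs (p <= threshold) divided by
  the gene-average count, so DOM averages to 1.

Between datasets of the *same* tissue only batch effects act, so the
hetero-/homo-tissue ratio of a rate is a signal-to-noise measure for the
underlying representation: a rank-pair representation that suppresses
batch shifts yields a higher ratio than absolute expression.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import as_rng, require_rng
from .io import intersect_genes, standardize_samples
from .rank import PairIndex, binarize_matrix

__all__ = [
    "differential_pathways",
    "arde",
    "rrde",
    "rrde_exhaustive",
    "RrdeResult",
    "dom",
    "hetero_homo_ratio",
    "batch_rate_report",
    "BatchRateReport",
]


def differential_pathways(scores_a: pd.DataFrame, scores_b: pd.DataFrame,
                          alpha: float = 0.01, equal_var: bool = False,
                          names: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Two-sided t-test per pathway on score matrices, Bonferroni-adjusted.

    Both inputs are pathways x samples.  Returns a DataFrame indexed by
    pathway with columns mean_a, mean_b, t, p, p_bonferroni, significant,
    direction (the group with the larger mean score, i.e. the more
    disordered one; empty where not significant).
    """
    if set(scores_a.index) != set(scores_b.index):
        raise ValueError("score matrices cover different pathway sets")
    scores_b = scores_b.reindex(scores_a.index)
    if scores_a.shape[1] < 2 or scores_b.shape[1] < 2:
        raise ValueError("need >=2 samples per group")
    a = scores_a.to_numpy(dtype=float)
    b = scores_b.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    # zero variance in both groups: identical means -> p = 1, else p = 0
    nan = ~np.isfinite(p)
    p[nan] = np.where(np.isclose(mean_a[nan], mean_b[nan]), 1.0, 0.0)
    t[~np.isfinite(t)] = 0.0
    m = len(p)
    p_adj = np.minimum(1.0, p * m)
    significant = p_adj < alpha
    direction = np.where(mean_a > mean_b, names[0], names[1])
    direction = np.where(significant, direction, "")
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "t": t,
            "p": p,
            "p_bonferroni": p_adj,
            "significant": significant,
            "direction": direction,
        },
        index=scores_a.index,
    )


def arde(data_a: pd.DataFrame, data_b: pd.DataFrame, standardized: bool = False,
         p_threshold: float = 0.01, equal_var: bool = False) -> float:
    """Absolute rate of differential expression between two datasets.

    Per shared gene, a two-sided t-test across the datasets; the rate is
    the fraction of genes with p strictly below ``p_threshold``.  With
    ``standardized=True`` each dataset is first column-standardized over
    its full gene profile, then restricted to the shared genes.
    """
    if data_a.shape[1] < 2 or data_b.shape[1] < 2:
        raise ValueError("need >=2 samples in each dataset")
    if standardized:
        data_a = standardize_samples(data_a)
        data_b = standardize_samples(data_b)
    a, b = intersect_genes([data_a, data_b])
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a.to_numpy(float), b.to_numpy(float),
                              axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0  # constant identical genes are not differential
    return float(np.mean(p < p_threshold))


def _pair_ordering_pvalues(count_a: np.ndarray, n_a: int,
                           count_b: np.ndarray, n_b: int) -> np.ndarray:
    """Two-sided Fisher exact p-values for many 2x2 ordering tables.

    ``count_x[k]`` is the number of samples in dataset x whose bit for
    pair k is 1.  Tables repeat heavily (only (n_a+1)*(n_b+1) are
    possible), so p-values are computed per unique table.
    """
    key = count_a.astype(np.int64) * (n_b + 1) + count_b.astype(np.int64)
    uniq, inv = np.unique(key, return_inverse=True)
    p_uniq = np.empty(uniq.size)
    for t, k in enumerate(uniq):
        a = int(k // (n_b + 1))
        b = int(k % (n_b + 1))
        p_uniq[t] = stats.fisher_exact(
            [[a, n_a - a], [b, n_b - b]], alternative="two-sided"
        ).pvalue
    return p_uniq[inv]


def _pair_pvalues(a: pd.DataFrame, b: pd.DataFrame, rng) -> tuple[np.ndarray, PairIndex]:
    pi = PairIndex(a.index)
    bits_a = binarize_matrix(a.to_numpy(float), pi, rng)
    bits_b = binarize_matrix(b.to_numpy(float), pi, rng)
    count_a = bits_a.sum(axis=0)
    count_b = bits_b.sum(axis=0)
    p = _pair_ordering_pvalues(count_a, bits_a.shape[0], count_b, bits_b.shape[0])
    return p, pi


class RrdeResult(NamedTuple):
    mean: float
    sd: float
    rates: np.ndarray


def rrde(data_a: pd.DataFrame, data_b: pd.DataFrame, n_draws: int = 10,
         genes_per_draw: int = 200, p_threshold: float = 0.01,
         rng=None) -> RrdeResult:
    """Relative rate of differential expression, subsampling estimator.

    Averages the significant-pair fraction over ``n_draws`` random draws
    of ``genes_per_draw`` shared genes (defaults 10 x 200); returns mean,
    sd over draws (ddof=1) and the individual rates.
    """
    if genes_per_draw < 2:
        raise ValueError("genes_per_draw must be >= 2")
    a, b = intersect_genes([data_a, data_b])
    if a.shape[0] < genes_per_draw:
        raise ValueError(
            f"only {a.shape[0]} shared genes; need >= {genes_per_draw}"
        )
    rng = require_rng(rng)
    rates = []
    for _ in range(n_draws):
        sel = np.sort(rng.choice(a.shape[0], size=genes_per_draw, replace=False))
        p, _ = _pair_pvalues(a.iloc[sel], b.iloc[sel], rng)
        rates.append(float(np.mean(p < p_threshold)))
    rates = np.asarray(rates)
    sd = float(np.std(rates, ddof=1)) if n_draws > 1 else 0.0
    return RrdeResult(float(rates.mean()), sd, rates)


def rrde_exhaustive(data_a: pd.DataFrame, data_b: pd.DataFrame,
                    p_threshold: float = 0.01, rng=None) -> float:
    """RRDE over *all* pairs of the shared gene set (quadratic; small sets)."""
    a, b = intersect_genes([data_a, data_b])
    if a.shape[0] < 2:
        raise ValueError("need >=2 shared genes")
    p, _ = _pair_pvalues(a, b, as_rng(rng))
    return float(np.mean(p < p_threshold))


def dom(data_a: pd.DataFrame, data_b: pd.DataFrame,
        p_threshold: float = 0.01, rng=None) -> pd.DataFrame:
    """Differential ordering measure per shared gene.

    Exhaustively tests every pair's ordering proportions between the
    datasets (Fisher exact, significant at p <= ``p_threshold``), counts
    per gene the significant pairs containing it, and normalises by the
    gene-average count so DOM has mean 1.  If no pair is significant the
    counts are all zero and DOM is reported as NaN with a warning.
    """
    a, b = intersect_genes([data_a, data_b])
    if a.shape[0] < 2:
        raise ValueError("need >=2 shared genes")
    p, pi = _pair_pvalues(a, b, as_rng(rng))
    sig = p <= p_threshold
    m = pi.n_genes
    counts = (np.bincount(pi.i[sig], minlength=m)
              + np.bincount(pi.j[sig], minlength=m))
    mean_count = counts.mean()
    if mean_count > 0:
        dom_values = counts / mean_count
    else:
        warnings.warn("no significant differentially ordered pairs; DOM undefined",
                      RuntimeWarning, stacklevel=2)
        dom_values = np.full(m, np.nan)
    out = pd.DataFrame({"count": counts, "dom": dom_values},
                       index=pd.Index(pi.genes, name="gene"))
    return out


def hetero_homo_ratio(homo, hetero):
    """Ratio of mean hetero-tissue rate to mean homo-tissue rate.

    Accepts scalars/sequences (returns a float) or aligned DataFrames /
    Series collections with one column per metric (returns a Series of
    per-metric ratios).
    """
    if isinstance(homo, pd.DataFrame) and isinstance(hetero, pd.DataFrame):
        hm = homo.mean(axis=0)
        ht = hetero.mean(axis=0)
        if (hm == 0).any():
            raise ValueError("zero homo-tissue mean rate")
        return ht / hm
    hm = float(np.mean(np.asarray(homo, dtype=float)))
    ht = float(np.mean(np.asarray(hetero, dtype=float)))
    if hm == 0:
        raise ValueError("zero homo-tissue mean rate")
    return ht / hm


@dataclass
class BatchRateReport:
    """Pairwise batch-effect rates and their hetero/homo ratios.

    ``pairs`` has one row per dataset pair with columns dataset_a,
    dataset_b, kind (homo/hetero), arde_n, arde_s, rrde_mean, rrde_sd;
    ``ratios`` holds the per-metric hetero/homo mean-rate ratio.
    """

    pairs: pd.DataFrame
    ratios: pd.Series = field(default=None)


def batch_rate_report(datasets: Mapping[str, pd.DataFrame],
                      tissues: Mapping[str, str], n_draws: int = 10,
                      genes_per_draw: int = 200, p_threshold: float = 0.01,
                      rng=None) -> BatchRateReport:
    """ARDE-N, ARDE-S and RRDE for every dataset pair, plus ratios.

    ``datasets`` maps dataset name -> genes x samples matrix; ``tissues``
    maps dataset name -> tissue label.  Pairs of equal tissue are "homo",
    otherwise "hetero".
    """
    rng = require_rng(rng)
    rows = []
    for name_a, name_b in combinations(sorted(datasets), 2):
        da, db = datasets[name_a], datasets[name_b]
        kind = "homo" if str(tissues[name_a]) == str(tissues[name_b]) else "hetero"
        rr = rrde(da, db, n_draws, genes_per_draw, p_threshold, rng)
        rows.append({
            "dataset_a": name_a,
            "dataset_b": name_b,
            "kind": kind,
            "arde_n": arde(da, db, standardized=False, p_threshold=p_threshold),
            "arde_s": arde(da, db, standardized=True, p_threshold=p_threshold),
            "rrde_mean": rr.mean,
            "rrde_sd": rr.sd,
        })
    pairs = pd.DataFrame.from_records(rows)
    metrics = ["arde_n", "arde_s", "rrde_mean"]
    homo = pairs.loc[pairs["kind"] == "homo", metrics]
    hetero = pairs.loc[pairs["kind"] == "hetero", metrics]
    if len(homo) and len(hetero):
        ratios = hetero_homo_ratio(homo, hetero)
        ratios.name = "hetero_homo_ratio"
    else:
        ratios = None
    return BatchRateReport(pairs, ratios)
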