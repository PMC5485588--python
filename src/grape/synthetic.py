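"""Synthetic expression cohorts with known ordering structure.

The generator targets *ordering* structure, not realistic count
distributions.  Each class has a consensus gene ordering (a permutation);
a sample's base value for a gene is that gene's consensus rank plus
Gaussian jitter.  The jitter scale is calibrated from ``flip_noise``: a
pair of genes adjacent in the consensus flips with exactly that
probability, and pairs further apart flip less -- mirroring the rank
stability of real profiles.  On top of the base values, a batch adds
gene-specific additive shifts (constant within the batch) and applies a
per-sample strictly increasing distortion (affine, exponential or power),
which perturbs absolute expression without touching within-sample
orderings.  A ``tie_rate`` sets genes to exactly 0, emulating unexpressed
genes -- the regime where exact expression ties actually occur.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from ._utils import require_rng
from .io import GeneSetCollection

__all__ = [
    "BatchSpec",
    "GeneratorConfig",
    "generate_cohort",
    "generate_gmt",
    "monotone_transform",
    "jitter_sd_for_flip_noise",
    "DISTORTIONS",
]


def jitter_sd_for_flip_noise(flip_noise: float) -> float:
    """Jitter sd such that adjacent-rank pairs flip with prob ``flip_noise``.

    Two genes one rank apart differ by 1 in base value; with iid Gaussian
    jitter of sd ``s`` on each, the difference has sd ``s*sqrt(2)``, so
    the flip probability is ``Phi(-1/(s*sqrt(2)))``.  Inverting gives
    ``s = 1/(sqrt(2) * Phi^-1(1 - flip_noise))``.  Requires
    ``0 <= flip_noise < 0.5``.
    """
    if not 0.0 <= flip_noise < 0.5:
        raise ValueError("flip_noise must lie in [0, 0.5)")
    if flip_noise == 0.0:
        return 0.0
    return float(1.0 / (np.sqrt(2.0) * ndtri(1.0 - flip_noise)))


def _affine(v: np.ndarray, rng) -> np.ndarray:
    a = rng.uniform(0.5, 2.0)
    b = rng.uniform(-2.0, 2.0)
    return a * v + b


def _exponential(v: np.ndarray, rng) -> np.ndarray:
    scale = max(1.0, float(np.abs(v).max()))
    return np.exp(3.0 * v / scale)


def _power(v: np.ndarray, rng) -> np.ndarray:
    gamma = rng.uniform(0.5, 2.0)
    return np.sign(v) * np.abs(v) ** gamma


DISTORTIONS = {
    "identity": lambda v, rng: v,
    "affine": _affine,
    "exp": _exponential,
    "power": _power,
}


def monotone_transform(values, family: str, rng=None) -> np.ndarray:
    """Apply a strictly increasing transform from a named family.

    Parameters of the affine/power families are drawn from ``rng``; the
    transform is rank-preserving by construction, so rank-pair statistics
    of the input are unchanged.
    """
    if family not in DISTORTIONS:
        raise ValueError(f"unknown distortion {family!r}; choose from {sorted(DISTORTIONS)}")
    rng = require_rng(rng)
    return DISTORTIONS[family](np.asarray(values, dtype=float), rng)


@dataclass(frozen=True)
class BatchSpec:
    """One batch: gene-shift scale and per-sample distortion family."""

    name: str = "batch0"
    shift_sd: float = 0.0
    distortion: str = "identity"

    def __post_init__(self):
        if self.distortion not in DISTORTIONS:
            raise ValueError(f"unknown distortion {self.distortion!r}")
        if self.shift_sd < 0:
            raise ValueError("shift_sd must be >= 0")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    ``class_orders`` is either an int (that many random consensus
    permutations, labelled class0, class1, ...) or a mapping
    label -> permutation of gene indices (position k holds the index of
    the gene with rank k, i.e. the k-th lowest expression).
    Samples are assigned to ``batch_specs`` round-robin within each class.
    ``seed`` is mandatory: the same config yields a bit-identical cohort.
    """

    seed: int
    n_genes: int = 100
    n_per_class: int = 30
    class_orders: int | Mapping[str, Sequence[int]] = 2
    flip_noise: float = 0.1
    batch_specs: tuple[BatchSpec, ...] = (BatchSpec(),)
    tie_rate: float = 0.0

    def __post_init__(self):
        if self.n_genes < 2 or self.n_per_class < 1:
            raise ValueError("need n_genes >= 2 and n_per_class >= 1")
        if not 0.0 <= self.tie_rate <= 1.0:
            raise ValueError("tie_rate must lie in [0, 1]")
        jitter_sd_for_flip_noise(self.flip_noise)  # validates range
        self.batch_specs = tuple(self.batch_specs)
        if not self.batch_specs:
            raise ValueError("need at least one batch spec")


def _resolve_orders(config: GeneratorConfig, rng) -> dict[str, np.ndarray]:
    m = config.n_genes
    if isinstance(config.class_orders, int):
        if config.class_orders < 1:
            raise ValueError("need at least one class")
        return {f"class{k}": rng.permutation(m) for k in range(config.class_orders)}
    orders = {}
    for label, perm in config.class_orders.items():
        perm = np.asarray(perm, dtype=int)
        if sorted(perm.tolist()) != list(range(m)):
            raise ValueError(f"class {label!r}: not a permutation of {m} genes")
        orders[str(label)] = perm
    return orders


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort; returns (genes x samples matrix, annotations).

    The annotation table is indexed by sample id with columns ``label``
    and ``batch``.  Identical configs give bit-identical cohorts.
    """
    root = np.random.SeedSequence(config.seed)
    ss_perm, ss_shift, ss_samples = root.spawn(3)
    rng_perm = np.random.default_rng(ss_perm)
    rng_shift = np.random.default_rng(ss_shift)
    rng = np.random.default_rng(ss_samples)

    m = config.n_genes
    genes = [f"G{k:04d}" for k in range(m)]
    orders = _resolve_orders(config, rng_perm)
    sigma = jitter_sd_for_flip_noise(config.flip_noise)
    shifts = {
        spec.name: rng_shift.normal(0.0, 1.0, size=m) * spec.shift_sd
        for spec in config.batch_specs
    }

    columns: list[str] = []
    values: list[np.ndarray] = []
    labels: list[str] = []
    batches: list[str] = []
    for label in sorted(orders):
        perm = orders[label]
        base = np.empty(m)
        base[perm] = np.arange(1, m + 1, dtype=float)  # rank of each gene
        for k in range(config.n_per_class):
            spec = config.batch_specs[k % len(config.batch_specs)]
            v = base + (rng.normal(0.0, sigma, size=m) if sigma > 0 else 0.0)
            v = v + shifts[spec.name]
            if config.tie_rate > 0:
                v[rng.random(m) < config.tie_rate] = 0.0
            v = DISTORTIONS[spec.distortion](v, rng)
            columns.append(f"{label}.{spec.name}.s{k:03d}")
            values.append(v)
            labels.append(label)
            batches.append(spec.name)
    df = pd.DataFrame(np.column_stack(values), index=pd.Index(genes, name="gene"),
                      columns=columns)
    ann = pd.DataFrame({"label": labels, "batch": batches},
                       index=pd.Index(columns, name="sample"))
    return df, ann


def generate_gmt(n_pathways: int, size_range: tuple[int, int],
                 gene_pool: Sequence[str], rng=None) -> GeneSetCollection:
    """Random gene sets drawn without replacement from a pool."""
    rng = require_rng(rng)
    lo, hi = int(size_range[0]), int(size_range[1])
    pool = [str(g) for g in gene_pool]
    if not (2 <= lo <= hi <= len(pool)):
        raise ValueError(
            f"infeasible size range ({lo}, {hi}) for a pool of {len(pool)} genes"
        )
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    for k in range(int(n_pathways)):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(pool), size=size, replace=False)
        name = f"PW{k:04d}"
        sets[name] = [pool[i] for i in members]
        desc[name] = "synthetic pathway"
    return GeneSetCollection(sets, desc)
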