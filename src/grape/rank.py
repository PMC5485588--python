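"""Pairwise rank profiles, consensus templates and reversal distances.

The model
---------
For a pathway with genes ``(g_1, ..., g_m)`` each sample's expression vector
is reduced to a bit vector ``B`` over the ``m(m-1)/2`` gene pairs, where the
bit for pair ``(g_i, g_j)``, ``i < j``, is 1 iff the expression of ``g_i`` is
below that of ``g_j``.  Equal values are resolved by a fair coin (or, in the
deterministic mode used for regression tests, set to 0).  This binary
representation carries exactly the ranking information of the sample, so it
is invariant to any strictly increasing per-sample transform -- the property
that makes rank-pair methods robust to monotone normalisation and many batch
distortions.

Averaging the bit vectors of a reference collection entrywise yields the
*probability template* ``T_P`` (per pair, the fraction of reference samples
with ``g_i < g_j``); rounding it gives the *binary template* ``T_B``, the
consensus ordering (exact 0.5 entries are assigned by a coin flip, or to 1 in
deterministic mode).

Distances between a sample's bits ``B`` and a template:

* uniform-weight (DIRAC) distance: the proportion of reversals,
  ``D = (1/|E|) * sum |T_B - B|``;
* weighted (GRAPE) distance:
  ``D = (1/S) * sum w(T_P) * |T_B - B|`` with ``S = sum w(T_P)``,

where the weight function ``w`` maps a template probability to a penalty.
The built-in quadratic weight ``w(x) = (x - 0.5)**2`` down-weights pairs
whose ordering is variable in the reference; the constant weight recovers
the uniform-weight distance exactly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "PairIndex",
    "PairwiseBinaryProfile",
    "PathwayTemplate",
    "WeightFunction",
    "QUADRATIC",
    "CONSTANT",
    "resolve_weight",
    "binarize",
    "binarize_matrix",
    "build_template",
    "dirac_distance",
    "grape_distance",
    "single_reversal_distance",
    "write_templates",
    "read_templates",
]


class PairIndex:
    """Deterministic enumeration of the gene pairs of one pathway.

    Pairs are the ``(i, j)`` with ``i < j`` in the pathway's given gene
    order, enumerated lexicographically:
    ``(g1,g2), (g1,g3), ..., (g_{m-1}, g_m)``.  All entrywise aggregation
    downstream relies only on this order being fixed and shared.
    """

    __slots__ = ("genes", "i", "j")

    def __init__(self, genes: Sequence[str]):
        genes = tuple(str(g) for g in genes)
        if len(genes) < 2:
            raise ValueError("a pathway needs at least 2 genes")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate genes in pathway")
        self.genes = genes
        i, j = np.triu_indices(len(genes), k=1)
        self.i = i
        self.j = j

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_pairs(self) -> int:
        return int(self.i.size)

    def pairs(self) -> list[tuple[str, str]]:
        return [(self.genes[a], self.genes[b]) for a, b in zip(self.i, self.j)]

    def __eq__(self, other) -> bool:
        return isinstance(other, PairIndex) and self.genes == other.genes

    def __hash__(self) -> int:
        return hash(self.genes)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PairIndex({self.n_genes} genes, {self.n_pairs} pairs)"


@dataclass
class PairwiseBinaryProfile:
    """One sample's bit vector over the pairs of a pathway."""

    pair_index: PairIndex
    bits: np.ndarray

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (self.pair_index.n_pairs,):
            raise ValueError(
                f"expected {self.pair_index.n_pairs} bits, got shape {self.bits.shape}"
            )
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("profile bits must be 0 or 1")


@dataclass
class PathwayTemplate:
    """Probability template ``T_P``, binary template ``T_B`` and provenance.

    ``probability[k]`` is the fraction of reference samples with
    ``g_i < g_j`` for the k-th pair; ``binary`` is its rounding, the
    consensus ordering of the reference collection.
    """

    pair_index: PairIndex
    probability: np.ndarray
    binary: np.ndarray
    n_reference: int = 0

    def __post_init__(self):
        self.probability = np.asarray(self.probability, dtype=float)
        self.binary = np.asarray(self.binary, dtype=np.uint8)
        n = self.pair_index.n_pairs
        if self.probability.shape != (n,) or self.binary.shape != (n,):
            raise ValueError("template arrays must match the pair index length")
        if ((self.probability < 0) | (self.probability > 1)).any():
            raise ValueError("template probabilities must lie in [0, 1]")

    def normalizer(self, weight="quadratic") -> float:
        """S = sum of weights over all pairs for this template."""
        weight = resolve_weight(weight)
        return float(np.sum(weight(self.probability)))

    def is_degenerate(self, weight="quadratic") -> bool:
        """True when every pair has zero weight (no informative pairs)."""
        return self.normalizer(weight) <= 0.0


@dataclass(frozen=True)
class WeightFunction:
    """A penalty weight ``w: [0,1] -> [0, inf)`` applied to ``T_P``."""

    fn: Callable[[np.ndarray], np.ndarray]
    label: str = "custom"

    def __call__(self, x):
        return np.asarray(self.fn(np.asarray(x, dtype=float)), dtype=float)


QUADRATIC = WeightFunction(lambda x: (x - 0.5) ** 2, "quadratic")
CONSTANT = WeightFunction(lambda x: np.ones_like(x), "constant")

_BUILTIN_WEIGHTS: Mapping[str, WeightFunction] = {
    "quadratic": QUADRATIC,
    "constant": CONSTANT,
}


def resolve_weight(weight) -> WeightFunction:
    """Accept a builtin name, a WeightFunction, or a bare callable."""
    if isinstance(weight, WeightFunction):
        return weight
    if isinstance(weight, str):
        try:
            return _BUILTIN_WEIGHTS[weight]
        except KeyError:
            raise ValueError(
                f"unknown weight {weight!r}; builtins: {sorted(_BUILTIN_WEIGHTS)}"
            ) from None
    if callable(weight):
        return WeightFunction(weight)
    raise TypeError(f"cannot interpret {weight!r} as a weight function")


def binarize(values, pair_index: PairIndex, rng=None) -> PairwiseBinaryProfile:
    """Reduce one sample's pathway expression to its pairwise bit vector.

    ``bit(i, j) = 1`` iff ``values[i] < values[j]``.  Exactly equal values
    draw a fair coin from ``rng``; with ``rng=None`` ties resolve to 0
    (deterministic mode).  Only exact equality counts as a tie.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size != pair_index.n_genes:
        raise ValueError(f"expected {pair_index.n_genes} values, got {v.size}")
    if not np.isfinite(v).all():
        raise ValueError("non-finite expression value in sample")
    vi = v[pair_index.i]
    vj = v[pair_index.j]
    bits = (vi < vj).astype(np.uint8)
    ties = vi == vj
    if ties.any() and rng is not None:
        bits[ties] = rng.integers(0, 2, size=int(ties.sum()), dtype=np.uint8)
    return PairwiseBinaryProfile(pair_index, bits)


def binarize_matrix(values, pair_index: PairIndex, rng=None) -> np.ndarray:
    """Vectorised :func:`binarize` over a genes x samples matrix.

    Returns a ``(n_samples, n_pairs)`` uint8 array.  Tie coin flips, when
    ``rng`` is given, are drawn in C order over the (sample, pair) tie mask,
    so identical inputs (and in particular monotone transforms of the same
    input) consume the stream identically.
    """
    V = np.asarray(values, dtype=float)
    if V.ndim != 2 or V.shape[0] != pair_index.n_genes:
        raise ValueError(
            f"expected a ({pair_index.n_genes}, n_samples) matrix, got {V.shape}"
        )
    if not np.isfinite(V).all():
        raise ValueError("non-finite expression value in matrix")
    Vi = V[pair_index.i, :]
    Vj = V[pair_index.j, :]
    bits = (Vi < Vj).T.astype(np.uint8)
    ties = (Vi == Vj).T
    if ties.any() and rng is not None:
        bits[ties] = rng.integers(0, 2, size=int(ties.sum()), dtype=np.uint8)
    return bits


def _stack_profiles(profiles, pair_index):
    """Normalise profile input to (bits 2-D array, PairIndex)."""
    if isinstance(profiles, np.ndarray):
        if pair_index is None:
            raise ValueError("pair_index is required with a raw bit array")
        bits = np.atleast_2d(np.asarray(profiles, dtype=np.uint8))
        if bits.shape[1] != pair_index.n_pairs:
            raise ValueError("bit array width does not match pair index")
        return bits, pair_index
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    pi = profiles[0].pair_index
    for p in profiles[1:]:
        if p.pair_index != pi:
            raise ValueError("profiles built on different pair indexes")
    if pair_index is not None and pair_index != pi:
        raise ValueError("pair_index does not match the profiles")
    return np.stack([p.bits for p in profiles]), pi


def build_template(profiles, pair_index: PairIndex | None = None,
                   rng=None) -> PathwayTemplate:
    """Aggregate reference profiles into probability and binary templates.

    ``T_P`` is the entrywise mean of the bits; ``T_B`` its rounding, with
    entries at exactly 0.5 drawn from ``rng`` (or set to 1 when ``rng`` is
    None).  ``profiles`` may be a list of :class:`PairwiseBinaryProfile`
    or a ``(n_samples, n_pairs)`` bit array plus an explicit ``pair_index``.
    """
    bits, pi = _stack_profiles(profiles, pair_index)
    tp = bits.mean(axis=0)
    tb = (tp > 0.5).astype(np.uint8)
    half = tp == 0.5
    if half.any():
        if rng is None:
            tb[half] = 1
        else:
            tb[half] = rng.integers(0, 2, size=int(half.sum()), dtype=np.uint8)
    return PathwayTemplate(pi, tp, tb, n_reference=bits.shape[0])


def _as_bits(profile, template: PathwayTemplate) -> np.ndarray:
    if isinstance(profile, PairwiseBinaryProfile):
        if profile.pair_index != template.pair_index:
            raise ValueError("profile and template use different pair indexes")
        return profile.bits
    bits = np.asarray(profile, dtype=np.uint8)
    if bits.shape[-1] != template.pair_index.n_pairs:
        raise ValueError("bit vector length does not match the template")
    return bits


def dirac_distance(profile, template: PathwayTemplate):
    """Proportion of reversals against the binary template (in [0, 1]).

    Accepts a single profile (returns a float) or a 2-D bit array
    (returns one distance per row).
    """
    bits = _as_bits(profile, template)
    d = np.mean(template.binary != bits, axis=-1)
    return float(d) if np.ndim(d) == 0 else d


def grape_distance(profile, template: PathwayTemplate, weight="quadratic"):
    """Weighted reversal distance against the template (in [0, 1]).

    ``D = (1/S) * sum_k w(T_P[k]) * [T_B[k] != B[k]]`` with
    ``S = sum_k w(T_P[k])``.  With the constant weight this equals
    :func:`dirac_distance` exactly.  A fully uninformative template
    (``S = 0``, e.g. all ``T_P = 0.5`` under the quadratic weight) yields
    distance 0 with a degeneracy warning; such pathways carry no evidence
    of deviation and should be flagged unusable for scoring.
    """
    weight = resolve_weight(weight)
    bits = _as_bits(profile, template)
    w = weight(template.probability)
    if (w < 0).any():
        raise ValueError("weight function produced negative weights")
    S = float(w.sum())
    if S <= 0.0:
        warnings.warn(
            "degenerate template: all pair weights are zero; distance set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        if bits.ndim == 1:
            return 0.0
        return np.zeros(bits.shape[0])
    viol = (template.binary != bits).astype(float)
    d = viol @ w / S
    return float(d) if np.ndim(d) == 0 else d


def single_reversal_distance(template: PathwayTemplate, weight="quadratic",
                             p: float = 0.75) -> float:
    """Distance contributed by one reversal of a pair with ``T_P = p``.

    Equals ``w(p) / S``; used as the floor for the score-calibration
    spread.  With the constant weight this is ``1/|E|`` for any ``p``.
    """
    weight = resolve_weight(weight)
    S = template.normalizer(weight)
    if S <= 0.0:
        raise ValueError("degenerate template: normalizer S is zero")
    return float(weight(p) / S)


# ---------------------------------------------------------------------------
# template serialization (tab-separated; round-trips exactly via repr floats)

def write_templates(templates: Mapping[str, PathwayTemplate], path,
                    provenance: str | None = None) -> None:
    """Serialise templates to TSV: pathway, gene_i, gene_j, probability, binary.

    Reference sample counts go into ``# n_reference`` comment lines.
    Probabilities are written with ``repr`` so the round trip is exact.
    """
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        for name, t in templates.items():
            fh.write(f"# n_reference\t{name}\t{t.n_reference}\n")
        fh.write("pathway\tgene_i\tgene_j\tprobability\tbinary\n")
        for name, t in templates.items():
            pairs = t.pair_index.pairs()
            for k, (gi, gj) in enumerate(pairs):
                fh.write(
                    f"{name}\t{gi}\t{gj}\t{float(t.probability[k])!r}\t{int(t.binary[k])}\n"
                )


def read_templates(path) -> dict[str, PathwayTemplate]:
    """Read templates written by :func:`write_templates`."""
    n_ref: dict[str, int] = {}
    rows: dict[str, list[tuple[str, str, float, int]]] = {}
    order: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        header_seen = False
        for raw in fh:
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith("#"):
                fields = line[1:].strip().split("\t")
                if fields and fields[0] == "n_reference" and len(fields) == 3:
                    n_ref[fields[1]] = int(fields[2])
                continue
            if not header_seen:
                header_seen = True  # column header
                continue
            name, gi, gj, prob, binary = line.split("\t")
            if name not in rows:
                rows[name] = []
                order.append(name)
            rows[name].append((gi, gj, float(prob), int(binary)))
    out: dict[str, PathwayTemplate] = {}
    for name in order:
        genes: list[str] = []
        seen: set[str] = set()
        for gi, gj, _, _ in rows[name]:
            for g in (gi, gj):
                if g not in seen:
                    seen.add(g)
                    genes.append(g)
        pi = PairIndex(genes)
        if len(rows[name]) != pi.n_pairs:
            raise ValueError(
                f"template {name!r}: {len(rows[name])} rows for "
                f"{pi.n_pairs} expected pairs"
            )
        pos = {pair: k for k, pair in enumerate(pi.pairs())}
        tp = np.empty(pi.n_pairs)
        tb = np.empty(pi.n_pairs, dtype=np.uint8)
        for gi, gj, prob, binary in rows[name]:
            if (gi, gj) not in pos:
                raise ValueError(f"template {name!r}: unexpected pair ({gi}, {gj})")
            k = pos[(gi, gj)]
            tp[k] = prob
            tb[k] = binary
        out[name] = PathwayTemplate(pi, tp, tb, n_reference=n_ref.get(name, 0))
    return out
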