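"""Readers, writers and preprocessing for expression matrices and gene sets.

An expression matrix is a plain :class:`pandas.DataFrame` with gene
identifiers as the row index and sample identifiers as columns.  Values may
be on any monotone-comparable scale (microarray intensities, RPKM, ...);
the rank-pair machinery downstream only uses within-sample orderings.
Gene identifiers are matched by exact, case-sensitive string equality.

Gene-set collections use the GMT dialect: one set per line, tab-separated,
``name<TAB>description<TAB>gene1<TAB>gene2...``; trailing empty fields are
ignored and duplicate genes within a line are dropped keeping the first
occurrence.
"""
from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSetCollection",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_annotations",
    "write_annotations",
    "aggregate_probes",
    "standardize_samples",
    "intersect_genes",
    "filter_pathways",
]


class GmtParseError(ValueError):
    """Raised for malformed GMT input; carries the offending line number."""

    def __init__(self, message: str, lineno: int | None = None):
        super().__init__(message)
        self.lineno = lineno


class GeneSetCollection(Mapping):
    """Named, ordered gene lists (pathways) with one description per set.

    Behaves as a read-only mapping ``name -> list of gene ids``.  Within a
    set, genes are unique (duplicates dropped, first occurrence kept) and
    their order is preserved as given.
    """

    def __init__(self, sets: Mapping[str, Sequence[str]], descriptions=None):
        descriptions = dict(descriptions or {})
        self._sets: dict[str, list[str]] = {}
        self._desc: dict[str, str] = {}
        for name, genes in dict(sets).items():
            name = str(name)
            seen: set[str] = set()
            dedup: list[str] = []
            for g in genes:
                g = str(g)
                if g not in seen:
                    seen.add(g)
                    dedup.append(g)
            self._sets[name] = dedup
            self._desc[name] = str(descriptions.get(name, ""))

    def __getitem__(self, name: str) -> list[str]:
        return list(self._sets[name])

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def description(self, name: str) -> str:
        return self._desc[name]

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        names = list(names)
        return GeneSetCollection(
            {n: self._sets[n] for n in names},
            {n: self._desc[n] for n in names},
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneSetCollection({len(self)} sets)"


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each non-empty line must have at least three tab-separated fields
    (name, description, >=1 gene); anything less raises
    :class:`GmtParseError` naming the line.
    """
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise GmtParseError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}",
                    lineno,
                )
            name, description, *genes = fields
            if name in sets:
                raise GmtParseError(f"GMT line {lineno}: duplicate set name {name!r}", lineno)
            sets[name] = genes
            desc[name] = description
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection:
            genes = "\t".join(collection[name])
            fh.write(f"{name}\t{collection.description(name)}\t{genes}\n")


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples tab-separated expression matrix.

    First column holds gene ids, header row holds sample ids.  Lines
    starting with ``#`` are comments; CRLF line endings are tolerated.
    Duplicate identifiers and non-finite values are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate gene identifiers: {dupes}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate sample identifiers: {dupes}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression values in {path}: {exc}") from exc
    finite = np.isfinite(df.to_numpy())
    if not finite.all():
        bad_rows = df.index[np.where(~finite)[0]].unique().tolist()[:5]
        raise ValueError(f"missing or non-finite expression values (genes {bad_rows})")
    return df


def write_expression(df: pd.DataFrame, path, provenance: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index_label="gene")


def read_annotations(path) -> pd.DataFrame:
    """Read a sample annotation table (sample, label[, batch]) with header."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    df.index = df.index.astype(str)
    cols = list(df.columns)
    if not cols or cols[0] != "label":
        # tolerate arbitrary header names: first column is the class label
        rename = {cols[0]: "label"}
        if len(cols) > 1:
            rename[cols[1]] = "batch"
        df = df.rename(columns=rename)
    if df.index.duplicated().any():
        raise ValueError("duplicate sample identifiers in annotation table")
    return df


def write_annotations(ann: pd.DataFrame, path, provenance: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        ann.to_csv(fh, sep="\t", index_label="sample")


def aggregate_probes(matrix: pd.DataFrame, probe_to_gene: Mapping[str, str],
                     policy: str = "mean") -> pd.DataFrame:
    """Collapse probe-level rows to gene-level rows.

    ``policy="mean"`` averages all probes mapped to a gene per sample;
    ``policy="max_variance"`` keeps the single probe with the largest
    across-sample variance.  Unmapped probes are dropped.  Output genes
    appear in order of first mapped probe.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    if policy not in ("mean", "max_variance"):
        raise ValueError(f"unknown aggregation policy {policy!r}")
    keep = [p for p in matrix.index if p in probe_to_gene]
    sub = matrix.loc[keep]
    genes = [probe_to_gene[p] for p in keep]
    if policy == "mean":
        out = sub.groupby(genes, sort=False).mean()
        out.index.name = matrix.index.name
        return out
    variances = sub.var(axis=1, ddof=0).to_numpy()
    best: dict[str, int] = {}
    order: list[str] = []
    for pos, g in enumerate(genes):
        if g not in best:
            best[g] = pos
            order.append(g)
        elif variances[pos] > variances[best[g]]:
            best[g] = pos
    out = sub.iloc[[best[g] for g in order]]
    out.index = pd.Index(order, name=matrix.index.name)
    return out


def standardize_samples(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each sample (column) to mean 0, population sd 1.

    The sd uses the population convention (divide by n).  Rank-pair methods
    are invariant to this monotone transform; it only matters for
    absolute-expression baselines such as the pathway centroid.
    """
    if matrix.shape[0] < 2:
        raise ValueError("standardization needs at least 2 genes")
    values = matrix.to_numpy(dtype=float)
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        bad = matrix.columns[zero].tolist()[:5]
        raise ValueError(f"zero-variance sample(s): {bad}")
    return pd.DataFrame((values - mu) / sd, index=matrix.index, columns=matrix.columns)


def intersect_genes(matrices: Sequence[pd.DataFrame]) -> list[pd.DataFrame]:
    """Restrict every matrix to the genes shared by all, in a common order.

    The order is that of the first matrix.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one matrix")
    common = matrices[0].index
    for m in matrices[1:]:
        common = common.intersection(m.index, sort=False)
    if len(common) == 0:
        raise ValueError("no genes shared across all matrices")
    return [m.loc[common] for m in matrices]


def filter_pathways(collection: GeneSetCollection, genes,
                    min_size: int = 2, max_size: int = 250):
    """Restrict sets to genes present in the data, then filter by size.

    ``genes`` may be an expression matrix (its index is used) or any
    iterable of gene identifiers.  Bounds are inclusive.  Returns the
    filtered collection and a dict of per-set dropped-gene counts.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if isinstance(genes, pd.DataFrame):
        genes = genes.index
    universe = set(str(g) for g in genes)
    kept: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    dropped: dict[str, int] = {}
    for name in collection:
        members = collection[name]
        covered = [g for g in members if g in universe]
        dropped[name] = len(members) - len(covered)
        if min_size <= len(covered) <= max_size:
            kept[name] = covered
            desc[name] = collection.description(name)
    return GeneSetCollection(kept, desc), dropped
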