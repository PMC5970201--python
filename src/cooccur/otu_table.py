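"""OTU count tables: reading, prevalence filtering, rarefaction and sample distances.

An OTU table is an integer count matrix (OTUs × samples) with optional
taxonomy lineage strings per OTU.  All downstream stages of the
co-occurrence pipeline consume this container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "OTUTable",
    "DistanceMatrix",
    "read_otu_table",
    "write_otu_table",
    "filter_prevalence",
    "rarefy",
    "jaccard_similarity_matrix",
    "bray_curtis_matrix",
    "median_pairwise",
    "abundance_share",
]


@dataclass
class OTUTable:
    """Integer count matrix indexed (OTU, sample) with optional taxonomy.

    Parameters
    ----------
    otu_ids : list of str
        Unique OTU identifiers (rows of ``counts``).
    sample_ids : list of str
        Unique sample identifiers (columns of ``counts``).
    counts : ndarray of shape (n_otus, n_samples)
        Non-negative integer read counts.
    taxonomy : dict, optional
        Map from OTU id to a semicolon-delimited lineage string.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.size == 0 or counts.ndim != 2:
            raise ValueError("OTU table must be a non-empty 2-D count matrix")
        if counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.otu_ids)} OTU ids x {len(self.sample_ids)} sample ids"
            )
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.otu_ids)
            if unknown:
                raise ValueError(f"taxonomy given for unknown OTU ids: {sorted(unknown)}")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def copy(self) -> "OTUTable":
        return OTUTable(
            list(self.otu_ids),
            list(self.sample_ids),
            self.counts.copy(),
            dict(self.taxonomy) if self.taxonomy is not None else None,
        )


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise sample scores in [0, 1]."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str  # "jaccard_similarity" | "bray_curtis_distance"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("entries must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def read_otu_table(path, format: str = "tsv") -> OTUTable:
    """Read an OTU table from tab-separated text.

    The header row names the samples, the first column holds OTU ids, and an
    optional trailing column named ``taxonomy`` (case-insensitive) holds
    lineage strings.  Leading ``#``-comment lines in the BIOM TSV export
    dialect (e.g. "# Constructed from biom file") are skipped; a ``#OTU ID``
    header line is not treated as a comment.
    """
    if format != "tsv":
        raise ValueError(f"unsupported format: {format!r}")
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.readlines()
    # skip BIOM-style comment lines but keep a "#OTU ID..." header
    start = 0
    for i, line in enumerate(lines):
        if line.startswith("#") and "\t" not in line:
            start = i + 1
        else:
            break
    body = "".join(lines[start:])
    if not body.strip():
        raise ValueError(f"empty OTU table: {path}")
    from io import StringIO

    df = pd.read_csv(StringIO(body), sep="\t", header=0, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty OTU table: {path}")

    taxonomy = None
    tax_cols = [c for c in df.columns if str(c).strip().lower() == "taxonomy"]
    if tax_cols:
        taxonomy = {str(o): str(t) for o, t in df[tax_cols[0]].items() if pd.notna(t)}
        df = df.drop(columns=tax_cols)
    if df.shape[1] == 0:
        raise ValueError(f"OTU table has no sample columns: {path}")

    otu_ids = [str(o) for o in df.index]
    if len(set(otu_ids)) != len(otu_ids):
        dupes = sorted({o for o in otu_ids if otu_ids.count(o) > 1})
        raise ValueError(f"duplicate OTU ids: {dupes}")
    sample_ids = [str(s) for s in df.columns]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in header")

    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric count at OTU {otu_ids[i]!r}, sample {col!r}: {raw!r}"
                ) from None
            if val < 0 or val != int(val):
                raise ValueError(
                    f"invalid count at OTU {otu_ids[i]!r}, sample {col!r}: {raw!r}"
                )
            counts[i, j] = int(val)
    return OTUTable(otu_ids, sample_ids, counts, taxonomy)


def write_otu_table(table: OTUTable, path) -> None:
    """Write a table as TSV; taxonomy, if present, becomes a trailing column."""
    df = table.to_dataframe()
    if table.taxonomy is not None:
        df = df.copy()
        df["taxonomy"] = [table.taxonomy.get(o, "") for o in table.otu_ids]
    df.index.name = "#OTU ID"
    df.to_csv(path, sep="\t")


def filter_prevalence(table: OTUTable, min_samples: int) -> OTUTable:
    """Drop OTUs present (count > 0) in fewer than ``min_samples`` samples.

    The strict reading of "fewer than": an OTU present in exactly
    ``min_samples`` samples is retained.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    prevalence = (table.counts > 0).sum(axis=1)
    keep = prevalence >= min_samples
    if not keep.any():
        raise ValueError(
            f"prevalence filter (min_samples={min_samples}) removed every OTU"
        )
    otu_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    taxonomy = None
    if table.taxonomy is not None:
        taxonomy = {o: t for o, t in table.taxonomy.items() if o in set(otu_ids)}
    return OTUTable(otu_ids, list(table.sample_ids), table.counts[keep], taxonomy)


def rarefy(table: OTUTable, depth: int, seed) -> OTUTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a warning.
    Sampling uses a multivariate hypergeometric draw per sample, i.e. classic
    rarefaction of the read pool.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} reads")
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"rarefy: dropping {len(dropped)} sample(s) below depth {depth}: {dropped}",
            stacklevel=2,
        )
    new_counts = np.empty((table.n_otus, int(keep.sum())), dtype=np.int64)
    col = 0
    for j in range(table.n_samples):
        if not keep[j]:
            continue
        column = table.counts[:, j]
        if totals[j] == depth:
            new_counts[:, col] = column
        else:
            new_counts[:, col] = rng.multivariate_hypergeometric(column, depth)
        col += 1
    sample_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    taxonomy = dict(table.taxonomy) if table.taxonomy is not None else None
    return OTUTable(list(table.otu_ids), sample_ids, new_counts, taxonomy)


def jaccard_similarity_matrix(table: OTUTable) -> DistanceMatrix:
    """Pairwise Jaccard similarity |A∩B| / |A∪B| on presence (count > 0) sets.

    A pair with an empty union is defined to have similarity 0; the diagonal
    is 1.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    presence = (table.counts > 0).astype(bool).T  # samples x otus
    n = table.n_samples
    sim = np.ones((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            union = (presence[a] | presence[b]).sum()
            inter = (presence[a] & presence[b]).sum()
            val = inter / union if union > 0 else 0.0
            sim[a, b] = sim[b, a] = val
    return DistanceMatrix(list(table.sample_ids), sim, "jaccard_similarity")


def bray_curtis_matrix(table: OTUTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity 1 − 2·Σ min(cᵢₐ, cᵢᵦ) / (Σcᵢₐ + Σcᵢᵦ)."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if (table.counts.sum(axis=0) == 0).any():
        raise ValueError("every sample must have at least one read")
    d = squareform(pdist(table.counts.T.astype(float), metric="braycurtis"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(table.sample_ids), d, "bray_curtis_distance")


def median_pairwise(matrix: DistanceMatrix) -> float:
    """Median of the strict upper triangle (self-pairs excluded)."""
    n = len(matrix.sample_ids)
    if n < 2:
        raise ValueError("need at least 2 samples")
    iu = np.triu_indices(n, k=1)
    return float(np.median(matrix.values[iu]))


def abundance_share(table: OTUTable, otu_ids) -> float:
    """Fraction of all reads held by the listed OTUs."""
    otu_ids = list(otu_ids)
    index = {o: i for i, o in enumerate(table.otu_ids)}
    missing = [o for o in otu_ids if o not in index]
    if missing:
        raise KeyError(f"unknown OTU ids: {missing}")
    if not otu_ids:
        return 0.0
    rows = [index[o] for o in otu_ids]
    total = table.counts.sum()
    return float(table.counts[rows].sum() / total)
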