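"""Domain containers and table I/O for integration-site (IS) abundance data.

An *integration site* is the genomic position where a viral vector inserted
into a transduced cell; every descendant of that cell (a *clone*) carries the
same set of IS, so all IS of one clone share one underlying cell count.  The
containers here hold the three central objects of the reconstruction method:
read counts / relative abundances per IS and measurement, the symmetric
matrix of pairwise R-squared similarities, and the clustering of IS into
putative clones.

Tables are wide format (rows = IS, columns = measurements), tab-delimited by
default.  Tables whose columns already sum to ~1 are accepted as relative
abundances directly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: Column totals within this tolerance of 1 are treated as pre-normalized.
PRENORMALIZED_TOL = 1e-6

#: Tolerance on column sums of a full (unfiltered) abundance matrix.
COLSUM_TOL = 1e-9


class TableFormatError(ValueError):
    """Raised when an input table violates the expected layout."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one measurement (a time point and/or compartment).

    The method only uses measurement identity, never absolute time, so
    ``time`` defaults to the measurement's ordinal position and
    ``compartment`` to ``"sim"`` when no metadata table is supplied.
    """

    sample_id: str
    time: float = 0.0
    compartment: str = "sim"

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time < 0:
            raise ValueError(
                f"sample {self.sample_id!r}: time must be finite and >= 0, "
                f"got {self.time!r}"
            )


def default_samples(sample_ids: Sequence[str]) -> list[SampleMeta]:
    """Ordered, equally spaced measurements for metadata-less tables."""
    return [SampleMeta(sid, float(i)) for i, sid in enumerate(sample_ids)]


def _check_samples(columns: Sequence[str], samples: Sequence[SampleMeta]) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in metadata")
    if list(columns) != ids:
        raise ValueError(
            "sample metadata does not match table columns: "
            f"{list(columns)} vs {ids}"
        )


@dataclass
class ReadCountMatrix:
    """Non-negative integer sequence-read counts per IS per measurement."""

    counts: pd.DataFrame  # index = IS ids, columns = sample ids
    samples: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise TableFormatError(f"duplicate IS id {dup!r}")
        if not self.samples:
            self.samples = default_samples(self.counts.columns)
        _check_samples(self.counts.columns, self.samples)
        if len(self.counts) and (self.counts.to_numpy() < 0).any():
            raise TableFormatError("negative read count")

    @property
    def is_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)


@dataclass
class AbundanceMatrix:
    """Relative IS abundances; every column of a full matrix sums to 1.

    Rows of a *filtered* matrix are a subset of a full one and are
    deliberately not renormalized, so column sums may be below 1.
    """

    abundance: pd.DataFrame
    samples: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.abundance.index.has_duplicates:
            dup = self.abundance.index[self.abundance.index.duplicated()][0]
            raise TableFormatError(f"duplicate IS id {dup!r}")
        if not self.samples:
            self.samples = default_samples(self.abundance.columns)
        _check_samples(self.abundance.columns, self.samples)
        vals = self.abundance.to_numpy(dtype=float)
        if vals.size and (np.isnan(vals).any() or (vals < 0).any()):
            raise TableFormatError("abundances must be non-negative and finite")

    @property
    def is_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def values(self) -> np.ndarray:
        return self.abundance.to_numpy(dtype=float)

    def subset(self, is_ids: Iterable[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(self.abundance.loc[list(is_ids)], self.samples)


@dataclass
class SimilarityMatrix:
    """Symmetric matrix S of pairwise R-squared values with unit diagonal."""

    values_df: pd.DataFrame  # square, index == columns == IS ids

    def __post_init__(self) -> None:
        v = self.values_df.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if list(self.values_df.index) != list(self.values_df.columns):
            raise ValueError("similarity matrix index/columns mismatch")
        if v.size:
            if not np.allclose(v, v.T, atol=1e-12):
                raise ValueError("similarity matrix must be symmetric")
            if not np.allclose(np.diag(v), 1.0, atol=1e-12):
                raise ValueError("similarity matrix diagonal must be 1")
            if v.min() < -1e-12 or v.max() > 1 + 1e-12:
                raise ValueError("similarity values must lie in [0, 1]")

    @property
    def is_ids(self) -> list[str]:
        return list(self.values_df.index)

    @property
    def values(self) -> np.ndarray:
        return self.values_df.to_numpy(dtype=float)

    def dissimilarity(self) -> np.ndarray:
        """D = 1 - S, the dissimilarity used by clustering and silhouette."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return np.clip(d, 0.0, 1.0)


@dataclass
class ClusteringResult:
    """Assignment of IS to clusters (putative clones).

    Labels are integers 1..k; each cluster is represented by one of its own
    members (the medoid).
    """

    is_ids: list[str]
    labels: np.ndarray  # shape (n_is,), values in 1..k
    k: int
    silhouette: float
    medoids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.is_ids):
            raise ValueError("labels/is_ids length mismatch")
        if len(set(self.labels.tolist())) != self.k:
            raise ValueError("number of distinct labels must equal k")
        if len(self.medoids) != self.k:
            raise ValueError("need one medoid per cluster")
        pos = {iid: i for i, iid in enumerate(self.is_ids)}
        for j, m in enumerate(self.medoids, start=1):
            if m not in pos:
                raise ValueError(f"medoid {m!r} is not an IS of this result")
            if self.labels[pos[m]] != j:
                raise ValueError(f"medoid {m!r} does not belong to cluster {j}")

    def members(self, label: int) -> list[str]:
        return [iid for iid, l in zip(self.is_ids, self.labels) if l == label]

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "silhouette": self.silhouette,
                "medoids": self.medoids,
                "labels": {i: int(l) for i, l in zip(self.is_ids, self.labels)},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClusteringResult":
        obj = json.loads(text)
        ids = list(obj["labels"])
        return cls(
            is_ids=ids,
            labels=np.array([obj["labels"][i] for i in ids], dtype=int),
            k=int(obj["k"]),
            silhouette=float(obj["silhouette"]),
            medoids=list(obj["medoids"]),
        )


@dataclass
class ClonalAbundanceMatrix:
    """Clone-level relative abundances, optionally with a background row."""

    abundance: pd.DataFrame  # index = clone ids (+ "background"), cols = samples
    samples: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            self.samples = default_samples(self.abundance.columns)
        _check_samples(self.abundance.columns, self.samples)

    @property
    def clone_ids(self) -> list[str]:
        return list(self.abundance.index)


# ---------------------------------------------------------------------------
# Table readers / writers
# ---------------------------------------------------------------------------

def read_table(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a wide IS table; first column is the IS identifier.

    Raises :class:`TableFormatError` naming the offending cell for duplicate
    IS ids and negative or non-numeric values.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={0: str})
    if df.shape[1] < 1:
        raise TableFormatError(f"{path}: no columns found")
    id_col = df.columns[0]
    ids = df[id_col].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise TableFormatError(f"{path}: duplicate IS id {dup.iloc[0]!r}")
    df = df.set_index(id_col)
    df.index.name = "is_id"
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise TableFormatError(
                f"{path}: non-numeric value {df.loc[row, col]!r} "
                f"at row {row!r}, column {col!r}"
            )
        if numeric.isna().any():
            row = numeric.isna().idxmax()
            raise TableFormatError(f"{path}: missing value at row {row!r}, column {col!r}")
        if (numeric < 0).any():
            row = (numeric < 0).idxmax()
            raise TableFormatError(
                f"{path}: negative value at row {row!r}, column {col!r}"
            )
        df[col] = numeric
    return df


def read_counts_table(path, delimiter: str = "\t",
                      samples: Sequence[SampleMeta] | None = None) -> ReadCountMatrix:
    """Read a wide table of raw read counts (row/column order preserved)."""
    df = read_table(path, delimiter)
    return ReadCountMatrix(df, list(samples) if samples else [])


def read_sample_metadata(path, delimiter: str = "\t") -> list[SampleMeta]:
    """Read a (sample_id, time[, compartment]) metadata table."""
    df = pd.read_csv(path, sep=delimiter, dtype={0: str})
    if df.shape[1] < 2:
        raise TableFormatError(f"{path}: metadata needs sample_id and time columns")
    out = []
    for _, row in df.iterrows():
        compartment = str(row.iloc[2]) if df.shape[1] >= 3 else "sim"
        out.append(SampleMeta(str(row.iloc[0]), float(row.iloc[1]), compartment))
    return out


def write_table(df: pd.DataFrame, path, delimiter: str = "\t") -> None:
    df.to_csv(path, sep=delimiter, index=True, index_label=df.index.name or "is_id")


def load_abundance(path, delimiter: str = "\t",
                   samples: Sequence[SampleMeta] | None = None) -> AbundanceMatrix:
    """Read a wide table and return relative abundances.

    Columns already summing to 1 (within ``PRENORMALIZED_TOL``) are accepted
    as-is; otherwise the values are treated as raw counts and normalized.
    """
    df = read_table(path, delimiter)
    meta = list(samples) if samples else []
    sums = df.to_numpy(dtype=float).sum(axis=0)
    if len(df) and np.all(np.abs(sums - 1.0) <= PRENORMALIZED_TOL):
        return AbundanceMatrix(df.astype(float), meta)
    return to_relative_abundance(ReadCountMatrix(df, meta))


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def to_relative_abundance(m: ReadCountMatrix | AbundanceMatrix) -> AbundanceMatrix:
    """Divide each column by its total so columns sum to 1.

    Idempotent: applied to an already-normalized matrix it returns the same
    values (within floating-point round-off).
    """
    df = m.counts if isinstance(m, ReadCountMatrix) else m.abundance
    if len(df) == 0:
        raise TableFormatError("cannot normalize an empty matrix")
    vals = df.to_numpy(dtype=float)
    totals = vals.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if len(zero):
        raise TableFormatError(
            f"column {df.columns[zero[0]]!r} has zero total abundance"
        )
    rel = pd.DataFrame(vals / totals, index=df.index, columns=df.columns)
    return AbundanceMatrix(rel, m.samples)


# ---------------------------------------------------------------------------
# Graph export
# ---------------------------------------------------------------------------

def to_similarity_graph(s: SimilarityMatrix, c: ClusteringResult,
                        edge_floor: float = 0.0) -> nx.Graph:
    """Build the similarity network: nodes = IS, edge weights = R-squared."""
    if s.is_ids != c.is_ids:
        raise ValueError("similarity matrix and clustering have different IS ids")
    g = nx.Graph()
    for iid, lab in zip(c.is_ids, c.labels):
        g.add_node(iid, cluster=int(lab))
    vals = s.values
    ids = s.is_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            w = float(vals[i, j])
            if w >= edge_floor:
                g.add_edge(ids[i], ids[j], weight=w)
    return g


def export_similarity_graph(s: SimilarityMatrix, c: ClusteringResult, path,
                            edge_floor: float = 0.0) -> None:
    """Write the similarity network as GraphML (cluster node attribute,
    R-squared edge weights; edges below ``edge_floor`` are dropped)."""
    nx.write_graphml(to_similarity_graph(s, c, edge_floor), path)
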