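"""Core data containers and file I/O.

The package works on log2-scale gene-by-sample expression matrices with
per-sample group and batch labels, pathway gene sets, and subject-level
case-control genotype records. All on-disk formats are plain text:

* expression TSV — rows are genes, first column the gene identifier, the
  remaining columns one per sample;
* metadata TSV — columns ``sample_id``, ``group``, ``batch``;
* gene sets — GMT (set name, description, tab-separated member IDs) or a
  plain one-ID-per-line list;
* genotypes CSV — columns ``subject_id``, ``status`` plus one column per
  SNP holding unordered genotype strings such as ``"TT"``/``"AT"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GeneSet",
    "AlignmentError",
    "EmptyDatasetError",
    "read_expression",
    "write_expression",
    "read_gene_set",
    "read_genotypes",
    "write_genotypes",
]


class AlignmentError(ValueError):
    """Matrix columns and sample metadata do not line up."""


class EmptyDatasetError(ValueError):
    """An operation would leave the dataset with no samples or genes."""


@dataclass
class ExpressionDataset:
    """A log2 expression matrix (genes x samples) with sample metadata.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Finite log2 intensities.
    gene_ids : list
        Unique gene identifiers, one per row.
    sample_ids : list
        Unique sample identifiers, one per column.
    groups : ndarray of str
        Per-sample group label (e.g. case/control).
    batches : ndarray
        Per-sample batch label.
    """

    values: np.ndarray
    gene_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)
    groups: np.ndarray = None
    batches: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.groups = np.asarray(self.groups)
        self.batches = np.asarray(self.batches)
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if not (len(self.sample_ids) == len(self.groups) == len(self.batches) == n_samples):
            raise AlignmentError(
                "sample_ids, groups and batches must each have one entry per column"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids are not unique")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("sample_ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values.copy(),
            list(self.gene_ids),
            list(self.sample_ids),
            self.groups.copy(),
            self.batches.copy(),
        )

    def select_samples(self, mask_or_idx) -> "ExpressionDataset":
        idx = np.arange(self.n_samples)[mask_or_idx]
        if len(idx) == 0:
            raise EmptyDatasetError("selection leaves no samples")
        return ExpressionDataset(
            self.values[:, idx],
            self.gene_ids,
            [self.sample_ids[i] for i in idx],
            self.groups[idx],
            self.batches[idx],
        )

    def select_genes(self, gene_ids) -> "ExpressionDataset":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        if len(idx) == 0:
            raise EmptyDatasetError("selection leaves no genes")
        return ExpressionDataset(
            self.values[idx, :],
            list(gene_ids),
            self.sample_ids,
            self.groups,
            self.batches,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "group": self.groups, "batch": self.batches}
        )


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered pathway gene set."""

    name: str
    gene_ids: tuple

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if len(self.gene_ids) == 0:
            raise ValueError("gene set is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene set contains duplicate ids")

    def __len__(self) -> int:
        return len(self.gene_ids)


def read_expression(matrix_path, metadata_path) -> ExpressionDataset:
    """Load an expression TSV plus metadata TSV into an :class:`ExpressionDataset`.

    Metadata may cover extra samples (ignored with a warning); every matrix
    column must be present in the metadata or an :class:`AlignmentError` is
    raised. Matrix column order is preserved.
    """
    try:
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"could not parse expression matrix: {exc}") from exc
    non_numeric = mat.columns[[not np.issubdtype(dt, np.number) for dt in mat.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = mat[col][pd.to_numeric(mat[col], errors="coerce").isna()]
        row = bad.index[0] if len(bad) else "?"
        raise ValueError(
            f"non-numeric expression value in column {col!r}, row {row!r}"
        )
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "group", "batch"}
    if not required.issubset(meta.columns):
        raise AlignmentError(f"metadata must have columns {sorted(required)}")
    meta = meta.set_index("sample_id")
    missing = [c for c in mat.columns if c not in meta.index]
    if missing:
        raise AlignmentError(
            f"samples present in matrix but missing from metadata: {missing}"
        )
    extra = meta.index.difference(mat.columns)
    if len(extra):
        warnings.warn(
            f"{len(extra)} metadata rows have no matrix column and are ignored"
        )
    meta = meta.loc[list(mat.columns)]
    return ExpressionDataset(
        mat.to_numpy(dtype=float),
        list(mat.index),
        list(mat.columns),
        meta["group"].to_numpy(),
        meta["batch"].to_numpy(),
    )


def write_expression(ds: ExpressionDataset, matrix_path, metadata_path) -> None:
    ds.to_frame().to_csv(matrix_path, sep="\t", index_label="gene_id")
    ds.metadata_frame().to_csv(metadata_path, sep="\t", index=False)


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """Read a gene set from GMT (first line used) or a one-ID-per-line list.

    A line containing tabs is treated as GMT: ``name<TAB>description<TAB>id...``.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"gene set file {path} is empty")
    if "\t" in lines[0]:
        fields = lines[0].split("\t")
        if len(fields) < 3:
            raise ValueError("GMT line needs name, description and at least one id")
        return GeneSet(name or fields[0], fields[2:])
    return GeneSet(name or "gene_set", [ln.strip() for ln in lines])


def read_genotypes(path) -> pd.DataFrame:
    """Read subject-level genotype records (CSV).

    Returns a DataFrame with ``subject_id``, ``status`` (``case``/``control``)
    and one genotype-string column per SNP.
    """
    df = pd.read_csv(path, dtype=str)
    if "subject_id" not in df.columns or "status" not in df.columns:
        raise ValueError("genotype CSV must have subject_id and status columns")
    bad = set(df["status"].unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown status labels {sorted(bad)}; expected case/control")
    return df


def write_genotypes(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
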