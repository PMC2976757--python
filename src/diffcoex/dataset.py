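"""Containers and delimited-text I/O for multi-condition expression data.

The central object is :class:`ExpressionDataset`: a genes × samples matrix of
expression values together with a map from each sample to its condition
(e.g. mutant vs. wild type).  Correlation-based downstream steps require at
least two conditions with at least three samples each, and no missing or
non-finite values; validation is performed eagerly at construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

UNASSIGNED = "grey"
"""Reserved label for genes not placed in any differential module."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:10]}")


@dataclass
class ExpressionDataset:
    """Genes × samples expression matrix with a sample → condition map.

    Parameters
    ----------
    values : pandas.DataFrame
        Expression values, rows indexed by gene id, columns by sample id.
    conditions : pandas.Series
        Condition label for every sample; index must equal ``values.columns``.
    """

    values: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if not isinstance(self.conditions, pd.Series):
            self.conditions = pd.Series(self.conditions)
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        missing = self.values.columns.difference(self.conditions.index)
        if len(missing):
            raise ValueError(
                f"samples missing from the condition map: {missing.tolist()[:10]}"
            )
        extra = self.conditions.index.difference(self.values.columns)
        if len(extra):
            raise ValueError(
                f"condition map lists unknown samples: {extra.tolist()[:10]}"
            )
        # align condition order with the expression columns
        self.conditions = self.conditions.loc[self.values.columns]
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))
            g, s = bad[0]
            raise ValueError(
                f"non-finite expression value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r} "
                f"({len(bad)} non-finite values in total)"
            )
        counts = self.conditions.value_counts()
        if len(counts) < 2:
            raise ValueError("at least two conditions are required")
        small = counts[counts < 3]
        if len(small):
            raise ValueError(
                "every condition needs >= 3 samples for correlation; got "
                + ", ".join(f"{k}: {v}" for k, v in small.items())
            )

    # -- accessors -----------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def condition_labels(self) -> list:
        """Condition labels in order of first appearance among the samples."""
        return list(dict.fromkeys(self.conditions))

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def samples_of(self, condition) -> pd.Index:
        return self.conditions.index[self.conditions == condition]

    def subset_genes(self, genes: Iterable) -> "ExpressionDataset":
        genes = pd.Index(genes)
        unknown = genes.difference(self.gene_ids)
        if len(unknown):
            raise KeyError(f"unknown gene ids: {unknown.tolist()[:10]}")
        return ExpressionDataset(self.values.loc[genes], self.conditions.copy())

    # -- I/O -----------------------------------------------------------
    @classmethod
    def from_files(
        cls, expression_path, condition_path, sep: str | None = None
    ) -> "ExpressionDataset":
        """Read expression matrix and condition map from delimited text.

        Expression file: first column gene ids, header row sample ids.
        Condition file: two columns, sample id and condition label
        (a header row is detected and skipped if its first field matches
        no expression sample).
        """
        values = pd.read_csv(
            expression_path, sep=sep or _sniff_sep(expression_path), index_col=0
        )
        cond = _read_condition_map(condition_path, sep)
        return cls(values, cond)

    def to_files(self, expression_path, condition_path, sep: str = "\t") -> None:
        self.values.to_csv(expression_path, sep=sep)
        self.conditions.rename("condition").rename_axis("sample_id").to_csv(
            condition_path, sep=sep
        )


def _sniff_sep(path) -> str:
    first = Path(path).open().readline()
    return "," if ("," in first and "\t" not in first) else "\t"


def _read_condition_map(path, sep: str | None = None) -> pd.Series:
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: condition map needs two columns")
    df = df.iloc[:, :2]
    # tolerate a header row such as "sample_id<TAB>condition"
    if df.iloc[0, 0].lower() in {"sample", "sample_id", "id"}:
        df = df.iloc[1:]
    ser = pd.Series(df.iloc[:, 1].values, index=pd.Index(df.iloc[:, 0], name="sample_id"))
    if ser.index.has_duplicates:
        dups = ser.index[ser.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: samples listed more than once: {dups[:10]}")
    return ser


@dataclass
class ModuleAssignment:
    """Gene → module labels, with ``grey`` reserved for unassigned genes."""

    labels: pd.Series

    def __post_init__(self) -> None:
        if isinstance(self.labels, Mapping):
            self.labels = pd.Series(self.labels)
        self.labels = self.labels.astype(str)
        _check_unique(self.labels.index, "gene ids")

    @property
    def gene_ids(self) -> pd.Index:
        return self.labels.index

    @property
    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def modules(self, include_unassigned: bool = False) -> list[str]:
        """Module labels ordered by descending size (ties by label)."""
        sizes = self.module_sizes
        labels = sorted(sizes.index, key=lambda m: (-sizes[m], m))
        if not include_unassigned:
            labels = [m for m in labels if m != UNASSIGNED]
        return labels

    def genes_in(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]

    def to_file(self, path, sep: str = "\t") -> None:
        self.labels.rename("module_label").rename_axis("gene_id").to_csv(path, sep=sep)

    @classmethod
    def from_file(cls, path, sep: str | None = None) -> "ModuleAssignment":
        sep = sep or _sniff_sep(path)
        df = pd.read_csv(path, sep=sep, dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: module file needs two columns")
        return cls(pd.Series(df.iloc[:, 1].values, index=pd.Index(df.iloc[:, 0])))
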