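"""Core in-memory containers for two-phenotype expression experiments.

The central object is :class:`ExpressionDataset`: a genes x samples matrix of
(assumed log-scale) expression values, a unique gene identifier per row and a
binary phenotype label per column.  Group 1 is the first label encountered in
the label vector, which matters for direction-sensitive statistics such as the
rank sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DatasetError(ValueError):
    """Raised when an expression dataset violates its invariants."""


@dataclass
class ExpressionDataset:
    """Expression matrix with sample phenotypes.

    Parameters
    ----------
    values : ndarray, shape (n_genes, n_samples)
        Expression intensities, assumed already normalised / log-transformed.
    gene_ids : sequence of str
        One unique identifier per row.
    labels : sequence
        Phenotype per sample; exactly two distinct values.  The first label
        encountered defines group 1 (conventionally the control group).
    """

    values: np.ndarray
    gene_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise DatasetError("expression values must be a 2-D matrix")
        if self.gene_ids.shape[0] != self.values.shape[0]:
            raise DatasetError(
                f"{self.gene_ids.shape[0]} gene ids for {self.values.shape[0]} rows"
            )
        if self.labels.shape[0] != self.values.shape[1]:
            raise DatasetError(
                f"{self.labels.shape[0]} labels for {self.values.shape[1]} samples"
            )
        if any(lab is None or (isinstance(lab, float) and np.isnan(lab)) for lab in self.labels):
            raise DatasetError("missing phenotype labels are not allowed")
        classes = list(dict.fromkeys(self.labels))  # preserves encounter order
        if len(classes) != 2:
            raise DatasetError(
                f"exactly two phenotype classes required, got {len(classes)}: {classes}"
            )
        self._classes = classes
        ids, counts = np.unique(self.gene_ids.astype(str), return_counts=True)
        if (counts > 1).any():
            dup = ids[counts > 1][:5]
            raise DatasetError(f"duplicate gene ids (collapse probes first): {list(dup)}")

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> tuple:
        """(group-1 label, group-2 label) in encounter order."""
        return tuple(self._classes)

    @property
    def group1_mask(self) -> np.ndarray:
        return self.labels == self._classes[0]

    @property
    def group2_mask(self) -> np.ndarray:
        return self.labels == self._classes[1]

    @property
    def n1(self) -> int:
        return int(self.group1_mask.sum())

    @property
    def n2(self) -> int:
        return int(self.group2_mask.sum())

    def group_values(self) -> tuple[np.ndarray, np.ndarray]:
        """(genes x n1, genes x n2) sub-matrices."""
        return self.values[:, self.group1_mask], self.values[:, self.group2_mask]

    def with_labels(self, labels) -> "ExpressionDataset":
        """Same matrix under a new phenotype assignment (used by permutation)."""
        return ExpressionDataset(self.values, self.gene_ids, np.asarray(labels, dtype=object))

    def subset_samples(self, idx) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return ExpressionDataset(self.values[:, idx], self.gene_ids, self.labels[idx])


@dataclass
class GroupSummary:
    """Per-gene sufficient statistics for the two phenotype groups.

    Sample standard deviations use the n-1 denominator.  For a group of a
    single sample the standard deviation is undefined and stored as NaN;
    metrics that need it refuse to run (mean-based ones do not).
    """

    mean1: np.ndarray
    mean2: np.ndarray
    sd1: np.ndarray
    sd2: np.ndarray
    n1: int
    n2: int

    @property
    def diff(self) -> np.ndarray:
        return self.mean1 - self.mean2


def group_summaries(dataset: ExpressionDataset) -> GroupSummary:
    """Compute per-group means and standard deviations for every gene."""
    x1, x2 = dataset.group_values()
    n1, n2 = x1.shape[1], x2.shape[1]
    sd1 = x1.std(axis=1, ddof=1) if n1 > 1 else np.full(dataset.n_genes, np.nan)
    sd2 = x2.std(axis=1, ddof=1) if n2 > 1 else np.full(dataset.n_genes, np.nan)
    return GroupSummary(
        mean1=x1.mean(axis=1),
        mean2=x2.mean(axis=1),
        sd1=sd1,
        sd2=sd2,
        n1=n1,
        n2=n2,
    )


@dataclass
class GeneSet:
    """A named collection of member gene identifiers (duplicates removed)."""

    set_id: str
    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.members = frozenset(str(m) for m in self.members)

    def __len__(self) -> int:
        return len(self.members)

    def intersect(self, gene_ids) -> "GeneSet":
        return GeneSet(self.set_id, self.name, self.members & {str(g) for g in gene_ids})


@dataclass
class RankVector:
    """Per-gene ranking-metric values together with the induced gene order.

    ``order`` indexes genes from strongest to weakest (descending metric
    value); ties are broken by gene identifier so the sort is reproducible
    across runs and platforms.
    """

    metric_name: str
    gene_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.values.shape != self.gene_ids.shape:
            raise ValueError("values and gene_ids length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in ranking metric {self.metric_name!r}")

    @property
    def order(self) -> np.ndarray:
        """Indices sorting genes by descending value; ties by gene id."""
        ids = self.gene_ids.astype(str)
        # lexsort: last key is primary
        return np.lexsort((ids, -self.values))

    def sorted_values(self) -> np.ndarray:
        return self.values[self.order]

    def sorted_gene_ids(self) -> np.ndarray:
        return self.gene_ids[self.order]
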