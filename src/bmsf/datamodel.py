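"""Core data containers for two-class expression datasets and selection results.

The internal orientation is fixed: rows are samples, columns are genes.
Class labels are stored as +1/-1 integers; the mapping back to the user's
class names is kept so reports remain meaningful.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class DatasetError(ValueError):
    """Raised when an expression dataset violates a structural invariant."""


@dataclass(frozen=True)
class ExpressionDataset:
    """An N-samples x G-genes expression matrix with binary class labels.

    Parameters
    ----------
    matrix : ndarray of shape (N, G)
        Real-valued expression measurements; no missing or non-finite entries.
    sample_ids : sequence of str
        N unique sample identifiers.
    gene_ids : sequence of str
        G unique gene identifiers, one per column.
    labels : ndarray of shape (N,)
        +1 / -1 class codes.
    class_names : (str, str)
        Original names of the (positive, negative) class.
    """

    matrix: np.ndarray
    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    labels: np.ndarray
    class_names: tuple[str, str] = ("+", "-")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise DatasetError(f"expression matrix must be 2-D, got shape {m.shape}")
        bad = ~np.isfinite(m)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise DatasetError(
                f"non-finite expression value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        n, g = m.shape
        if len(self.sample_ids) != n:
            raise DatasetError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.gene_ids) != g:
            raise DatasetError(f"{len(self.gene_ids)} gene ids for {g} columns")
        if len(set(self.gene_ids)) != g:
            raise DatasetError("gene identifiers are not unique")
        if labels.shape != (n,):
            raise DatasetError(f"labels shape {labels.shape} does not match N={n}")
        classes = np.unique(labels)
        if not np.array_equal(classes, [-1, 1]):
            raise DatasetError(
                f"labels must contain exactly the two codes +1/-1, got {classes.tolist()}"
            )
        # Stratified 5-fold CV needs a handful of samples per class; tiny
        # classes are allowed in the container (e.g. for I/O round-trips)
        # but flagged here, and rejected at cross-validation time.
        for cls in (1, -1):
            if int(np.sum(labels == cls)) < 4:
                warnings.warn(
                    f"class {cls:+d} has fewer than 4 samples; "
                    "cross-validated scoring will be unavailable"
                )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def submatrix(self, gene_indices: Sequence[int]) -> np.ndarray:
        """Expression values restricted to the given gene columns."""
        return self.matrix[:, list(gene_indices)]

    def gene_names(self, gene_indices: Sequence[int]) -> list[str]:
        return [self.gene_ids[i] for i in gene_indices]


@dataclass(frozen=True)
class GeneSubset:
    """An ordered set of column indices into an :class:`ExpressionDataset`."""

    indices: tuple[int, ...]

    def __init__(self, indices: Sequence[int]):
        idx = tuple(int(i) for i in indices)
        if len(set(idx)) != len(idx):
            raise ValueError("gene subset indices must be unique")
        if any(i < 0 for i in idx):
            raise ValueError("gene subset indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def __contains__(self, i: int) -> bool:
        return i in self.indices

    def validate_against(self, dataset: ExpressionDataset) -> None:
        if self.indices and max(self.indices) >= dataset.n_genes:
            raise ValueError(
                f"gene index {max(self.indices)} out of range for G={dataset.n_genes}"
            )

    @classmethod
    def all_genes(cls, dataset: ExpressionDataset) -> "GeneSubset":
        return cls(range(dataset.n_genes))


@dataclass
class SelectionResult:
    """Final output of the selection pipeline.

    ``genes`` holds the surviving gene identifiers in order of importance
    (most important first); ``p_values`` aligns with ``genes``.
    """

    genes: list[str] = field(default_factory=list)
    indices: list[int] = field(default_factory=list)
    p_values: list[float] = field(default_factory=list)
    round_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.p_values and len(self.p_values) != len(self.genes):
            raise ValueError("p_values must align with genes")
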