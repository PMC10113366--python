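"""Shared containers and the canonical edge indexing.

Every stage of the pipeline refers to functional connections (FCs, edges)
through one canonical ordering: the strict upper triangle of the region ×
region matrix, traversed row-major, 0-based.  For R regions this yields
E = R(R-1)/2 edges; edge id e maps to the region pair (i, j) with i < j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "n_edges",
    "edge_pairs",
    "edge_id",
    "FCDataset",
]


def n_edges(n_regions: int) -> int:
    """Number of distinct region pairs: R(R-1)/2."""
    if n_regions < 2:
        raise ValueError(f"need at least 2 regions, got {n_regions}")
    return n_regions * (n_regions - 1) // 2


def edge_pairs(n_regions: int) -> np.ndarray:
    """(E, 2) array of region pairs in canonical (row-major upper-triangle) order."""
    iu = np.triu_indices(n_regions, k=1)
    return np.column_stack(iu)


def edge_id(i: int, j: int, n_regions: int) -> int:
    """Canonical edge id of the pair (i, j), i < j < n_regions."""
    if not (0 <= i < j < n_regions):
        raise ValueError(f"require 0 <= i < j < n_regions, got ({i}, {j}, {n_regions})")
    return i * n_regions - i * (i + 1) // 2 + (j - i - 1)


@dataclass
class FCDataset:
    """A cohort's FC feature matrix plus the covariates the analysis uses.

    Attributes
    ----------
    X : (n_subjects, E) array
        Edge values in canonical order, on the Fisher-z scale unless
        ``scale`` says otherwise.
    y : (n_subjects,) int array
        Diagnosis labels, 1 = StD (positive class), 0 = healthy control.
    age, sex : (n_subjects,) arrays
        Nuisance covariates; sex coded 1 = male, 0 = female.
    """

    X: np.ndarray
    y: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    subject_ids: list[str]
    n_regions: int
    scale: str = "fisher_z"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        n = self.X.shape[0]
        if not (len(self.y) == len(self.age) == len(self.sex) == len(self.subject_ids) == n):
            raise ValueError("inconsistent subject counts across fields")
        if self.X.shape[1] != n_edges(self.n_regions):
            raise ValueError(
                f"X has {self.X.shape[1]} columns but {self.n_regions} regions "
                f"imply {n_edges(self.n_regions)} edges"
            )
        if set(np.unique(self.y)) - {0, 1}:
            raise ValueError("labels must be 0 (HC) or 1 (StD)")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "FCDataset":
        idx = np.asarray(idx)
        return FCDataset(
            X=self.X[idx],
            y=self.y[idx],
            age=np.asarray(self.age)[idx],
            sex=np.asarray(self.sex)[idx],
            subject_ids=[self.subject_ids[k] for k in np.atleast_1d(idx)],
            n_regions=self.n_regions,
            scale=self.scale,
        )
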