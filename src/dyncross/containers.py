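"""Core in-memory container for time-course expression data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExpressionTimeCourse", "CONDITIONS"]

#: Canonical condition labels: unstimulated control, Sonic Hedgehog only,
#: EGF only, and co-stimulation.
CONDITIONS = ("CTRL", "SHH", "EGF", "EGF_SHH")


@dataclass
class ExpressionTimeCourse:
    """Per-condition expression matrix: genes x time points x replicates.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row.
    condition : str
        Condition label, conventionally one of ``CONDITIONS``.
    time_grid : ndarray, shape (K,)
        Sampling times in hours, strictly increasing, starting at 0.
    values : ndarray, shape (n, K, N)
        Expression values for n genes at K time points in N replicates.
    """

    gene_ids: list[str]
    condition: str
    time_grid: np.ndarray
    values: np.ndarray
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValueError("values must be a genes x time x replicates array")
        n, k, _ = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n} rows")
        if self.time_grid.size != k:
            raise ValueError(f"time grid has {self.time_grid.size} points for {k} columns")
        if np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time grid must be strictly increasing")
        seen = set()
        for g in self.gene_ids:
            if g in seen:
                raise ValueError(f"duplicate gene id: {g!r}")
            seen.add(g)
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self._index[gene_id]]

    def profile(self, gene_id: str) -> np.ndarray:
        """Single-replicate profile for a gene; requires N == 1."""
        if self.n_replicates != 1:
            raise ValueError("profile() requires replicate-collapsed data (N=1)")
        return self.values[self._index[gene_id], :, 0]

    def profiles(self) -> np.ndarray:
        """(n, K) matrix of profiles; requires N == 1."""
        if self.n_replicates != 1:
            raise ValueError("profiles() requires replicate-collapsed data (N=1)")
        return self.values[:, :, 0]

    def subset(self, gene_ids) -> "ExpressionTimeCourse":
        idx = [self._index[g] for g in gene_ids]
        return ExpressionTimeCourse(
            gene_ids=list(gene_ids),
            condition=self.condition,
            time_grid=self.time_grid.copy(),
            values=self.values[idx].copy(),
        )

    def copy_with(self, values: np.ndarray, condition: str | None = None) -> "ExpressionTimeCourse":
        return ExpressionTimeCourse(
            gene_ids=list(self.gene_ids),
            condition=self.condition if condition is None else condition,
            time_grid=self.time_grid.copy(),
            values=np.asarray(values, dtype=float),
        )
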