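"""Vectorised Spearman rank correlation on short time-course curves.

Spearman's rho is the pipeline's universal similarity measure between
temporal profiles (clustering, module matching, condition comparisons and
the cross-talk rules all use it).  Ranks use average tie handling; a curve
with zero rank variance (constant profile) has undefined rho, reported as
NaN and handled by the caller.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["spearman_pairwise", "spearman_matrix", "spearman"]


def _centered_ranks(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    r = rankdata(X, axis=1)
    r = r - r.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(r**2, axis=1))
    return r, norms


def spearman_pairwise(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rho between matching rows of two (n, k) arrays."""
    rx, nx = _centered_ranks(X)
    ry, ny = _centered_ranks(Y)
    if rx.shape != ry.shape:
        raise ValueError("arrays must have matching shapes")
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.sum(rx * ry, axis=1) / (nx * ny)
    rho[(nx == 0) | (ny == 0)] = np.nan
    return rho


def spearman_matrix(X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """All-pairs Spearman rho between rows of X (n, k) and Y (m, k)."""
    rx, nx = _centered_ranks(X)
    if Y is None:
        ry, ny = rx, nx
    else:
        ry, ny = _centered_ranks(Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx @ ry.T) / np.outer(nx, ny)
    rho[nx == 0, :] = np.nan
    rho[:, ny == 0] = np.nan
    return rho


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho between two curves; NaN if either is constant."""
    return float(spearman_pairwise(np.asarray(x)[None, :], np.asarray(y)[None, :])[0])
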