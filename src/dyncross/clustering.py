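"""Iterative hierarchical clustering (IHC) of DRGs into gene response modules.

Genes with similar temporal patterns are grouped into gene response
modules (GRMs).  The algorithm:

1. initial average-linkage hierarchical clustering with distance
   ``1 - Spearman rho``, tree cut at ``1 - rho_threshold``;
2. iterate until stable (or ``max_iter``):
   a. merge any two clusters whose mean curves correlate at or above the
      threshold (best pair first);
   b. reassign every gene to the cluster whose mean curve it correlates
      with best, provided that correlation reaches the threshold —
      otherwise the gene becomes a singleton;
   c. recompute mean curves.

Modules are numbered by size descending, so GRM1 is always the largest
module.  The similarity threshold defaults to 0.7, the pipeline's global
similarity cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .rankstats import spearman_matrix

__all__ = ["GRM", "ModulePairing", "ihc_cluster", "large_size_grms", "match_modules"]


@dataclass
class GRM:
    """A gene response module: genes sharing one temporal pattern."""

    module_id: int  # 1-based, by size descending (1 = largest)
    condition: str
    members: list[str]
    mean_curve: np.ndarray

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def name(self) -> str:
        return f"GRM{self.module_id}"


@dataclass
class ModulePairing:
    """Greedy cross-condition pairing of modules by mean-curve similarity."""

    pairs: list[tuple[int, int, float]]  # (module_id_a, module_id_b, spearman rho)


def _labels_to_clusters(labels: np.ndarray) -> list[np.ndarray]:
    return [np.where(labels == lab)[0] for lab in np.unique(labels)]


def _mean_curves(profiles: np.ndarray, clusters: list[np.ndarray]) -> np.ndarray:
    return np.vstack([profiles[idx].mean(axis=0) for idx in clusters])


def ihc_cluster(
    profiles: np.ndarray,
    gene_ids: list[str],
    condition: str = "",
    rho_threshold: float = 0.7,
    max_iter: int = 100,
) -> list[GRM]:
    """Cluster temporal profiles into GRMs with the IHC procedure."""
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if not (0 < rho_threshold < 1):
        raise ValueError("rho_threshold must lie in (0, 1)")
    if profiles.shape[0] != len(gene_ids):
        raise ValueError("one gene id per profile required")
    if not np.all(np.isfinite(profiles)):
        raise ValueError("profiles must be finite")
    n = profiles.shape[0]
    if n == 0:
        return []
    if n == 1:
        return [GRM(1, condition, [gene_ids[0]], profiles[0].copy())]

    # Undefined rho (constant profile) is mapped to -1: a flat profile
    # certifies similarity to nothing and gravitates to a singleton.
    sim = spearman_matrix(profiles)
    sim = np.where(np.isfinite(sim), sim, -1.0)
    np.fill_diagonal(sim, 1.0)
    dist = np.clip(1.0 - sim, 0.0, 2.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=1.0 - rho_threshold, criterion="distance")
    clusters = _labels_to_clusters(labels)

    assignment = np.empty(n, dtype=int)
    for ci, idx in enumerate(clusters):
        assignment[idx] = ci

    for _ in range(max_iter):
        means = _mean_curves(profiles, clusters)
        # (a) merge clusters whose mean curves are mutually similar.
        while len(clusters) > 1:
            mm = spearman_matrix(means)
            mm = np.where(np.isfinite(mm), mm, -1.0)
            np.fill_diagonal(mm, -np.inf)
            i, j = np.unravel_index(np.argmax(mm), mm.shape)
            if mm[i, j] < rho_threshold:
                break
            lo, hi = min(i, j), max(i, j)
            clusters[lo] = np.concatenate([clusters[lo], clusters[hi]])
            del clusters[hi]
            means = _mean_curves(profiles, clusters)
        # (b) reassign each gene to its best-correlated mean (ties to the
        # smaller cluster index); below-threshold genes become singletons.
        gene_rho = spearman_matrix(profiles, means)
        gene_rho = np.where(np.isfinite(gene_rho), gene_rho, -1.0)
        best = np.argmax(gene_rho, axis=1)
        best_rho = gene_rho[np.arange(n), best]
        new_assignment = np.where(best_rho >= rho_threshold, best, -1)
        # (c) rebuild clusters; each unassigned gene forms a singleton.
        new_clusters = [np.where(new_assignment == ci)[0] for ci in range(len(clusters))]
        new_clusters = [idx for idx in new_clusters if idx.size > 0]
        for g in np.where(new_assignment == -1)[0]:
            new_clusters.append(np.array([g]))
        new_vec = np.empty(n, dtype=int)
        for ci, idx in enumerate(new_clusters):
            new_vec[idx] = ci
        converged = _same_partition(assignment, new_vec)
        clusters = new_clusters
        assignment = new_vec
        if converged:
            break

    clusters.sort(key=lambda idx: (-idx.size, min(gene_ids[g] for g in idx)))
    return [
        GRM(
            module_id=ci + 1,
            condition=condition,
            members=sorted(gene_ids[g] for g in idx),
            mean_curve=profiles[idx].mean(axis=0),
        )
        for ci, idx in enumerate(clusters)
    ]


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label vectors induce the same partition."""
    pairs = {}
    for x, y in zip(a.tolist(), b.tolist()):
        if x in pairs and pairs[x] != y:
            return False
        pairs[x] = y
    return len(set(pairs.values())) == len(pairs)


def large_size_grms(grms: list[GRM], min_size: int = 70) -> list[GRM]:
    """Large-size GRMs: modules with ``min_size`` or more members
    (boundary inclusive), order preserved."""
    return [g for g in grms if g.size >= min_size]


def match_modules(grms_a: list[GRM], grms_b: list[GRM]) -> ModulePairing:
    """Greedy maximum-similarity pairing of two module lists.

    Repeatedly pairs the unmatched (a, b) with the highest Spearman rho
    between mean curves until one list is exhausted.  Pairs involving a
    constant mean curve (undefined rho) are formed last and report NaN.
    """
    if not grms_a or not grms_b:
        return ModulePairing(pairs=[])
    ma = np.vstack([g.mean_curve for g in grms_a])
    mb = np.vstack([g.mean_curve for g in grms_b])
    rho = spearman_matrix(ma, mb)
    score = np.where(np.isfinite(rho), rho, -2.0)
    pairs = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for _ in range(min(len(grms_a), len(grms_b))):
        masked = score.copy()
        masked[list(used_a), :] = -np.inf
        masked[:, list(used_b)] = -np.inf
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if not np.isfinite(masked[i, j]):
            break
        pairs.append((grms_a[i].module_id, grms_b[j].module_id, float(rho[i, j])))
        used_a.add(int(i))
        used_b.add(int(j))
    return ModulePairing(pairs=pairs)
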