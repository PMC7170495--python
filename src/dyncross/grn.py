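"""Gene regulatory network inference among modules via sparse linear ODEs.

Module dynamics are modelled by rate equations: the instantaneous rate of
change of module q is a linear combination of the expression levels of
all modules,

    dM_q/dt = a_{0,q} + sum_p a_{p,q} M_p ,

with only a few regulators per target expected to be active.  Fitting is
two-stage, per target module: (1) model selection decides which
coefficients are non-zero — candidate supports (exhaustive best-subset
for small module counts, the lasso path otherwise) scored by an extended
BIC with backward t-pruning; (2) ordinary least squares refit restricted
to the selected support.  The
response dM_q/dt is the analytic derivative of the smoothing-spline fit
of the module mean curve — no finite differencing of raw values.  A
positive coefficient is read as stimulation, a negative one as
inhibition; self-regulation (diagonal entries) is allowed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.linear_model import lars_path

from .smoothing import SplineSmoother

__all__ = ["GRNModel", "estimate_derivatives", "fit_grn", "network_from_model"]

logger = logging.getLogger(__name__)

#: Refit coefficients with magnitude below this are numerical noise.
COEF_FLOOR = 1e-8


@dataclass
class GRNModel:
    """Fitted sparse linear-ODE network over modules.

    ``coefficients[p, q]`` is the effect of module p on the rate of change
    of module q; entries are zero wherever ``support`` is False.
    """

    module_ids: list
    intercepts: np.ndarray  # (Q,)
    coefficients: np.ndarray  # (Q, Q)
    support: np.ndarray  # (Q, Q) bool


def _smooth_curves(mean_curves: np.ndarray, time_grid: np.ndarray):
    """Smooth each module mean curve; return fitted values and analytic
    spline derivatives on the grid, both (Q, K)."""
    mean_curves = np.atleast_2d(np.asarray(mean_curves, dtype=float))
    if not np.all(np.isfinite(mean_curves)):
        raise ValueError("module mean curves must be finite")
    smoother = SplineSmoother(time_grid)
    fitted = np.empty_like(mean_curves)
    deriv = np.empty_like(mean_curves)
    for i, y in enumerate(mean_curves):
        fit = smoother.fit(y)
        fitted[i] = fit.fitted
        deriv[i] = fit.derivative()
    return fitted, deriv


def estimate_derivatives(mean_curves: np.ndarray, time_grid: np.ndarray) -> np.ndarray:
    """Instantaneous rates of change of module mean curves on the grid."""
    _, deriv = _smooth_curves(mean_curves, time_grid)
    return deriv


#: Largest per-target support size the selector will consider.
MAX_REGULATORS = 3
#: Exhaustive best-subset search is used up to this many modules; beyond
#: it the lasso path provides the candidate sets.
_EXHAUSTIVE_LIMIT = 12
#: Extended-BIC sparsity weight (penalty 2*gamma*log(C(p, df))); strong
#: control is needed in this K ~ Q regime with correlated module curves.
EBIC_GAMMA = 2.0
#: Post-selection backward pruning drops coefficients with |t| below this.
T_PRUNE = 2.0
#: ... and regressors whose contribution sd is below this fraction of the
#: response sd (practical-significance floor).
MIN_EFFECT = 0.05
#: Regression rows dropped at each end of the time grid: the spline
#: derivative is least reliable at the window boundaries.
BOUNDARY_TRIM = 1


def _rss(xc: np.ndarray, yc: np.ndarray, sub: tuple) -> float:
    beta, *_ = np.linalg.lstsq(xc[:, sub], yc, rcond=None)
    return float(np.sum((yc - xc[:, sub] @ beta) ** 2))


def _candidate_sets(xc, yc, usable, max_k):
    """Best candidate support per size, either exhaustively (small Q) or
    along the lasso (LARS) path."""
    import itertools

    idx = np.where(usable)[0]
    if idx.size <= _EXHAUSTIVE_LIMIT:
        best = {0: (float(yc @ yc), ())}
        for kk in range(1, min(max_k, idx.size) + 1):
            b = (np.inf, ())
            for sub in itertools.combinations(idx, kk):
                r = _rss(xc, yc, sub)
                if r < b[0]:
                    b = (r, sub)
            best[kk] = b
        return best
    scale = xc[:, idx].std(axis=0)
    xs = xc[:, idx] / scale
    _, _, coefs = lars_path(xs, yc, method="lasso")
    best = {0: (float(yc @ yc), ())}
    for j in range(coefs.shape[1]):
        active = np.where(coefs[:, j] != 0)[0]
        kk = active.size
        if kk == 0 or kk > max_k:
            continue
        sub = tuple(idx[active])
        r = _rss(xc, yc, sub)
        if kk not in best or r < best[kk][0]:
            best[kk] = (r, sub)
    return best


def _select_support(X: np.ndarray, y: np.ndarray, max_k: int = MAX_REGULATORS) -> np.ndarray:
    """Per-target support selection.

    Candidate supports of size 0..max_k are scored by an extended BIC
    with the noise variance referenced to the best model at the maximal
    candidate size: RSS/sigma^2 + df*log(K) + 2*gamma*log(C(p, df)).
    Profiling the variance per candidate (the log-RSS form) degenerates
    toward the saturated model when derivatives are nearly noiseless, and
    the fully saturated fit has too few residual df to estimate sigma^2
    honestly — hence the max-candidate-size reference.  The winning
    support is then pruned backward: the refit coefficient with the
    smallest |t| is dropped while it stays below ``T_PRUNE``.
    """
    k, q = X.shape
    xc, yc = X - X.mean(axis=0), y - y.mean()
    usable = xc.std(axis=0) > 1e-12
    support = np.zeros(q, dtype=bool)
    if not usable.any() or yc.std() < 1e-14:
        return support
    max_k = min(max_k, k - 4)
    best = _candidate_sets(xc, yc, usable, max_k)
    top = max(best)
    sigma2 = max(best[top][0] / max(k - top - 1, 1), 1e-12)
    from math import comb, log

    best_score, best_sub = np.inf, ()
    for kk, (rss, sub) in sorted(best.items()):
        score = rss / sigma2 + (kk + 1) * log(k) + 2.0 * EBIC_GAMMA * log(comb(q, kk))
        if score < best_score - 1e-12:
            best_score, best_sub = score, sub
    sub = list(best_sub)
    y_scale = max(float(yc.std()), 1e-300)
    while sub:
        Xs = np.column_stack([np.ones(k), X[:, sub]])
        beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
        resid = y - Xs @ beta
        s2 = float(resid @ resid) / max(k - len(sub) - 1, 1)
        cov = s2 * np.linalg.pinv(Xs.T @ Xs)
        tvals = beta[1:] / np.sqrt(np.maximum(np.diag(cov)[1:], 1e-300))
        # Effect size of regressor j: sd of its contribution relative to
        # the response sd.  Statistically "significant" but practically
        # negligible terms (they absorb smoothing bias in near-noiseless
        # fits) are pruned along with low-|t| ones.
        effects = np.abs(beta[1:]) * X[:, sub].std(axis=0) / y_scale
        weak = np.abs(tvals) < T_PRUNE
        weak |= effects < MIN_EFFECT
        if weak.any():
            order = np.where(weak)[0]
            weakest = int(order[np.argmin(np.abs(tvals)[order])])
            sub.pop(weakest)
        else:
            break
    support[sub] = True
    return support


def fit_grn(
    mean_curves: np.ndarray,
    time_grid: np.ndarray,
    module_ids: list | None = None,
    selector: str = "sparse_bic",
    fixed_support: np.ndarray | None = None,
) -> GRNModel:
    """Fit the sparse linear-ODE network to module mean curves.

    Parameters
    ----------
    mean_curves : (Q, K) array
        One mean curve per module on the common time grid.
    selector : {"sparse_bic", "none"}
        Edge selection strategy: best-subset (exhaustive for small Q,
        lasso-path candidates for large Q) scored by extended BIC with
        backward pruning, or "none" to keep the full support.
    fixed_support : (Q, Q) bool array, optional
        Skip selection and refit on this support (used for diagnostics).
    """
    mean_curves = np.atleast_2d(np.asarray(mean_curves, dtype=float))
    q = mean_curves.shape[0]
    time_grid = np.asarray(time_grid, dtype=float)
    for i in range(q):
        for j in range(i + 1, q):
            if np.array_equal(mean_curves[i], mean_curves[j]):
                raise ValueError(f"modules {i} and {j} have exactly duplicate curves")
    fitted, deriv = _smooth_curves(mean_curves, time_grid)
    rows = slice(BOUNDARY_TRIM, time_grid.size - BOUNDARY_TRIM) \
        if time_grid.size - 2 * BOUNDARY_TRIM >= 6 else slice(None)
    design = fitted.T[rows]  # (K_used, Q)
    deriv_used = deriv[:, rows]
    nondegenerate = design.std(axis=0) > 1e-12
    if nondegenerate.sum() >= 2:
        cond = np.linalg.cond(design[:, nondegenerate])
        if cond > 1e6:
            logger.warning("module curves are nearly collinear (condition number %.3g)", cond)

    support = np.zeros((q, q), dtype=bool)
    coefficients = np.zeros((q, q))
    intercepts = np.zeros(q)
    for target in range(q):
        y = deriv_used[target]
        if fixed_support is not None:
            sel = np.asarray(fixed_support, dtype=bool)[:, target]
        elif selector == "sparse_bic":
            sel = _select_support(design, y)
        elif selector == "none":
            sel = nondegenerate.copy()
        else:
            raise ValueError(f"unknown selector {selector!r}")
        if sel.any():
            Xs = np.column_stack([np.ones(design.shape[0]), design[:, sel]])
            beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
            intercepts[target] = beta[0]
            coef = beta[1:]
            coef[np.abs(coef) < COEF_FLOOR] = 0.0
            coefficients[sel, target] = coef
            support[:, target] = sel & (coefficients[:, target] != 0.0)
            coefficients[~support[:, target], target] = 0.0
        else:
            intercepts[target] = float(y.mean())
            if abs(intercepts[target]) < COEF_FLOOR:
                intercepts[target] = 0.0
    return GRNModel(
        module_ids=list(module_ids) if module_ids is not None else list(range(1, q + 1)),
        intercepts=intercepts,
        coefficients=coefficients,
        support=support,
    )


def network_from_model(model: GRNModel) -> nx.DiGraph:
    """Directed weighted graph: edge p -> q iff the coefficient of module p
    in module q's rate equation was selected.  Self-loops are retained
    here; path-based metrics ignore them downstream."""
    g = nx.DiGraph()
    g.add_nodes_from(model.module_ids)
    q = len(model.module_ids)
    for p in range(q):
        for t in range(q):
            if model.support[p, t]:
                g.add_edge(
                    model.module_ids[p],
                    model.module_ids[t],
                    weight=float(model.coefficients[p, t]),
                    sign=int(np.sign(model.coefficients[p, t])),
                )
    return g
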