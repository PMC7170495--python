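"""Synthetic four-condition time-course studies with known ground truth.

The generator emulates the study design the pipeline targets: four
stimulation conditions (CTRL, SHH, EGF, EGF_SHH), 14 time points over
24 hours, 3 biological replicates, values on the centered log fold-change
scale.  Observed values follow the observation model the analysis assumes:
a smooth per-gene signal plus i.i.d. Gaussian noise with a single variance
shared across genes and replicates.

Planted structure
-----------------
* flat genes: zero signal, pure noise;
* background dynamic genes: one smooth template per module, the same
  template under every condition;
* cross-talk genes: flat under CTRL, template A under SHH, template B
  under EGF, and a third template C under co-stimulation that correlates
  poorly with both A and B — directly instantiating the cross-talk rules;
* co-activation genes: one template under CTRL/SHH/EGF and a dissimilar
  template under co-stimulation only.

All templates are pairwise separable in Spearman correlation so that the
planted modules are recoverable under the pipeline's similarity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .containers import CONDITIONS, ExpressionTimeCourse

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_template_curves",
    "simulate_condition",
    "simulate_study",
    "simulate_linear_ode_modules",
    "write_study",
]

#: Default pairwise Spearman separation enforced between distinct templates.
#: Stricter than the pipeline's 0.7 similarity threshold so that planted
#: modules stay separable after noise.
TEMPLATE_MAX_RHO = 0.5


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the target design: 14 time points over 24 h, three
    replicates.  ``module_amplitude`` is the min-to-max range of each
    template on the log2 fold-change scale (3.0 ~ an 8-fold swing, typical
    of strongly responsive genes and comfortably above the 1.96
    significant-variation cutoff); ``noise_sd`` is the replicate-level
    noise standard deviation on the same scale.
    """

    n_genes: int = 500
    n_dynamic: int = 300
    n_modules: int = 5
    n_timepoints: int = 14
    t_max: float = 24.0
    n_replicates: int = 3
    noise_sd: float = 0.3
    module_amplitude: float = 3.0
    n_crosstalk: int = 0
    n_coactivation: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not (0 <= self.n_dynamic <= self.n_genes):
            raise ValueError("need 0 <= n_dynamic <= n_genes")
        if self.n_crosstalk + self.n_coactivation > self.n_dynamic:
            raise ValueError("n_crosstalk + n_coactivation must not exceed n_dynamic")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_timepoints < 8:
            raise ValueError("at least 8 time points are required for the smoothing F-test")
        if self.n_modules < 1:
            raise ValueError("n_modules must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")

    @property
    def time_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.t_max, self.n_timepoints)


@dataclass
class GroundTruth:
    """Planted structure of a simulated study.

    ``true_curves`` holds the noiseless centered signal of every gene under
    every condition; downstream recovery tests evaluate against it.
    """

    drg_flags: pd.DataFrame  # genes x conditions, bool
    module_labels: dict[str, pd.Series]  # condition -> labels for dynamic genes
    crosstalk_genes: set[str]
    coactivation_genes: set[str]
    true_curves: dict[str, pd.DataFrame]  # condition -> genes x K
    templates: np.ndarray = None
    ode_matrix: np.ndarray | None = None


def _random_smooth_curve(time_grid: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One smooth random curve: a natural cubic spline through a handful of
    random control values, evaluated on the grid."""
    n_ctrl = 6
    ctrl_t = np.linspace(time_grid[0], time_grid[-1], n_ctrl)
    ctrl_y = rng.standard_normal(n_ctrl)
    return CubicSpline(ctrl_t, ctrl_y, bc_type="natural")(time_grid)


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    from .rankstats import spearman

    return spearman(a, b)


def make_template_curves(
    n_modules: int,
    time_grid: np.ndarray,
    amplitude: float,
    seed: int,
    max_rho: float = TEMPLATE_MAX_RHO,
    normalize: str = "range",
    max_tries: int = 5000,
) -> np.ndarray:
    """Draw ``n_modules`` smooth template curves that are mutually separable.

    Each accepted template is centered and rescaled so that its min-to-max
    range (``normalize="range"``) or temporal standard deviation
    (``normalize="sd"``) equals ``amplitude``.  Candidates whose Spearman
    correlation with any accepted template reaches ``max_rho`` are
    redrawn; generation fails after ``max_tries`` rejected candidates.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    if np.any(np.diff(time_grid) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive: flat templates cannot show variation")
    if normalize not in ("range", "sd"):
        raise ValueError("normalize must be 'range' or 'sd'")
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    tries = 0
    while len(accepted) < n_modules:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not draw {n_modules} templates with pairwise Spearman rho "
                f"< {max_rho} within {max_tries} attempts"
            )
        tries += 1
        cand = _random_smooth_curve(time_grid, rng)
        cand = cand - cand.mean()
        scale = np.ptp(cand) if normalize == "range" else cand.std()
        if scale < 1e-12:
            continue
        cand = cand * (amplitude / scale)
        if all(_spearman(cand, other) < max_rho for other in accepted):
            accepted.append(cand)
    return np.vstack(accepted)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_condition(
    config: SimulationConfig,
    templates: np.ndarray,
    assignment: np.ndarray,
    seed: int,
    condition: str = "CTRL",
) -> tuple[ExpressionTimeCourse, pd.DataFrame]:
    """Simulate one condition given per-gene template assignments.

    ``assignment[g]`` is a row index into ``templates`` or -1 for a flat
    gene.  Returns the noisy dataset and the noiseless signal per gene.
    """
    templates = np.atleast_2d(templates)
    assignment = np.asarray(assignment)
    time_grid = config.time_grid
    n, k = config.n_genes, config.n_timepoints
    if assignment.shape != (n,):
        raise ValueError("assignment must have one entry per gene")
    truth = np.zeros((n, k))
    dyn = assignment >= 0
    if dyn.any():
        truth[dyn] = templates[assignment[dyn]]
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, config.noise_sd, size=(n, k, config.n_replicates))
    values = truth[:, :, None] + noise
    ids = _gene_ids(n)
    etc = ExpressionTimeCourse(gene_ids=ids, condition=condition, time_grid=time_grid, values=values)
    return etc, pd.DataFrame(truth, index=ids, columns=time_grid)


def simulate_study(
    config: SimulationConfig,
) -> tuple[dict[str, ExpressionTimeCourse], GroundTruth]:
    """Simulate the full four-condition study with planted structure.

    Cross-talk genes are flat under CTRL, follow one template under SHH,
    a second under EGF and a third, dissimilar to both, under EGF_SHH.
    Co-activation genes share one template under CTRL/SHH/EGF and switch
    to a dissimilar one under EGF_SHH only.  Background dynamic genes keep
    their module template under every condition; remaining genes are flat.
    """
    cfg = config
    time_grid = cfg.time_grid
    n_extra = 5  # A, B, C (cross-talk) + D, E (co-activation)
    templates = make_template_curves(
        cfg.n_modules + n_extra, time_grid, cfg.module_amplitude, seed=cfg.seed
    )
    i_a, i_b, i_c = cfg.n_modules, cfg.n_modules + 1, cfg.n_modules + 2
    i_d, i_e = cfg.n_modules + 3, cfg.n_modules + 4

    n = cfg.n_genes
    ids = _gene_ids(n)
    ct = list(range(cfg.n_crosstalk))
    ca = list(range(cfg.n_crosstalk, cfg.n_crosstalk + cfg.n_coactivation))
    background = list(range(cfg.n_crosstalk + cfg.n_coactivation, cfg.n_dynamic))

    assignments = {c: np.full(n, -1, dtype=int) for c in CONDITIONS}
    for j, g in enumerate(background):
        for c in CONDITIONS:
            assignments[c][g] = j % cfg.n_modules
    for g in ct:
        assignments["SHH"][g] = i_a
        assignments["EGF"][g] = i_b
        assignments["EGF_SHH"][g] = i_c
    for g in ca:
        assignments["CTRL"][g] = i_d
        assignments["SHH"][g] = i_d
        assignments["EGF"][g] = i_d
        assignments["EGF_SHH"][g] = i_e

    seeds = np.random.SeedSequence(cfg.seed).generate_state(len(CONDITIONS)) % (2**31)
    study: dict[str, ExpressionTimeCourse] = {}
    true_curves: dict[str, pd.DataFrame] = {}
    for c, s in zip(CONDITIONS, seeds):
        etc, truth = simulate_condition(cfg, templates, assignments[c], seed=int(s), condition=c)
        study[c] = etc
        true_curves[c] = truth

    drg_flags = pd.DataFrame(
        {c: assignments[c] >= 0 for c in CONDITIONS}, index=ids
    )
    module_labels = {
        c: pd.Series(
            assignments[c][assignments[c] >= 0],
            index=[ids[g] for g in np.where(assignments[c] >= 0)[0]],
        )
        for c in CONDITIONS
    }
    truth = GroundTruth(
        drg_flags=drg_flags,
        module_labels=module_labels,
        crosstalk_genes={ids[g] for g in ct},
        coactivation_genes={ids[g] for g in ca},
        true_curves=true_curves,
        templates=templates,
    )
    return study, truth


def simulate_linear_ode_modules(
    q: int,
    time_grid: np.ndarray | None = None,
    coef_range: tuple[float, float] = (0.5, 1.0),
    noise_sd: float = 0.02,
    seed: int = 0,
):
    """Simulate module mean curves from a planted sparse linear ODE system.

    The system is dM/dt = A^T M where ``A[p, q]`` is the effect of module
    p on the rate of module q, with a couple of regulators per target.
    A generic sparse random A is useless here: from a single trajectory
    its fast modes die immediately and the design of module curves is
    numerically rank-deficient, so no method (and no amount of data at
    this K) could recover the support.  The planted systems are therefore
    built to be identifiable from one trajectory:

    * modules are paired into antisymmetric rotation blocks, one distinct
      (stratified) frequency per block, so the spectrum is purely
      imaginary — every mode persists across the sampling window and the
      distinct frequencies decorrelate the module curves;
    * consecutive blocks are coupled feed-forward (acyclic, hence
      nilpotent: the spectrum is unchanged), giving each module in a
      non-root block exactly two regulators — its rotation partner and
      one upstream module.

    All coefficient magnitudes are uniform in ``coef_range`` with random
    signs on the couplings.  ``q`` must be even.  Gaussian observation
    noise with sd ``noise_sd`` is added to the sampled trajectories.

    Returns ``(noisy_curves, clean_curves, A)`` with curves of shape
    (q, K).
    """
    if q < 2 or q % 2:
        raise ValueError("q must be an even number of modules >= 2")
    if time_grid is None:
        # ~2 periods of the fastest rotation, comfortably resolved by 14
        # samples.
        time_grid = np.linspace(0.0, 12.0, 14)
    time_grid = np.asarray(time_grid, dtype=float)
    rng = np.random.default_rng(seed)
    n_blocks = q // 2
    a = np.zeros((q, q))
    lo, hi = coef_range
    edges = np.linspace(lo, hi, n_blocks + 1)
    freqs = np.array([rng.uniform(edges[j], edges[j + 1]) for j in range(n_blocks)])
    rng.shuffle(freqs)
    for j in range(n_blocks):
        a[2 * j, 2 * j + 1] = freqs[j]
        a[2 * j + 1, 2 * j] = -freqs[j]
    for j in range(1, n_blocks):
        for member in range(2):
            src = 2 * (j - 1) + rng.integers(2)
            a[src, 2 * j + member] = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
    x0 = rng.uniform(1.0, 2.0, size=q) * rng.choice([-1.0, 1.0], size=q)
    sol = solve_ivp(
        lambda _, x: a.T @ x,
        (time_grid[0], time_grid[-1]),
        x0,
        t_eval=time_grid,
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    clean = sol.y  # (q, K)
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    return noisy, clean, a


def write_study(study: dict[str, ExpressionTimeCourse], truth: GroundTruth, out_dir) -> None:
    """Write per-condition TSV tables plus a JSON ground-truth sidecar."""
    import json
    from pathlib import Path

    from .expression_io import write_expression_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cond, etc in study.items():
        write_expression_table(etc, out / f"expression_{cond}.tsv")
    sidecar = {
        "drg_flags": {c: truth.drg_flags[c].astype(int).to_dict() for c in truth.drg_flags},
        "module_labels": {c: s.astype(int).to_dict() for c, s in truth.module_labels.items()},
        "crosstalk_genes": sorted(truth.crosstalk_genes),
        "coactivation_genes": sorted(truth.coactivation_genes),
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
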