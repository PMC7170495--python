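"""Cross-condition comparisons and cross-talk / co-activation screening.

Definitions (all on smoothed, centered fold-change curves):

* *differential activity* between two conditions: the Spearman correlation
  of the two curves is strictly below 0.7.  An undefined correlation
  (constant curve) is treated as differential — a flat curve cannot
  certify similarity — and flagged.
* *significant variation*: the curve's max-minus-min range is at least
  1.96, the two-sided 5% normal critical value on the standardized
  fold-change scale.
* *cross-talk pattern* (all six required): differential SHH vs CTRL;
  significant variation under SHH; differential EGF vs CTRL; significant
  variation under EGF; differential EGF_SHH vs SHH; differential EGF_SHH
  vs EGF.
* *co-activation pattern* (all three required): no differential SHH vs
  CTRL; no differential EGF vs CTRL; differential EGF_SHH vs SHH.

The two patterns are mutually exclusive (their first rules conflict).
Screening is two-stage: module mean curves are classified first, then the
individual genes inside qualifying modules are re-classified, and a gene
keeps a label only when module and gene level agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import GRM
from .containers import CONDITIONS, ExpressionTimeCourse
from .rankstats import spearman, spearman_pairwise
from .smoothing import SplineSmoother

__all__ = [
    "ComparisonTable",
    "CrossTalkRecord",
    "CrossTalkReport",
    "RANGE_THRESHOLD",
    "RHO_THRESHOLD",
    "spearman_between_conditions",
    "bin_correlations",
    "differential_activity",
    "significant_variation",
    "classify_crosstalk",
    "screen_grms",
]

#: Similarity cutoff: rho below this means differential activity.
RHO_THRESHOLD = 0.7
#: Significant-variation cutoff (normal 5% two-sided critical value).
RANGE_THRESHOLD = 1.96

CT_RULES = (
    "diff_SHH_vs_CTRL",
    "var_SHH",
    "diff_EGF_vs_CTRL",
    "var_EGF",
    "diff_EGF_SHH_vs_SHH",
    "diff_EGF_SHH_vs_EGF",
)
CA_RULES = (
    "no_diff_SHH_vs_CTRL",
    "no_diff_EGF_vs_CTRL",
    "diff_EGF_SHH_vs_SHH",
)


@dataclass
class ComparisonTable:
    """Binned per-gene Spearman correlations between two conditions.

    Bins: similar (rho > 0.7), opposite (rho < -0.7), near-zero
    (|rho| < 0.1) and the remainder; they partition the finite values.
    Undefined correlations are counted separately, not binned.
    """

    condition_a: str
    condition_b: str
    rhos: np.ndarray
    counts: dict[str, int]
    n: int
    n_undefined: int

    @property
    def percentages(self) -> dict[str, float]:
        if self.n == 0:
            return {k: float("nan") for k in self.counts}
        return {k: 100.0 * v / self.n for k, v in self.counts.items()}


@dataclass
class CrossTalkRecord:
    """Per-gene (or per-module) evaluation of the classification rules."""

    gene_id: str
    crosstalk_flags: dict[str, bool]
    coactivation_flags: dict[str, bool]
    classification: str  # "crosstalk" | "coactivation" | "neither"
    ranges: dict[str, float] = field(default_factory=dict)
    rhos: dict[str, float] = field(default_factory=dict)
    undefined_rho: bool = False


@dataclass
class CrossTalkReport:
    module_records: list[CrossTalkRecord]
    gene_records: list[CrossTalkRecord]
    crosstalk_genes: list[str]
    coactivation_genes: list[str]
    unevaluable_genes: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.gene_records:
            row = {"gene_id": r.gene_id, "classification": r.classification}
            row.update({f"ct_{k}": v for k, v in r.crosstalk_flags.items()})
            row.update({f"ca_{k}": v for k, v in r.coactivation_flags.items()})
            row.update({f"range_{k}": v for k, v in r.ranges.items()})
            row.update({f"rho_{k}": v for k, v in r.rhos.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def spearman_between_conditions(curves_a: np.ndarray, curves_b: np.ndarray) -> np.ndarray:
    """Per-gene Spearman rho between matching rows of two curve matrices.
    Constant curves yield NaN."""
    return spearman_pairwise(curves_a, curves_b)


def bin_correlations(
    rhos: np.ndarray, condition_a: str = "", condition_b: str = ""
) -> ComparisonTable:
    rhos = np.asarray(rhos, dtype=float)
    finite = rhos[np.isfinite(rhos)]
    similar = int(np.sum(finite > 0.7))
    opposite = int(np.sum(finite < -0.7))
    near_zero = int(np.sum(np.abs(finite) < 0.1))
    other = finite.size - similar - opposite - near_zero
    return ComparisonTable(
        condition_a=condition_a,
        condition_b=condition_b,
        rhos=rhos,
        counts={
            "similar": similar,
            "opposite": opposite,
            "near_zero": near_zero,
            "other": int(other),
        },
        n=int(finite.size),
        n_undefined=int(rhos.size - finite.size),
    )


#: Numerical guard: rank correlations that equal the cutoff exactly in
#: rational arithmetic can land a few ulp below it in floating point; the
#: inequality is strict only beyond this tolerance.
_RHO_EPS = 1e-9


def _diff(curve_a: np.ndarray, curve_b: np.ndarray) -> tuple[bool, float, bool]:
    """(differential?, rho, rho_undefined?)."""
    rho = spearman(curve_a, curve_b)
    if np.isnan(rho):
        return True, rho, True
    return bool(rho < RHO_THRESHOLD - _RHO_EPS), rho, False


def differential_activity(curve_a: np.ndarray, curve_b: np.ndarray) -> bool:
    """True iff the two curves' Spearman rho is strictly below 0.7 (or
    undefined)."""
    return _diff(curve_a, curve_b)[0]


def significant_variation(curve: np.ndarray, threshold: float = RANGE_THRESHOLD) -> bool:
    """True iff the curve's range (max - min) is not smaller than the
    threshold (inclusive)."""
    return bool(np.ptp(np.asarray(curve, dtype=float)) >= threshold)


def classify_crosstalk(
    curves: dict[str, np.ndarray],
    gene_id: str = "",
    differential_mode: str = "rho_or_variation",
) -> CrossTalkRecord:
    """Evaluate the six cross-talk and three co-activation rules for one
    gene's per-condition curves.

    ``differential_mode`` controls what counts as differential activity:

    * ``"rho_or_variation"`` (default): rho below 0.7, or the two curves
      disagree on significant variation.  A statistically flat profile is
      noise on the rank scale — after smoothing it becomes an arbitrary
      gentle trend whose rank correlation with anything is spurious — so
      similarity to it cannot be certified, which matches reading
      "not initially differentially expressed" through the dynamic-gene
      lens.
    * ``"rho"``: the similarity rule alone, rho below 0.7 (with an
      undefined rho of a constant curve treated as differential).
    """
    missing = [c for c in CONDITIONS if c not in curves]
    if missing:
        raise ValueError(f"missing condition(s): {', '.join(missing)}")
    if differential_mode not in ("rho", "rho_or_variation"):
        raise ValueError(f"unknown differential_mode {differential_mode!r}")
    c = {k: np.asarray(v, dtype=float) for k, v in curves.items()}
    any_undef = False
    rhos: dict[str, float] = {}

    def diff(a: str, b: str) -> bool:
        nonlocal any_undef
        d, rho, undef = _diff(c[a], c[b])
        rhos[f"{a}_vs_{b}"] = rho
        any_undef = any_undef or undef
        if differential_mode == "rho_or_variation":
            d = d or (significant_variation(c[a]) != significant_variation(c[b]))
        return d

    d_shh_ctrl = diff("SHH", "CTRL")
    d_egf_ctrl = diff("EGF", "CTRL")
    d_both_shh = diff("EGF_SHH", "SHH")
    d_both_egf = diff("EGF_SHH", "EGF")
    ct = {
        "diff_SHH_vs_CTRL": d_shh_ctrl,
        "var_SHH": significant_variation(c["SHH"]),
        "diff_EGF_vs_CTRL": d_egf_ctrl,
        "var_EGF": significant_variation(c["EGF"]),
        "diff_EGF_SHH_vs_SHH": d_both_shh,
        "diff_EGF_SHH_vs_EGF": d_both_egf,
    }
    ca = {
        "no_diff_SHH_vs_CTRL": not d_shh_ctrl,
        "no_diff_EGF_vs_CTRL": not d_egf_ctrl,
        "diff_EGF_SHH_vs_SHH": d_both_shh,
    }
    if all(ct.values()):
        classification = "crosstalk"
    elif all(ca.values()):
        classification = "coactivation"
    else:
        classification = "neither"
    return CrossTalkRecord(
        gene_id=gene_id,
        crosstalk_flags=ct,
        coactivation_flags=ca,
        classification=classification,
        ranges={k: float(np.ptp(v)) for k, v in c.items()},
        rhos=rhos,
        undefined_rho=any_undef,
    )


def _smoothed_profiles(etc: ExpressionTimeCourse) -> pd.DataFrame:
    smoother = SplineSmoother(etc.time_grid)
    fitted, *_ = smoother.fit_batch(etc.profiles())
    return pd.DataFrame(fitted, index=etc.gene_ids, columns=etc.time_grid)


def screen_grms(
    grms: list[GRM],
    curves_by_condition: dict[str, ExpressionTimeCourse],
    smooth: bool = True,
    differential_mode: str = "rho_or_variation",
) -> CrossTalkReport:
    """Two-stage cross-talk / co-activation screen.

    ``grms`` are the modules clustered under a reference condition
    (conventionally SHH); ``curves_by_condition`` provides every gene's
    centered profile under each of the four conditions.  Stage 1
    classifies each module's per-condition mean curves; stage 2
    re-classifies the individual genes inside qualifying modules.  A gene
    is reported as cross-talk (or co-activation) only when both its module
    and its own curves carry that pattern.  Genes missing under some
    condition are reported as unevaluable, never silently dropped.
    """
    missing = [c for c in CONDITIONS if c not in curves_by_condition]
    if missing:
        raise ValueError(f"missing condition(s): {', '.join(missing)}")
    if smooth:
        prof = {c: _smoothed_profiles(etc) for c, etc in curves_by_condition.items()}
    else:
        prof = {
            c: pd.DataFrame(etc.profiles(), index=etc.gene_ids, columns=etc.time_grid)
            for c, etc in curves_by_condition.items()
        }

    module_records: list[CrossTalkRecord] = []
    gene_records: list[CrossTalkRecord] = []
    crosstalk_genes: list[str] = []
    coactivation_genes: list[str] = []
    unevaluable: list[str] = []
    for grm in grms:
        evaluable = [g for g in grm.members if all(g in prof[c].index for c in CONDITIONS)]
        unevaluable.extend(g for g in grm.members if g not in evaluable)
        if not evaluable:
            continue
        mean_curves = {
            c: prof[c].loc[evaluable].to_numpy().mean(axis=0) for c in CONDITIONS
        }
        mod_rec = classify_crosstalk(mean_curves, gene_id=grm.name,
                                     differential_mode=differential_mode)
        module_records.append(mod_rec)
        if mod_rec.classification == "neither":
            continue
        for g in evaluable:
            rec = classify_crosstalk(
                {c: prof[c].loc[g].to_numpy() for c in CONDITIONS},
                gene_id=g,
                differential_mode=differential_mode,
            )
            gene_records.append(rec)
            if rec.classification == "crosstalk" == mod_rec.classification:
                crosstalk_genes.append(g)
            elif rec.classification == "coactivation" == mod_rec.classification:
                coactivation_genes.append(g)
    return CrossTalkReport(
        module_records=module_records,
        gene_records=gene_records,
        crosstalk_genes=sorted(crosstalk_genes),
        coactivation_genes=sorted(coactivation_genes),
        unevaluable_genes=sorted(set(unevaluable)),
    )
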