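"""Reading, writing and preprocessing of expression time-course tables.

The on-disk format is a plain tab-separated table: first column ``gene_id``,
remaining columns one per (time point, replicate) pair with headers of the
form ``t<hours>_r<replicate>`` (e.g. ``t1.846_r2``).  Preprocessing follows
the study design: replicates are collapsed by their median (robust to
outlying arrays), values are expressed as fold changes relative to the
gene's control baseline at time 0, and each profile is centered by its
temporal mean before smoothing.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .containers import ExpressionTimeCourse

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "median_over_replicates",
    "fold_change_vs_control_t0",
    "center_profiles",
]

logger = logging.getLogger(__name__)

_COL_RE = re.compile(r"^t(?P<time>-?[0-9.]+(?:[eE][+-]?[0-9]+)?)_r(?P<rep>[0-9]+)$")


def write_expression_table(x: ExpressionTimeCourse, path) -> None:
    """Write an ``ExpressionTimeCourse`` as a TSV (replicate-major columns)."""
    cols = {}
    for r in range(x.n_replicates):
        for k, t in enumerate(x.time_grid):
            cols[f"t{t:.17g}_r{r + 1}"] = x.values[:, k, r]
    df = pd.DataFrame(cols, index=pd.Index(x.gene_ids, name="gene_id"))
    # %.17g guarantees exact float64 round trips through the text format
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_expression_table(path, condition: str | None = None) -> ExpressionTimeCourse:
    """Parse a TSV expression table into an ``ExpressionTimeCourse``.

    Raises ``ValueError`` with a descriptive message on malformed headers,
    non-numeric cells or duplicated gene ids.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate gene id(s): {', '.join(map(str, dups))}")
    times_by_rep: dict[int, dict[float, str]] = {}
    for col in df.columns:
        m = _COL_RE.match(col)
        if not m:
            raise ValueError(
                f"{path}: malformed column header {col!r}; expected 't<time>_r<replicate>'"
            )
        rep = int(m.group("rep"))
        times_by_rep.setdefault(rep, {})[float(m.group("time"))] = col
    reps = sorted(times_by_rep)
    time_sets = {rep: tuple(sorted(d)) for rep, d in times_by_rep.items()}
    if len(set(time_sets.values())) != 1:
        raise ValueError(f"{path}: replicates do not share a common time grid")
    time_grid = np.array(time_sets[reps[0]], dtype=float)
    n, k, nrep = df.shape[0], time_grid.size, len(reps)
    values = np.empty((n, k, nrep))
    for j, rep in enumerate(reps):
        for i, t in enumerate(time_grid):
            col = times_by_rep[rep][t]
            try:
                # numpy's str->float64 conversion is correctly rounded
                # (pandas' fast parser can be off by one ulp)
                values[:, i, j] = df[col].to_numpy(dtype=str).astype(float)
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: non-numeric value in column {col!r}: {exc}") from exc
    if not np.all(np.isfinite(values)):
        # Per-cell gaps are tolerated (median of present replicates); a gene
        # missing a time point in every replicate cannot be smoothed.
        all_missing = np.all(~np.isfinite(values), axis=2)
        bad = np.where(all_missing.any(axis=1))[0]
        if bad.size:
            dropped = [df.index[i] for i in bad]
            logger.warning("dropping %d gene(s) with fully missing time points: %s",
                           len(dropped), ", ".join(map(str, dropped[:10])))
            keep = np.setdiff1d(np.arange(n), bad)
            df = df.iloc[keep]
            values = values[keep]
    logger.info("read %d genes x %d time points x %d replicates from %s",
                values.shape[0], k, nrep, path)
    return ExpressionTimeCourse(
        gene_ids=[str(g) for g in df.index],
        condition=condition or "",
        time_grid=time_grid,
        values=values,
    )


def median_over_replicates(x: ExpressionTimeCourse) -> ExpressionTimeCourse:
    """Collapse replicates to their per-gene, per-time median (N becomes 1).

    Cells missing in some replicates use the median of the present ones.
    """
    med = np.nanmedian(x.values, axis=2)
    return x.copy_with(med[:, :, None])


def fold_change_vs_control_t0(
    x: ExpressionTimeCourse,
    control: ExpressionTimeCourse,
    log2: bool = True,
) -> ExpressionTimeCourse:
    """Express values as fold change over the control baseline at time 0.

    The baseline for gene g is the control value at the first time point
    (replicate-collapsed if needed).  By default the log2 ratio is returned
    so that up- and down-regulation are treated symmetrically; ``log2=False``
    gives the raw ratio.
    """
    if list(x.gene_ids) != list(control.gene_ids):
        raise ValueError("gene sets of data and control must be identical and aligned")
    ctrl_vals = control.values
    baseline = np.nanmedian(ctrl_vals[:, 0, :], axis=1)
    bad = ~(baseline > 0)
    if np.any(bad):
        offenders = [g for g, b in zip(x.gene_ids, bad) if b]
        raise ValueError(
            "control baseline at t=0 must be positive; offending gene(s): "
            + ", ".join(offenders[:20])
        )
    ratio = x.values / baseline[:, None, None]
    out = np.log2(ratio) if log2 else ratio
    return x.copy_with(out)


def center_profiles(x: ExpressionTimeCourse) -> ExpressionTimeCourse:
    """Subtract each gene's temporal mean (the mu_ij centering)."""
    if x.n_replicates != 1:
        raise ValueError("center_profiles expects replicate-collapsed data (N=1)")
    vals = x.values[:, :, 0]
    centered = vals - vals.mean(axis=1, keepdims=True)
    return x.copy_with(centered[:, :, None])
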