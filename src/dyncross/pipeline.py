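"""End-to-end orchestration of the dynamic-expression analysis.

Stage order mirrors the analysis design: preprocessing -> DRG detection
per condition -> top-k selection -> module clustering -> large-module
filter and cross-condition matching -> ODE network inference -> network
statistics and important modules -> condition comparison tables ->
cross-talk screen.  Every stage writes plain TSV artifacts plus a
deterministic log, so identical config + seed reproduce byte-identical
output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, crosstalk, drg, grn, netstats
from .containers import CONDITIONS, ExpressionTimeCourse
from .expression_io import (
    center_profiles,
    fold_change_vs_control_t0,
    median_over_replicates,
    read_expression_table,
)

__all__ = ["PipelineConfig", "run_all", "summarize", "percent_increase"]


def percent_increase(reference: float, value: float) -> float:
    """Percent increase of ``value`` over ``reference`` (e.g. growth in the
    number of dynamic genes after stimulation)."""
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * (value - reference) / reference


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run."""

    inputs: dict[str, str] = field(default_factory=dict)  # condition -> TSV path
    fold_change: bool = False  # apply fold-change vs CTRL t0 (raw-scale inputs)
    log2: bool = True
    alpha: float = 0.05
    mtc: str = "bh"
    drg_method: str = "permutation"
    n_permutations: int = 199
    top_k: int = 3000
    rho_threshold: float = 0.7
    min_module_size: int = 70
    importance_mode: str = "top_k"
    importance_k: int = 20
    reference_condition: str = "SHH"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def validate_inputs(self) -> None:
        for cond in CONDITIONS:
            if cond not in self.inputs:
                raise ValueError(f"missing input path for condition {cond}")
            p = Path(self.inputs[cond])
            if not p.exists():
                raise ValueError(f"input file for condition {cond} does not exist: {p}")


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def _preprocess(study: dict[str, ExpressionTimeCourse], cfg: PipelineConfig):
    collapsed = {c: median_over_replicates(x) for c, x in study.items()}
    if cfg.fold_change:
        control = collapsed["CTRL"]
        collapsed = {
            c: fold_change_vs_control_t0(x, control, log2=cfg.log2)
            for c, x in collapsed.items()
        }
    return {c: center_profiles(x) for c, x in collapsed.items()}


def run_all(
    config: PipelineConfig,
    out_dir,
    study: dict[str, ExpressionTimeCourse] | None = None,
) -> Path:
    """Execute every stage and write artifacts under ``out_dir``.

    ``study`` may be supplied in memory (e.g. straight from the synthetic
    generator); otherwise the configured input tables are read.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = ["# pipeline run", "# parameters:"]
    cfg_dict = asdict(config)
    for k in sorted(cfg_dict):
        log_lines.append(f"#   {k} = {cfg_dict[k]!r}")

    if study is None:
        config.validate_inputs()
        study = {c: read_expression_table(config.inputs[c], condition=c) for c in CONDITIONS}
    missing = [c for c in CONDITIONS if c not in study]
    if missing:
        raise ValueError(f"study is missing condition(s): {', '.join(missing)}")

    stage = "preprocess"
    try:
        centered = _preprocess(study, config)
        for c in CONDITIONS:
            log_lines.append(f"{stage}: {c}: {centered[c].n_genes} genes")

        stage = "drg"
        records: dict[str, list[drg.DRGRecord]] = {}
        topk: dict[str, list[drg.DRGRecord]] = {}
        for c in CONDITIONS:
            recs = drg.detect_drgs(
                centered[c],
                alpha=config.alpha,
                mtc=config.mtc,
                method=config.drg_method,
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
            records[c] = recs
            topk[c] = drg.top_k_by_fratio(recs, k=config.top_k)
            df = pd.DataFrame(
                [
                    {
                        "gene_id": r.gene_id,
                        "f_ratio": r.f_ratio,
                        "p": r.p_value,
                        "p_adj": r.p_adj,
                        "iqr": r.iqr,
                        "is_drg": r.is_drg,
                        "rank": r.rank,
                    }
                    for r in recs
                ]
            )
            _write(df, out / "01_drg" / f"{c}.tsv", index=False)
            log_lines.append(
                f"drg: {c}: {sum(r.is_drg for r in recs)} DRGs of {len(recs)} genes; "
                f"top-k kept {len(topk[c])}"
            )

        stage = "cluster"
        grms: dict[str, list[clustering.GRM]] = {}
        for c in CONDITIONS:
            genes = [r.gene_id for r in topk[c]]
            sub = centered[c].subset(genes) if genes else None
            mods = (
                clustering.ihc_cluster(
                    sub.profiles(), genes, condition=c, rho_threshold=config.rho_threshold
                )
                if genes
                else []
            )
            grms[c] = mods
            members = pd.DataFrame(
                [(m.name, g) for m in mods for g in m.members],
                columns=["module", "gene_id"],
            )
            _write(members, out / "03_grm" / f"{c}_members.tsv", index=False)
            means = pd.DataFrame(
                {m.name: m.mean_curve for m in mods},
                index=pd.Index(centered[c].time_grid, name="time"),
            )
            _write(means, out / "03_grm" / f"{c}_means.tsv")
            log_lines.append(
                f"cluster: {c}: {len(mods)} GRMs; "
                f"{len(clustering.large_size_grms(mods, config.min_module_size))} of size >= "
                f"{config.min_module_size}"
            )

        stage = "match"
        for a, b in itertools.combinations(CONDITIONS, 2):
            la = clustering.large_size_grms(grms[a], config.min_module_size) or grms[a]
            lb = clustering.large_size_grms(grms[b], config.min_module_size) or grms[b]
            pairing = clustering.match_modules(la, lb)
            df = pd.DataFrame(pairing.pairs, columns=[f"module_{a}", f"module_{b}", "rho"])
            _write(df, out / "04_match" / f"{a}_vs_{b}.tsv", index=False)

        stage = "grn"
        nets = {}
        for c in CONDITIONS:
            mods = grms[c]
            if len(mods) < 2:
                log_lines.append(f"grn: {c}: skipped ({len(mods)} module(s))")
                continue
            curves = np.vstack([m.mean_curve for m in mods])
            model = grn.fit_grn(
                curves, centered[c].time_grid, module_ids=[m.name for m in mods]
            )
            graph = grn.network_from_model(model)
            nets[c] = graph
            edges = pd.DataFrame(
                [
                    {"source": u, "target": v, "weight": d["weight"], "sign": d["sign"]}
                    for u, v, d in graph.edges(data=True)
                ]
            )
            _write(edges, out / "05_grn" / f"{c}_edges.tsv", index=False)
            adj = pd.DataFrame(model.coefficients, index=model.module_ids, columns=model.module_ids)
            _write(adj, out / "05_grn" / f"{c}_adjacency.tsv")
            log_lines.append(f"grn: {c}: {graph.number_of_edges()} edges over {len(mods)} modules")

        stage = "netstats"
        summary_rows = []
        for c, graph in nets.items():
            stats = netstats.compute_stats(graph)
            _write(stats.per_node, out / "06_netstats" / f"{c}_nodes.tsv")
            labels = netstats.important_grms(
                stats, mode=config.importance_mode, k=config.importance_k
            )
            imp = pd.DataFrame(
                [(l.module_id, "".join(sorted(l.flags))) for l in labels],
                columns=["module", "importance"],
            )
            _write(imp, out / "06_netstats" / f"{c}_important.tsv", index=False)
            summary_rows.append(
                {
                    "condition": c,
                    "density": stats.density,
                    "mean_clustering_coefficient": stats.mean_clustering_coefficient,
                }
            )
        _write(pd.DataFrame(summary_rows), out / "06_netstats" / "summary.tsv", index=False)

        stage = "compare"
        for a, b in itertools.combinations(CONDITIONS, 2):
            genes = sorted(
                set(r.gene_id for r in topk[a]) & set(centered[b].gene_ids)
            )
            if not genes:
                continue
            rhos = crosstalk.spearman_between_conditions(
                centered[a].subset(genes).profiles(), centered[b].subset(genes).profiles()
            )
            table = crosstalk.bin_correlations(rhos, a, b)
            df = pd.DataFrame(
                {
                    "bin": list(table.counts),
                    "count": list(table.counts.values()),
                    "percent": [table.percentages[k] for k in table.counts],
                }
            )
            _write(df, out / "07_compare" / f"{a}_vs_{b}.tsv", index=False)

        stage = "crosstalk"
        ref = config.reference_condition
        report = crosstalk.screen_grms(grms[ref], centered)
        _write(report.to_frame(), out / "08_crosstalk" / "gene_report.tsv", index=False)
        lists = pd.DataFrame(
            [("crosstalk", g) for g in report.crosstalk_genes]
            + [("coactivation", g) for g in report.coactivation_genes]
            + [("unevaluable", g) for g in report.unevaluable_genes],
            columns=["classification", "gene_id"],
        )
        _write(lists, out / "08_crosstalk" / "classified_genes.tsv", index=False)
        log_lines.append(
            f"crosstalk: {len(report.crosstalk_genes)} cross-talk, "
            f"{len(report.coactivation_genes)} co-activation gene(s)"
        )
    except Exception as exc:
        log_lines.append(f"ABORTED at stage {stage}: {exc}")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out


def summarize(run_dir) -> pd.DataFrame:
    """Per-condition summary table from a completed run directory."""
    run = Path(run_dir)
    required = ["01_drg", "03_grm"]
    missing = [d for d in required if not (run / d).exists()]
    if missing:
        raise ValueError(f"incomplete run: missing artifact dir(s) {', '.join(missing)}")
    netsum = None
    netsum_path = run / "06_netstats" / "summary.tsv"
    if netsum_path.exists():
        netsum = pd.read_csv(netsum_path, sep="\t").set_index("condition")
    rows = []
    for c in CONDITIONS:
        drg_path = run / "01_drg" / f"{c}.tsv"
        mem_path = run / "03_grm" / f"{c}_members.tsv"
        if not drg_path.exists() or not mem_path.exists():
            raise ValueError(f"incomplete run: missing artifacts for condition {c}")
        drgs = pd.read_csv(drg_path, sep="\t")
        members = pd.read_csv(mem_path, sep="\t")
        sizes = (
            members.groupby("module").size().sort_values(ascending=False)
            if len(members)
            else pd.Series(dtype=int)
        )
        n_clustered = int(sizes.sum())
        row = {
            "condition": c,
            "n_drg": int(drgs["is_drg"].sum()) if len(drgs) else 0,
            "n_grm": int(len(sizes)),
            "n_grm_ge_70": int((sizes >= 70).sum()),
            "grm1_size": int(sizes.iloc[0]) if len(sizes) else 0,
        }
        for first in (6, 8, 12):
            row[f"frac_first_{first}"] = (
                float(sizes.iloc[:first].sum() / n_clustered) if n_clustered else 0.0
            )
        if netsum is not None and c in netsum.index:
            row["density"] = float(netsum.loc[c, "density"])
            row["mean_clustering_coefficient"] = float(
                netsum.loc[c, "mean_clustering_coefficient"]
            )
        rows.append(row)
    return pd.DataFrame(rows)
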