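"""Domain-level report assembly: calibrate -> diagnose -> evaluate -> DIF.

Reports are deterministic text/CSV: fixed ordering, fixed float formats
(two decimals for logits and mean squares, two for percentages), every
criterion value read from the :class:`~raschkit.config.AnalysisConfig`.
Psychometric "failures" (misfit, DIF, low coverage, ...) are findings, not
errors; only unreadable input or non-convergence aborts a run.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .diagnostics import DiagnosticsReport, diagnose
from .dif import DIFTable, dif_contrast, dif_summary, split_groups
from .evaluation import ScaleEvaluation
from .instrument import InstrumentSpec, ResponseMatrix, read_responses
from .model import RaschModel
from .results import RaschResults


@dataclass
class DomainReport:
    domain: str
    result: RaschResults
    diagnostics: DiagnosticsReport
    evaluation: ScaleEvaluation
    dif: Dict[str, DIFTable] = field(default_factory=dict)
    wright: str = ""


@dataclass
class AnalysisReport:
    domains: Dict[str, DomainReport]
    skipped: Dict[str, str]            # domain -> reason
    config: AnalysisConfig

    def render(self) -> str:
        return render_report(self)


def analyze(matrix: ResponseMatrix, spec: InstrumentSpec,
            config: Optional[AnalysisConfig] = None,
            groupings: Optional[List[str]] = None) -> AnalysisReport:
    """Run the full per-domain pipeline on one response matrix."""
    cfg = config or AnalysisConfig()
    if groupings is None:
        groupings = []
        if cfg.dif_enabled and matrix.covariates is not None:
            if "age_years" in matrix.covariates.columns:
                groupings.append("age_75")
            if "stage" in matrix.covariates.columns:
                groupings.append("severity_stage")
    domains: Dict[str, DomainReport] = {}
    skipped: Dict[str, str] = {}
    for domain in sorted(spec.domains()):
        ids = [i for i in spec.analyzed_items(domain) if i in matrix.items]
        if len(ids) < 2:
            skipped[domain] = f"only {len(ids)} analyzed item(s); skipped"
            continue
        model = RaschModel(matrix, spec, domain=domain)
        result = model.fit(cfg)
        if not result.converged:
            raise RuntimeError(
                f"calibration of domain {domain!r} did not converge "
                f"within {cfg.max_iter} iterations "
                f"(max change {result.max_change:.4f})"
            )
        rep = DomainReport(
            domain=domain, result=result,
            diagnostics=diagnose(result, cfg),
            evaluation=result.evaluate(cfg),
            wright=result.wright_map(),
        )
        if cfg.dif_enabled:
            for rule in groupings:
                try:
                    a, b, names = split_groups(matrix, rule, cfg)
                    rep.dif[rule] = dif_contrast(
                        matrix, spec, (a, b), domain=domain, config=cfg,
                        grouping=rule, group_names=names, pooled=result,
                    )
                except ValueError as e:
                    skipped[f"{domain}/DIF:{rule}"] = str(e)
        domains[domain] = rep
    return AnalysisReport(domains=domains, skipped=skipped, config=cfg)


def _fmt_range(pair) -> str:
    return f"{pair[0]:.2f} to {pair[1]:.2f}"


def render_report(report: AnalysisReport) -> str:
    cfg = report.config
    out: List[str] = []
    out.append("Rasch psychometric evaluation report")
    out.append("====================================")
    out.append("")
    out.append("Criteria in use (from configuration):")
    out.append(f"  infit band: {cfg.infit_lower:.2f} to {cfg.infit_upper:.2f}")
    out.append(f"  reliability good: > {cfg.reliability_good:.2f}")
    out.append(
        f"  separation acceptable: {cfg.separation_acceptable[0]:.2f} to "
        f"{cfg.separation_acceptable[1]:.2f}; excellent: > "
        f"{cfg.separation_excellent:.2f}"
    )
    out.append(
        f"  targeting good: |t| < {cfg.targeting_good:.2f}; substantial: "
        f"|t| > {cfg.targeting_substantial:.2f}"
    )
    out.append(f"  coverage good: >= {cfg.coverage_good:.2f} %")
    out.append(f"  gap criterion: >= {cfg.gap_min:.2f} logits")
    out.append(f"  ceiling/floor flag: >= {cfg.ceiling_floor_max:.2f} %")
    out.append(f"  residual correlation flag: |r| > "
               f"{cfg.residual_corr_threshold:.2f}")
    out.append(f"  first-contrast eigenvalue cut: {cfg.unidim_eigen_cut:.2f}")
    out.append(f"  DIF contrast criterion: > {cfg.dif_criterion:.2f} logits")
    out.append("")
    for domain in sorted(report.domains):
        rep = report.domains[domain]
        res = rep.result
        d = rep.diagnostics
        ev = rep.evaluation
        out.append(f"Domain: {domain}")
        out.append("-" * (8 + len(domain)))
        out.append(res.summary(cfg))
        out.append("")
        out.append(
            f"person reliability (separation): "
            f"{d.person_reliability:.2f} ({d.person_separation:.2f})"
        )
        if d.kr20 is not None:
            out.append(f"KR-20 (dichotomous items): {d.kr20:.2f}")
        eig = ", ".join(f"{e:.2f}" for e in d.pca.eigenvalues[:5])
        out.append(
            f"residual PCA eigenvalues (item units): {eig} "
            f"[first contrast {d.pca.first_contrast:.2f}; "
            f"{'unidimensional' if d.pca.unidimensional else 'multidimensional'}"
            f" at cut {d.pca.cut:.2f}]"
        )
        if len(d.dependent_pairs):
            pairs = "; ".join(
                f"{r.item_a}~{r.item_b} (r={r.r:.2f})"
                for r in d.dependent_pairs.itertuples()
            )
            out.append(f"local dependence (|r| > "
                       f"{cfg.residual_corr_threshold:.2f}): {pairs}")
        else:
            out.append(
                f"local dependence (|r| > {cfg.residual_corr_threshold:.2f}): "
                f"none"
            )
        out.append("")
        out.append(f"targeting index: {ev.targeting_index:.2f} "
                   f"({ev.targeting_band})")
        out.append(f"range of item threshold: {_fmt_range(ev.threshold_range)}")
        out.append(f"range of person measure: {_fmt_range(ev.person_range)}")
        out.append(f"95 % person measure limits: "
                   f"{_fmt_range(ev.person_limits_95)}")
        out.append(f"coverage (%): {ev.coverage_pct:.2f}"
                   + ("" if ev.coverage_good else
                      f"  [below {cfg.coverage_good:.2f} % criterion]"))
        out.append(f"floor effect (%): {ev.floor_pct:.2f}"
                   + ("  [flagged]" if ev.floor_flag else ""))
        out.append(f"ceiling effect (%): {ev.ceiling_pct:.2f}"
                   + ("  [flagged]" if ev.ceiling_flag else ""))
        if len(ev.gaps):
            gtxt = "; ".join(
                f"{r.item_low}->{r.item_high} ({r.gap:.2f})"
                for r in ev.gaps.itertuples()
            )
            out.append(f"gaps >= {cfg.gap_min:.2f} logits: {gtxt}")
        else:
            out.append(f"gaps >= {cfg.gap_min:.2f} logits: none")
        if ev.disordered_items:
            out.append("disordered thresholds: "
                       + ", ".join(ev.disordered_items))
        else:
            out.append("disordered thresholds: none")
        out.append("")
        for rule in sorted(rep.dif):
            tab = rep.dif[rule]
            summ = dif_summary(tab)
            out.append(
                f"DIF ({rule}: {tab.group_names[0]} vs {tab.group_names[1]}, "
                f"criterion {tab.criterion:.2f} logits)"
            )
            for dom_name, row in summ.iterrows():
                out.append(f"  {dom_name}: {row['display']} items flagged "
                           f"of {row['n_testable']} testable")
            for item, row in tab.table.iterrows():
                if pd.isna(row["contrast"]):
                    out.append(f"  {item:<10} contrast n/a "
                               f"(extreme in a subgroup)")
                else:
                    mark = "  *DIF*" if bool(row["flag"]) else ""
                    out.append(
                        f"  {item:<10} {row['delta_a']:7.2f} "
                        f"{row['delta_b']:7.2f}  contrast "
                        f"{row['contrast']:7.2f}{mark}"
                    )
            out.append("")
        out.append("Item-person map")
        out.append(rep.wright)
        out.append("")
    for key in sorted(report.skipped):
        out.append(f"warning: {key}: {report.skipped[key]}")
    out.append("")
    return "\n".join(out)


def run_pipeline(responses_path, spec_path, out_dir,
                 config: Optional[AnalysisConfig] = None) -> AnalysisReport:
    """File-level entry: read inputs, analyze, write report + CSV tables."""
    cfg = config or AnalysisConfig()
    spec = InstrumentSpec.from_yaml(spec_path)
    matrix = read_responses(responses_path, spec)
    report = analyze(matrix, spec, cfg)
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "report.txt"), "w", encoding="utf-8") as fh:
        fh.write(report.render())
    for domain, rep in sorted(report.domains.items()):
        rep.result.to_csv(os.path.join(out_dir, f"calibration_{domain}.csv"),
                          cfg)
        for rule, tab in sorted(rep.dif.items()):
            tab.to_csv(os.path.join(out_dir, f"dif_{domain}_{rule}.csv"))
            tab.plot_data().to_csv(
                os.path.join(out_dir, f"dif_{domain}_{rule}_plot.csv"),
                index=False, float_format="%.4f")
    return report
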