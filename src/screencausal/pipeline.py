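"""End-to-end orchestration: simulate -> describe -> estimate -> sensitivity
-> scenario -> report, with a reproducible run manifest.

The run configuration is a nested mapping (usually loaded from YAML):

    seed: 1
    output_dir: results
    simulate: {n_women: 50000}          # or  input: cohort.csv
    describe: true
    estimate: {outcomes: [detection, recall], scheme: overlap}
    sensitivity: [{analysis: bootstrap, B: 100}]
    scenario: true
    dag_test: {alpha: 0.05, n_permutations: 200}

Every emitted artifact is listed in the manifest with its SHA-256
digest; rerunning with the same configuration and seed reproduces the
outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .records import read_cohort, write_cohort, apply_exclusions, validate_cohort
from .simulate import SimulationConfig, simulate_cohort
from .descriptives import cohort_summary, summary_frame
from .estimation import analyze_endpoint, model_ppv
from .sensitivity import (automation_scenario, bootstrap_analysis,
                          placebo_permutation, reader_level_analysis,
                          stratified_analysis, subsample_analysis)
from .dag import build_screening_dag
from .hsic import test_all_implications

__all__ = ["run_full_analysis", "render_report", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_full_analysis(config: dict, output_dir=None) -> dict:
    """Execute the configured stages in order; returns the manifest.

    On stage failure the pipeline aborts with the stage name; artifacts
    written so far stay on disk and the manifest carries ``"partial"``.
    """
    from . import __version__

    cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    out_dir = Path(output_dir or cfg.get("output_dir", "results"))
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": seed, "config": _jsonable(cfg),
                "stages": [], "artifacts": {}, "warnings": [], "partial": True}
    results: dict = {}

    def note(stage):
        manifest["stages"].append({"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S")})

    def emit(name: str, path: Path):
        manifest["artifacts"][name] = {"path": str(path), "sha256": _digest(path)}

    # --- input ------------------------------------------------------------
    if "input" in cfg:
        path = Path(cfg["input"])
        if not path.exists():
            raise PipelineError("input", f"input table {path} does not exist")
        note("load")
        table = read_cohort(path)
    elif "simulate" in cfg:
        note("simulate")
        sim = SimulationConfig.from_dict(cfg.get("simulate") or {})
        table = simulate_cohort(sim, seed=seed)
        sim_path = out_dir / "cohort.csv"
        write_cohort(table, sim_path)
        emit("cohort", sim_path)
    else:
        raise PipelineError("input", "config must provide 'input' or 'simulate'")

    table, exclusions = apply_exclusions(table)
    report = validate_cohort(table)
    if not report.passed:
        manifest["warnings"].append({"validation": report.violations})
    results["exclusions"] = {"missing_outcome": exclusions.excluded_missing_outcome,
                             "cancelled": exclusions.excluded_cancelled}

    # --- describe ---------------------------------------------------------
    if cfg.get("describe", True):
        note("describe")
        summ = cohort_summary(table)
        frame = summary_frame(summ)
        path = out_dir / "summary.csv"
        frame.to_csv(path, index=False, lineterminator="\n")
        emit("summary", path)
        results["summary"] = frame.to_dict(orient="records")
        results["triage"] = {g: _jsonable(dataclasses.asdict(t))
                             for g, t in summ.triage.items()}

    # --- estimate ---------------------------------------------------------
    est_cfg = cfg.get("estimate", {"outcomes": ["detection", "recall"]})
    if est_cfg:
        note("estimate")
        scheme = est_cfg.get("scheme", "overlap")
        margin = float(est_cfg.get("margin_pct", 10.0))
        effects = {}
        for outcome in est_cfg.get("outcomes", ["detection", "recall"]):
            try:
                est, dec = analyze_endpoint(table, outcome, scheme=scheme,
                                            margin_pct=margin)
            except Exception as exc:
                raise PipelineError("estimate", f"{outcome}: {exc}") from exc
            effects[outcome] = {"estimate": est.summary_row(),
                                "decision": {"verdict": dec.verdict if dec else "undefined",
                                             "margin_pct": dec.margin_pct if dec else None}}
        if est_cfg.get("ppv", False):
            effects["ppv_recall"] = model_ppv(table, "recall", seed=seed,
                                              n_boot=int(est_cfg.get("ppv_boot", 100)))
        results["effects"] = effects
        path = out_dir / "effects.json"
        path.write_text(json.dumps(_jsonable(effects), indent=2) + "\n")
        emit("effects", path)
        # companion delimited table, one endpoint per row
        rows = [dict(blk["estimate"], verdict=blk["decision"]["verdict"])
                for blk in effects.values() if "estimate" in blk]
        if rows:
            csv_path = out_dir / "effects.csv"
            pd.DataFrame(rows).to_csv(csv_path, index=False, lineterminator="\n")
            emit("effects_table", csv_path)

    # --- sensitivity ------------------------------------------------------
    for spec in cfg.get("sensitivity", []):
        kind = spec.get("analysis")
        note(f"sensitivity:{kind}")
        try:
            if kind == "bootstrap":
                r = bootstrap_analysis(table, spec.get("outcome", "detection"),
                                       B=int(spec.get("B", 200)), seed=seed)
                payload = {"mean_pct": r.mean_pct, "ci_pct": r.ci_pct,
                           "failed": r.n_failed}
            elif kind == "subsample80":
                r = subsample_analysis(table, spec.get("outcome", "detection"),
                                       fraction=float(spec.get("fraction", 0.8)),
                                       B=int(spec.get("B", 200)), seed=seed)
                payload = {"mean_pct": r.mean_pct, "ci_pct": r.ci_pct,
                           "failed": r.n_failed}
            elif kind == "reader_level":
                est, dec = reader_level_analysis(table, spec.get("outcome", "detection"))
                payload = {"estimate": est.summary_row(),
                           "verdict": dec.verdict if dec else "undefined"}
            elif kind == "stratified":
                est = stratified_analysis(table, spec.get("outcome", "detection"),
                                          min_n=int(spec.get("min_n", 0)), seed=seed)
                payload = {"estimate": est.summary_row()}
            elif kind == "placebo":
                est, dec = placebo_permutation(table, seed=seed,
                                               outcome=spec.get("outcome", "detection"))
                payload = {"estimate": est.summary_row(),
                           "verdict": dec.verdict if dec else "undefined"}
            else:
                raise ValueError(f"unknown sensitivity analysis {kind!r}")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"sensitivity:{kind}", str(exc)) from exc
        results.setdefault("sensitivity", {})[kind] = _jsonable(payload)

    # --- automation scenario ---------------------------------------------
    if cfg.get("scenario", False):
        note("scenario")
        transformed, workload = automation_scenario(table)
        scen = {"workload_fraction_pct": 100.0 * workload, "effects": {}}
        for outcome in ("detection", "recall"):
            est, dec = analyze_endpoint(transformed, outcome)
            scen["effects"][outcome] = {"estimate": est.summary_row(),
                                        "verdict": dec.verdict if dec else "undefined"}
        results["scenario"] = _jsonable(scen)

    # --- DAG consistency ---------------------------------------------------
    if cfg.get("dag_test", False):
        note("dag_test")
        opts = cfg["dag_test"] if isinstance(cfg["dag_test"], dict) else {}
        claims = test_all_implications(
            build_screening_dag(), table,
            alpha=float(opts.get("alpha", 0.05)), seed=seed,
            n_permutations=int(opts.get("n_permutations", 200)))
        results["dag_test"] = [{"claim": c.label(), "p": c.p_value,
                                "holds": c.holds} for c in claims]

    results_path = out_dir / "results.json"
    results_path.write_text(json.dumps(_jsonable(results), indent=2) + "\n")
    emit("results", results_path)
    report_path = out_dir / "report.txt"
    report_path.write_text(render_report(results))
    emit("report", report_path)
    manifest["partial"] = False
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(_jsonable(manifest), indent=2) + "\n")
    return manifest


def _fmt(x, nd=1):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return f"{x:.{nd}f}"


def render_report(results: dict) -> str:
    """Human-readable report with table-shaped sections.

    Numbers equal the underlying result values at display precision;
    missing sections are omitted with a notice.
    """
    lines = ["AI-supported double-reading screening analysis", "=" * 47, ""]
    if not results:
        return "\n".join(lines + ["(no results)"])

    if "summary" in results:
        lines += ["Population summary (crude)", "-" * 26]
        for row in results["summary"]:
            lines.append(
                f"  {row['group']:>8}: n={row['n']:>9,}  "
                f"consensus {_fmt(row['consensus_pct'])}%  "
                f"recall {_fmt(row['recall_per_1000'])}/1000  "
                f"biopsy {_fmt(row['biopsy_per_1000'])}/1000  "
                f"detection {_fmt(row['detection_per_1000'])}/1000  "
                f"PPV recall {_fmt(row['ppv_recall_pct'])}%")
        lines.append("")
    else:
        lines.append("(no descriptive section)\n")

    if "triage" in results:
        lines += ["AI predictions (percent of group)", "-" * 33]
        for g, t in results["triage"].items():
            n = t["n"] or 1
            lines.append(f"  {g:>8}: normal {_fmt(100*t['normal']/n)}%  "
                         f"safety net triggered {_fmt(100*t['sn_triggered']/n)}%")
        lines.append("")

    if "effects" in results:
        lines += ["Model-based effects (overlap weighting)", "-" * 39]
        for outcome, blk in results["effects"].items():
            if "estimate" not in blk:
                continue
            e = blk["estimate"]
            lines.append(
                f"  {outcome:>10}: AI {_fmt(e['mu_ai'], 2)} vs control "
                f"{_fmt(e['mu_control'], 2)} per 1000; "
                f"pct diff {_fmt(e['pct_diff'])}% "
                f"({_fmt(e['pct_ci_low'])}%, {_fmt(e['pct_ci_high'])}%) "
                f"-> {blk['decision']['verdict']}")
        lines.append("")

    if "sensitivity" in results:
        lines += ["Sensitivity analyses", "-" * 20]
        for kind, payload in results["sensitivity"].items():
            if "mean_pct" in payload:
                ci = payload.get("ci_pct") or (None, None)
                lines.append(f"  {kind:>12}: mean pct diff {_fmt(payload['mean_pct'])}% "
                             f"({_fmt(ci[0])}%, {_fmt(ci[1])}%)")
            elif "estimate" in payload:
                e = payload["estimate"]
                lines.append(f"  {kind:>12}: pct diff {_fmt(e['pct_diff'])}% "
                             f"({_fmt(e['pct_ci_low'])}%, {_fmt(e['pct_ci_high'])}%)")
        lines.append("")

    if "scenario" in results:
        s = results["scenario"]
        lines += ["Automation scenario (normal-tagged not read)", "-" * 44,
                  f"  workload reduction: {_fmt(s['workload_fraction_pct'])}%"]
        for outcome, blk in s["effects"].items():
            e = blk["estimate"]
            lines.append(f"  {outcome:>10}: pct diff {_fmt(e['pct_diff'])}% "
                         f"({_fmt(e['pct_ci_low'])}%, {_fmt(e['pct_ci_high'])}%) "
                         f"-> {blk['verdict']}")
        lines.append("")

    if "dag_test" in results:
        held = sum(1 for c in results["dag_test"] if c["holds"])
        lines += ["Causal-graph consistency",
                  "-" * 24,
                  f"  {held}/{len(results['dag_test'])} implied independences hold"]
        for c in results["dag_test"]:
            flag = "ok " if c["holds"] else "VIOLATED"
            lines.append(f"    [{flag}] {c['claim']} (p={_fmt(c['p'], 3)})")
        lines.append("")
    return "\n".join(lines)
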