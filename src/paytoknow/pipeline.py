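"""End-to-end analysis pipeline and report rendering.

Orchestrates: self-relevance filter → model-free indices → PSE bootstrap →
model-grid fitting → group-BIC comparison → classical contrasts, and renders
a JSON report plus a markdown summary of the numbers.  All stochastic stages
draw their seeds deterministically from one global seed and the stage name,
so a re-run with the same inputs reproduces every number bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import models, psychometrics, stats
from .errors import PayToKnowError, ZeroVarianceError
from .models import MODEL_GRID, ModelSpec
from .task import records_to_frame

__all__ = ["PipelineConfig", "derive_seed", "run_analysis", "render_markdown"]

log = logging.getLogger("paytoknow")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from stage name."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_boot: int = 200
    n_starts: int = 20
    relevance_filter: bool = True
    model_names: Sequence[str] = ("valence_specific", "shared_beta")
    log_level: str = "INFO"

    def specs(self) -> list[ModelSpec]:
        by_name = {s.name: s for s in MODEL_GRID}
        missing = [m for m in self.model_names if m not in by_name]
        if missing:
            raise PayToKnowError(f"unknown model(s): {', '.join(missing)} "
                                 f"(available: {', '.join(by_name)})")
        return [by_name[m] for m in self.model_names]


def _stage(name: str, seed: int):
    t0 = time.perf_counter()
    log.info("stage=%s seed=%d start", name, seed)
    return t0


def run_analysis(data: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    """Run the full pipeline on a trial table; returns the report dict."""
    config = config or PipelineConfig()
    df = records_to_frame(data) if not isinstance(data, pd.DataFrame) else data
    if len(df) == 0:
        raise PayToKnowError("empty dataset")
    report: dict = {"config": {"seed": config.seed, "n_boot": config.n_boot,
                               "n_starts": config.n_starts,
                               "relevance_filter": config.relevance_filter,
                               "models": list(config.model_names)},
                    "n_subjects": int(df["subject_id"].nunique()),
                    "n_trials": int(len(df)),
                    "failures": []}

    # 1. relevance filter
    if config.relevance_filter:
        res = stats.self_relevance_filter(df)
        df = res.records
        report["relevance_filter"] = {
            "skipped": res.skipped,
            "message": res.message,
            "retained_trials": int(len(df)),
        }

    # 2. model-free indices
    idx = stats.knowing_indices(df, by=["subject_id", "valence"])
    overall = stats.knowing_indices(df, by=["subject_id"])
    report["knowing_indices"] = {
        "overall_mean": float(overall["knowing_ratio"].mean()),
        "by_valence": idx.groupby("valence")["knowing_ratio"].mean().to_dict(),
        "costly_by_valence": idx.groupby("valence")["costly_knowing_ratio"].mean().to_dict(),
    }
    try:
        t = stats.one_sample_t(overall["knowing_ratio"], popmean=0.5)
        report["knowing_vs_chance"] = {"t": t.statistic, "df": t.df, "p": t.p_value,
                                       "cohens_d": t.cohens_d}
    except (ZeroVarianceError, PayToKnowError) as e:
        report["failures"].append({"stage": "knowing_vs_chance", "error": str(e)})

    wide = idx.pivot(index="subject_id", columns="valence", values="knowing_ratio")
    if {"positive", "negative"} <= set(wide.columns) and len(wide) >= 2:
        try:
            t = stats.paired_t(wide["positive"], wide["negative"])
            report["positive_vs_negative"] = {"t": t.statistic, "df": t.df,
                                              "p": t.p_value, "cohens_d": t.cohens_d}
        except ZeroVarianceError as e:
            report["failures"].append({"stage": "positive_vs_negative", "error": str(e)})

    # 3. PSE bootstrap per valence + difference
    _stage("pse", derive_seed(config.seed, "pse"))
    pse_out = {}
    for val in ("positive", "negative", None):
        key = val or "all"
        try:
            b = psychometrics.bootstrap_group_pse(
                df, valence=val, n_iter=config.n_boot,
                seed=derive_seed(config.seed, f"pse-{key}"))
            pse_out[key] = {"mean": b.mean, "ci95": list(b.ci95),
                            "n_failed": b.n_failed, "warning": b.warning}
        except PayToKnowError as e:
            report["failures"].append({"stage": f"pse-{key}", "error": str(e)})
    try:
        d = psychometrics.pse_difference_test(
            df, df, paired=True, valence_a="positive", valence_b="negative",
            n_iter=config.n_boot, seed=derive_seed(config.seed, "pse-diff"))
        pse_out["positive_minus_negative"] = {
            "mean": d.mean, "ci95": list(d.ci95), "significant": d.significant}
    except PayToKnowError as e:
        report["failures"].append({"stage": "pse-diff", "error": str(e)})
    report["pse"] = pse_out

    # 4. model grid + comparison
    _stage("models", derive_seed(config.seed, "models"))
    try:
        comp = models.compare_models(df, config.specs(), n_starts=config.n_starts,
                                     seed=derive_seed(config.seed, "models"))
        col_sums = comp.per_subject_bic.sum(axis=0, skipna=False)
        if not np.allclose(col_sums.to_numpy(float), comp.group_bic.to_numpy(float),
                           equal_nan=True):
            raise PayToKnowError("group BIC does not equal per-subject column sums")
        win_fits = [f for (u, m), f in comp.fits.items() if m == comp.winner]
        betas_pos = [f.params.beta_pos for f in win_fits]
        betas_neg = [f.params.beta_neg for f in win_fits]
        report["model_comparison"] = {
            "winner": comp.winner,
            "group_bic": {k: float(v) for k, v in comp.group_bic.items()},
            "n_failures": len(comp.failures),
            "winner_mean_accuracy": float(np.mean([f.accuracy for f in win_fits])) if win_fits else None,
            "winner_mean_beta_pos": float(np.mean(betas_pos)) if betas_pos else None,
            "winner_mean_beta_neg": float(np.mean(betas_neg)) if betas_neg else None,
            "per_subject_bic": json.loads(comp.per_subject_bic.to_json()),
        }
    except PayToKnowError as e:
        report["failures"].append({"stage": "model_comparison", "error": str(e)})

    return report


def render_markdown(report: dict) -> str:
    """Human-readable summary of a pipeline report."""
    lines = ["# Pay-to-know analysis report", ""]
    lines.append(f"Subjects: {report.get('n_subjects')}, trials: {report.get('n_trials')}")
    ki = report.get("knowing_indices", {})
    if ki:
        lines += ["", "## Model-free indices", "",
                  f"- overall knowing ratio: {ki['overall_mean']:.4f}"]
        for val, v in sorted(ki.get("by_valence", {}).items()):
            lines.append(f"- knowing ratio ({val}): {v:.4f}")
        for val, v in sorted(ki.get("costly_by_valence", {}).items()):
            if v == v:  # not NaN
                lines.append(f"- costly knowing ratio ({val}): {v:.4f}")
    if "knowing_vs_chance" in report:
        k = report["knowing_vs_chance"]
        lines.append(f"- knowing ratio vs 50%: t({k['df']:.0f}) = {k['t']:.2f}, "
                     f"p = {k['p']:.3g}, d = {k['cohens_d']:.2f}")
    if "positive_vs_negative" in report:
        k = report["positive_vs_negative"]
        lines.append(f"- positive vs negative: t({k['df']:.0f}) = {k['t']:.2f}, "
                     f"p = {k['p']:.3g}, d = {k['cohens_d']:.2f}")
    pse = report.get("pse", {})
    if pse:
        lines += ["", "## Point of subjective equivalence (bootstrap)", ""]
        for key, v in pse.items():
            if "mean" in v and v["mean"] == v["mean"]:
                extra = ""
                if "significant" in v:
                    extra = ", significant" if v["significant"] else ", n.s."
                lines.append(f"- PSE[{key}]: {v['mean']:.3f} tokens "
                             f"(95% CI {v['ci95'][0]:.3f} to {v['ci95'][1]:.3f}{extra})")
    mc = report.get("model_comparison")
    if mc:
        lines += ["", "## Model comparison (group BIC)", ""]
        for name, bic in mc["group_bic"].items():
            mark = " <- winner" if name == mc["winner"] else ""
            lines.append(f"- {name}: {bic:.1f}{mark}")
        if mc.get("winner_mean_accuracy") is not None:
            lines.append(f"- winning-model mean in-sample accuracy: "
                         f"{mc['winner_mean_accuracy']:.4f}")
        if mc.get("winner_mean_beta_pos") is not None:
            lines.append(f"- winning-model mean beta_pos: {mc['winner_mean_beta_pos']:.3f}, "
                         f"mean beta_neg: {mc['winner_mean_beta_neg']:.3f}")
    if report.get("failures"):
        lines += ["", "## Stage failures", ""]
        for f in report["failures"]:
            lines.append(f"- {f['stage']}: {f['error']}")
    return "\n".join(lines) + "\n"
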