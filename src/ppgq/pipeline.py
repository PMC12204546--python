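"""End-to-end orchestration: simulate -> screen -> metrics -> compare -> report.

Every run is fully reproducible from ``(config, seed)``: the single global
seed is fanned out to per-stage child seeds through a counter-based
``numpy.random.SeedSequence`` scheme, so each stage can be re-run
independently yet deterministically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    Condition,
    PPGRecording,
    PROTOCOL_CONDITIONS,
    RunConfig,
    SubjectRecord,
    cohort_to_frame,
    write_cohort_table,
)
from .preprocess import QC_PASS, screen_cohort
from .quality import compute_all
from .stats import (
    METRICS,
    TestFamily,
    boxplot_stats,
    covariate_model_spec,
    enumerate_direct_comparisons,
    fit_contrast,
    fit_lmm,
    holm_sidak,
    metric_r2,
    summarize_metric,
)
from .synthetic import default_condition_configs, generate_waveform_cohort

logger = logging.getLogger("ppgq")

__all__ = ["RunManifest", "PipelineError", "run_pipeline", "render_report", "compute_metrics_table"]

#: Stage names in execution order (used for seed fan-out and manifests).
STAGES = ("simulate", "screen", "metrics", "compare", "report")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, manifest: "RunManifest", cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.__cause__ = cause


@dataclass
class RunManifest:
    """Bookkeeping of one pipeline run."""

    config_hash: str
    seed: int
    version: str = __version__
    subjects_generated: int = 0
    subjects_included: int = 0
    subjects_excluded: int = 0
    exclusion_reasons: dict = field(default_factory=dict)
    files: list = field(default_factory=list)

    def check(self) -> None:
        assert self.subjects_included + self.subjects_excluded == self.subjects_generated
        for f in self.files:
            assert Path(f).exists(), f"registered output {f} is missing"


def _config_hash(cfg: RunConfig) -> str:
    blob = yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic child seed for a named stage (counter-based fan-out)."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence(seed).spawn(len(STAGES))[idx].generate_state(1)[0] % (2**31))


def compute_metrics_table(
    recordings: Iterable[PPGRecording], cfg: Optional[RunConfig] = None
) -> pd.DataFrame:
    """Quality metrics for a collection of recordings, one row each.

    Repetition indices are assigned per (subject, condition) in input
    order.
    """
    cfg = cfg or RunConfig()
    rows = []
    reps: dict[tuple[str, str], int] = {}
    for rec in recordings:
        key = (rec.subject_id, rec.condition.value)
        rep = reps.get(key, 0)
        reps[key] = rep + 1
        qm = compute_all(rec, cfg)
        rows.append(
            {
                "subject_id": qm.subject_id,
                "condition": qm.condition,
                "rep": rep,
                "snr_db": qm.snr_db,
                "pi_percent": qm.pi_percent,
                "tmcc": qm.tmcc,
                "median_ac": qm.median_ac,
                "median_dc": qm.median_dc,
                "n_beats": qm.n_beats,
                "qc": qm.qc,
            }
        )
    return pd.DataFrame(rows)


def _condition_configs(cfg: RunConfig):
    """Per-condition waveform configs with ``cfg.simulator`` overrides.

    Recognised simulator keys: ``ac_amps`` (mapping condition value ->
    pulse amplitude) and any scalar WaveformConfig field (``noise_sd``,
    ``mean_hr``, ``hr_sd``, ``duration``, ...) applied to every condition.
    """
    configs = default_condition_configs()
    sim = dict(cfg.simulator or {})
    ac_amps = sim.pop("ac_amps", {})
    for cond_value, ac in ac_amps.items():
        cond = Condition(cond_value)
        configs[cond] = dataclasses.replace(configs[cond], ac_amp=float(ac))
    if sim:
        configs = {c: dataclasses.replace(w, **sim) for c, w in configs.items()}
    return configs


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Run the full analysis on a simulated waveform cohort.

    Products in ``cfg.out_dir``: the per-recording metrics table, the
    per-condition summary, Holm–Šidák-corrected direct posture/height
    comparisons, covariate mixed-model tables (with and without the
    DC-amplitude term for the SNR), metric-vs-metric R², per-condition
    boxplot statistics, a markdown report, and the run manifest.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(cfg), seed=cfg.seed)

    def register(path: Path) -> Path:
        manifest.files.append(str(path))
        return path

    stage = "simulate"
    try:
        logger.info("stage=%s n_subjects=%d seed=%d", stage, cfg.n_subjects, cfg.seed)
        recordings, subjects, truths = generate_waveform_cohort(
            cfg.n_subjects,
            condition_configs=_condition_configs(cfg),
            seed=stage_seed(cfg.seed, "simulate"),
        )
        manifest.subjects_generated = len(subjects)
        register(write_cohort_table(subjects, out / "cohort.tsv"))

        stage = "screen"
        included, reasons = screen_cohort(recordings, PROTOCOL_CONDITIONS)
        manifest.subjects_included = len(included)
        manifest.subjects_excluded = len(subjects) - len(included)
        manifest.exclusion_reasons = reasons
        logger.info("stage=%s included=%d excluded=%d", stage, len(included), len(reasons))

        stage = "metrics"
        kept = [r for r in recordings if r.subject_id in included]
        metrics = compute_metrics_table(kept, cfg)
        register(_write_tsv(metrics, out / "metrics.tsv"))

        summary_rows = []
        for cond in Condition:
            sub = metrics[metrics["condition"] == cond.value]
            for m in METRICS:
                if sub[m].notna().any():
                    s = summarize_metric(sub[m])
                    summary_rows.append({"condition": cond.value, "metric": m, **s})
        summary = pd.DataFrame(summary_rows)
        register(_write_tsv(summary, out / "summary.tsv"))

        stage = "compare"
        cohort_df = cohort_to_frame(subjects)
        analysis = metrics.merge(cohort_df, on="subject_id", how="left")

        contrasts = enumerate_direct_comparisons(list(Condition))
        est, pvals, labels = [], [], []
        for c in contrasts:
            e, p = fit_contrast(analysis, c)
            est.append(e)
            pvals.append(p)
            labels.append(c.label)
        family = holm_sidak(pvals, alpha=0.05, labels=labels)
        direct = family.to_frame()
        direct.insert(1, "estimate", est)
        register(_write_tsv(direct, out / "direct_comparisons.tsv"))

        def fit_covariate_model(metric: str, include_dc: bool):
            spec = covariate_model_spec(metric, include_dc, with_conditions=True)
            # small demo cohorts can yield constant covariates (e.g. nobody
            # with diabetes); drop zero-variance terms rather than fail
            keep = tuple(
                t
                for t in spec.fixed_terms
                if t not in analysis.columns or analysis[t].nunique(dropna=True) > 1
            )
            dropped = set(spec.fixed_terms) - set(keep)
            if dropped:
                logger.info("stage=compare metric=%s dropping constant term(s) %s", metric, sorted(dropped))
            from .stats import ModelSpec
            from .io_formats import ValidationError
            import re

            # tiny demo cohorts cannot identify all subject-level
            # covariates (rank <= n_subjects); drop flagged terms and refit
            while True:
                try:
                    return fit_lmm(analysis, ModelSpec(response=metric, fixed_terms=keep))
                except ValidationError as err:
                    if "collinear" not in str(err):
                        raise
                    flagged = set(re.findall(r"'(\w+)'", str(err))) & set(keep)
                    if not flagged:
                        raise
                    logger.info(
                        "stage=compare metric=%s dropping collinear term(s) %s", metric, sorted(flagged)
                    )
                    keep = tuple(t for t in keep if t not in flagged)

        model_tables = {}
        for metric in METRICS:
            model_tables[f"covariate_{metric}"] = fit_covariate_model(metric, True)
        model_tables["covariate_snr_db_no_dc"] = fit_covariate_model("snr_db", False)
        for name, res in model_tables.items():
            tab = res.table.reset_index(names="term")
            register(_write_tsv(tab, out / f"model_{name}.tsv"))

        r2 = {
            "pi_vs_tmcc": metric_r2(metrics["pi_percent"], metrics["tmcc"]),
            "snr_vs_pi": metric_r2(metrics["snr_db"], metrics["pi_percent"]),
            "snr_vs_tmcc": metric_r2(metrics["snr_db"], metrics["tmcc"]),
        }
        boxes = {
            m: {
                cond.value: boxplot_stats(metrics.loc[metrics["condition"] == cond.value, m])
                for cond in Condition
                if metrics.loc[metrics["condition"] == cond.value, m].notna().any()
            }
            for m in METRICS
        }
        with open(register(out / "r2.json"), "w") as fh:
            json.dump(r2, fh, indent=1)
        with open(register(out / "boxplots.json"), "w") as fh:
            json.dump(boxes, fh, indent=1)

        stage = "report"
        report = render_report(
            {
                "summary": summary,
                "direct": direct,
                "models": {k: v.table for k, v in model_tables.items()},
                "r2": r2,
            }
        )
        register(out / "report.md").write_text(report)

        with open(register(out / "manifest.json"), "w") as fh:
            json.dump(dataclasses.asdict(manifest) | {"files": manifest.files + [str(out / "manifest.json")]}, fh, indent=1)
        manifest.check()
    except Exception as err:  # noqa: BLE001 - abort with stage context
        if isinstance(err, AssertionError):
            raise
        raise PipelineError(stage, manifest, err) from err
    return manifest


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.3g}") -> str:
    df = df.copy()
    for c in df.columns:
        if pd.api.types.is_float_dtype(df[c]):
            df[c] = df[c].map(lambda v: floatfmt.format(v) if pd.notna(v) else "")
    header = "| " + " | ".join(str(c) for c in df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    body = ["| " + " | ".join(str(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *body])


def render_report(results: dict) -> str:
    """Format pipeline results as a markdown summary (no computation).

    Significant direct comparisons (Holm–Šidák adjusted p < 0.05) are
    marked with an asterisk.
    """
    lines = ["# PPG signal-quality report", ""]

    lines.append("## Observed signal quality by condition\n")
    summary = results.get("summary")
    if summary is None or len(summary) == 0:
        lines.append("no data\n")
    else:
        lines.append(_md_table(summary) + "\n")

    lines.append("## Direct posture / sensor-height comparisons\n")
    direct = results.get("direct")
    if direct is None or len(direct) == 0:
        lines.append("no data\n")
    else:
        d = direct.copy()
        d["sig"] = np.where(d["p_adjusted"] < 0.05, "*", "")
        lines.append(_md_table(d) + "\n")

    lines.append("## Participant-characteristic mixed models\n")
    models = results.get("models") or {}
    if not models:
        lines.append("no data\n")
    for name, tab in models.items():
        lines.append(f"### {name}\n")
        lines.append(_md_table(tab.reset_index(names="term")) + "\n")

    lines.append("## Between-metric R²\n")
    r2 = results.get("r2")
    if not r2:
        lines.append("no data\n")
    else:
        lines.append(_md_table(pd.DataFrame([r2])) + "\n")
    return "\n".join(lines)
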