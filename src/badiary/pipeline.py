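"""End-to-end pipeline: ingest or simulate diaries, run all analyses, report.

Outputs are plain CSV/JSON under an output directory, plus a log that
echoes every convention choice (alpha, pairing, JAC denominator,
tie-breaks, day-pairing rule) and the seed, so a report is reproducible
from its log.  Stage failures are reported per stage without aborting the
rest of the pipeline.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml

from . import descriptives, diurnal, dose_response, goodworse
from .diary import Diary, compliance_rate
from .io import parse_diary_table, write_diary_csv
from .synthetic import CohortConfig, generate_cohort
from .taxonomy import ActivityCategory

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (exactly one input mode)."""

    mode: Literal["simulate", "diaries"] = "simulate"
    input_path: str | None = None
    out_dir: str = "ba_report"
    seed: int = 0
    alpha: float = 0.05
    pairing: Literal["rank_order", "index"] = "index"
    jac_denominator: Literal["all_slots", "filled_slots"] = "all_slots"
    consecutive_only: bool = True
    dose_category: str = "Social"
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "diaries"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "diaries" and not self.input_path:
            raise ValueError("diaries mode requires input_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohort" in raw:
            cohort_raw = raw.pop("cohort") or {}
            if "start_date" in cohort_raw:
                cohort_raw["start_date"] = dt.date.fromisoformat(
                    str(cohort_raw["start_date"])
                )
            if "category_effects" in cohort_raw:
                cohort_raw["category_effects"] = {
                    ActivityCategory.from_label(k): float(v)
                    for k, v in cohort_raw["category_effects"].items()
                }
            if "pleasure_scale" in cohort_raw:
                cohort_raw["pleasure_scale"] = tuple(cohort_raw["pleasure_scale"])
            raw["cohort"] = CohortConfig(**cohort_raw)
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns a dict with the in-memory tables, the stage errors, and the
    paths written.  The process-level contract (exit status) lives in the
    CLI wrapper.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    errors: dict[str, str] = {}
    report: dict = {"out_dir": str(out), "errors": errors}

    log.append(f"seed: {config.seed}")
    log.append(f"alpha: {config.alpha}")
    log.append(f"signed-rank pairing convention: {config.pairing}")
    log.append(f"JAC denominator convention: {config.jac_denominator}")
    log.append(
        "adherence day pairs: "
        + ("calendar-adjacent weekdays (no Fri->Mon)"
           if config.consecutive_only else "next available scored weekday")
    )
    log.append("template tie-break: lowest category ordinal")
    log.append("median-split ties: labeled worse with weight 0")

    # --- input stage -----------------------------------------------------
    if config.mode == "simulate":
        diaries_list, truth = generate_cohort(config.cohort, seed=config.seed)
        diaries = {d.patient_id: d for d in diaries_list}
        write_diary_csv(diaries, out / "diaries.csv")
        truth.to_json(out / "truth.json")
        report["truth"] = truth
        log.append(f"input: simulated cohort of {len(diaries)} patients")
    else:
        path = Path(config.input_path)  # type: ignore[arg-type]
        if not path.exists():
            raise FileNotFoundError(f"diaries file not found: {path}")
        diaries, parse_report = parse_diary_table(path)
        report["parse_report"] = parse_report
        log.append(
            f"input: {path} ({parse_report.n_parsed} rows parsed, "
            f"{parse_report.n_rejected} rejected, "
            f"{parse_report.n_duplicates} duplicate-slot rows kept as overflow)"
        )
    report["diaries"] = diaries
    scored = {pid: d for pid, d in diaries.items() if d.has_pleasure_scores()}
    for pid in diaries:
        if pid not in scored:
            log.append(
                f"{pid}: no pleasure scores; included in descriptives, "
                "excluded from PS-dependent analyses"
            )

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:  # keep later stages running
                errors[name] = f"{type(exc).__name__}: {exc}"
                log.append(f"stage {name} FAILED: {errors[name]}")
        return deco

    # --- descriptives -----------------------------------------------------
    @stage("demographics")
    def _demographics():
        rows = []
        for pid, d in diaries.items():
            rows.append(
                {
                    "patient_id": pid,
                    "days": len(d.reporting_days),
                    "activities": d.n_activities,
                    "compliance_pct": round(100 * compliance_rate(d)),
                    "pleasure_scores": pid in scored,
                }
            )
        df = pd.DataFrame(rows).set_index("patient_id")
        df.to_csv(out / "demographics.csv")
        report["demographics"] = df

    @stage("category_distribution")
    def _distribution():
        rows = {}
        for pid, d in diaries.items():
            dist = descriptives.category_distribution(d)
            rows[pid] = {c.name: v for c, v in dist.rounded().items()}
        pooled = descriptives.pooled_category_distribution(diaries.values())
        rows["pooled"] = {c.name: v for c, v in pooled.rounded().items()}
        df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("patient_id")
        df.to_csv(out / "category_distribution.csv")
        report["category_distribution"] = df

    @stage("ps_by_category")
    def _ps_by_category():
        if not scored:
            log.append("ps_by_category skipped: no scored diaries")
            return
        df = descriptives.ps_by_category(scored.values())
        df.to_csv(out / "ps_by_category.csv")
        report["ps_by_category"] = df

    # --- good/worse days ---------------------------------------------------
    @stage("goodworse")
    def _goodworse():
        rows = []
        for pid, d in diaries.items():
            table = goodworse.category_goodworse_table(
                d, alpha=config.alpha, pairing=config.pairing
            )
            if table.skipped:
                rows.append({"patient_id": pid, "skipped": table.skipped_reason})
                continue
            summaries = descriptives.daily_summaries(d)
            for cat, res in table.results.items():
                good, worse = goodworse.weighted_category_hours(
                    table.split, summaries, cat
                )
                rows.append(
                    {
                        "patient_id": pid,
                        "category": cat.name,
                        "mean_weighted_good": float(pd.Series(good).mean())
                        if good else float("nan"),
                        "mean_weighted_worse": float(pd.Series(worse).mean())
                        if worse else float("nan"),
                        "z": res.z,
                        "p": res.p,
                        "n_pairs": res.n_pairs,
                        "significant": res.significant(config.alpha),
                        "skipped": None,
                    }
                )
        df = pd.DataFrame(rows)
        df.to_csv(out / "goodworse.csv", index=False)
        report["goodworse"] = df

    # --- diurnal rhythm -----------------------------------------------------
    @stage("diurnal")
    def _diurnal():
        templates = {}
        all_pairs = []
        for pid, d in scored.items():
            tpl = diurnal.build_template(d)
            templates[pid] = tpl
            all_pairs.extend(
                diurnal.adherence_change_pairs(
                    d, tpl,
                    denominator=config.jac_denominator,
                    consecutive_only=config.consecutive_only,
                )
            )
        if templates:
            pd.concat(
                [t.as_frame().assign(patient_id=pid) for pid, t in templates.items()]
            ).to_csv(out / "templates.csv", index=False)
        report["templates"] = templates
        pairs_df = pd.DataFrame(
            [
                {"patient_id": p.patient_id, "date": p.date_x,
                 "jac": p.jac, "delta_ps": p.delta_ps}
                for p in all_pairs
            ]
        )
        pairs_df.to_csv(out / "adherence_pairs.csv", index=False)
        report["adherence_pairs"] = all_pairs
        if len(all_pairs) >= 3:
            res = diurnal.within_subject_ancova(all_pairs)
            per_subject = {}
            for pid in sorted({p.patient_id for p in all_pairs}):
                try:
                    r, p = diurnal.per_subject_correlation(all_pairs, pid)
                    per_subject[pid] = {"correlation": r, "p": p}
                except ValueError as exc:
                    per_subject[pid] = {"error": str(exc)}
            payload = {
                "correlation": res.correlation,
                "p": res.p,
                "beta_jac": res.beta_jac,
                "jac_zero": res.jac_zero,
                "n_obs": res.n_obs,
                "subject_intercepts": res.subject_intercepts,
                "per_subject": per_subject,
            }
            with open(out / "ancova.json", "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=2)
            report["ancova"] = res
        else:
            log.append("ANCOVA skipped: fewer than 3 adherence pairs")

    # --- dose-response -------------------------------------------------------
    @stage("dose_response")
    def _dose():
        rows = []
        category = ActivityCategory.from_label(config.dose_category)
        for cat in ActivityCategory:
            points = dose_response.daily_dose_points(scored.values(), cat)
            try:
                fit = dose_response.fit_dose_response(points, alpha=config.alpha)
            except ValueError as exc:
                rows.append({"category": cat.name, "error": str(exc)})
                continue
            rows.append(
                {
                    "category": cat.name,
                    "model_order": fit.model_order,
                    "beta0": fit.beta0,
                    "beta1": fit.beta1,
                    "beta2": fit.beta2,
                    "quad_beta2": fit.quadratic_betas[2],
                    "quad_t2": fit.quadratic_t2,
                    "quad_p2": fit.quadratic_p2,
                    "df": fit.df,
                    "argmax_hours": fit.argmax_hours,
                    "n_points": fit.n_points,
                }
            )
            if cat is category:
                report["dose_fit"] = fit
                bins = dose_response.hour_bin_quantiles(points)
                bins.to_csv(out / f"{cat.name.lower()}_hour_bins.csv")
                report["hour_bins"] = bins
        df = pd.DataFrame(rows)
        df.to_csv(out / "dose_response.csv", index=False)
        report["dose_response"] = df

    (out / "pipeline_log.txt").write_text("\n".join(log) + "\n", encoding="utf-8")
    report["log"] = log
    return report
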