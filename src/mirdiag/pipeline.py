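"""End-to-end runs: train, validate and classify-only.

A run reads a raw Ct table, applies triplicate QC, computes the configured
ΔCt score, then either fits the Gaussian Bayes classifier and solves its
thresholds (train), applies a previously fitted model/thresholds and
evaluates (validate), or assigns boxes without any labels (classify).  All
stages write plain-text artifacts (TSV/JSON) to the output directory and
the whole run is reproducible from config + input + seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .classifier import (ClassCall, GaussianClassModel, ThresholdSet,
                         classify_sample, bayes_max_accuracy, fit_model,
                         solve_thresholds)
from .errors import ConfigurationError, InsufficientDataError
from .evaluation import (classification_metrics, confusion_table,
                         empirical_roc_auc, normalizer_stability,
                         separation_t_test, stage_anova)
from .qc import QCParams, qc_cohort, verdicts_to_frame, OUTLIER, PASS, PASS_AFTER_REMOVAL
from .scores import get_score_spec, score_table
from .simulate import read_ct_table

MODES = ("train", "validate", "classify")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML/JSON loadable)."""

    mode: str
    input_path: str
    score: str = "dct375"
    qc: QCParams = field(default_factory=QCParams)
    priors: Any = "equal"
    odds_level: float = 9.0
    thresholds: tuple[float, float, float] | None = None
    model_path: str | None = None
    outdir: str | None = None
    seed: int = 0
    score_outliers: bool = False
    normalizer_assay: str = "U6"
    write_figures: bool = False

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "train" and self.thresholds is not None:
            raise ConfigurationError("thresholds override is only legal in "
                                     "validate/classify modes")
        if self.mode in ("validate", "classify") and self.thresholds is None \
                and self.model_path is None:
            raise ConfigurationError(
                f"{self.mode} mode requires --thresholds or a fitted model")
        self.qc.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.thresholds is not None:
            d["thresholds"] = list(self.thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("qc"), dict):
            d["qc"] = QCParams(**d["qc"])
        if d.get("thresholds") is not None:
            d["thresholds"] = tuple(float(t) for t in d["thresholds"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)


def _prepare(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, list, pd.DataFrame]:
    """Shared front end: read table, QC, score. Returns (table, cleaned, verdicts, scores)."""
    table = read_ct_table(config.input_path)
    if len(table) == 0:
        raise InsufficientDataError(f"{config.input_path}: empty Ct table")
    spec = get_score_spec(config.score)
    cleaned, verdicts = qc_cohort(table, config.qc,
                                  required_assays=spec.assays,
                                  keep_outliers=config.score_outliers)
    # samples lacking a mean for a score assay cannot be scored even when
    # outliers are kept
    scoreable = cleaned.dropna(subset=[a for a in spec.assays if a in cleaned.columns])
    missing_assay = [a for a in spec.assays if a not in cleaned.columns]
    if missing_assay:
        raise InsufficientDataError(
            f"assays {missing_assay} absent from the cohort; cannot compute "
            f"score {spec.name!r}")
    scores = score_table(scoreable, [spec])
    return table, cleaned, verdicts, scores


def _qc_summary(verdicts) -> dict:
    counts = {PASS: 0, PASS_AFTER_REMOVAL: 0, OUTLIER: 0}
    for v in verdicts:
        counts[v.status] += 1
    return counts


def _calls_for(scores: pd.DataFrame, thresholds: ThresholdSet,
               model: GaussianClassModel | None) -> list[ClassCall]:
    return [classify_sample(rec["value"], thresholds, model,
                            sample_id=rec["sample_id"],
                            qc_outlier=bool(rec["qc_outlier"]))
            for _, rec in scores.iterrows()]


def _evaluate(scores: pd.DataFrame, calls: list[ClassCall], cleaned: pd.DataFrame,
              model: GaussianClassModel | None, config: RunConfig,
              class_a: str, class_b: str) -> dict:
    """Confusion table + metrics + ROC + t-test + stage ANOVA + normalizer."""
    subtypes = dict(zip(scores["sample_id"], scores["subtype"]))
    class_map = {s: c for s, c in zip(scores["subtype"], scores["class"])}
    ct = confusion_table(calls, subtypes, class_map, class_a, class_b)
    metrics = classification_metrics(ct)
    labels = scores["class"].to_numpy()
    values = scores["value"].to_numpy()
    _, metrics.auc = empirical_roc_auc(values, labels, pos_label=class_b)
    metrics.t_statistic, metrics.t_pvalue = separation_t_test(values, labels)
    anova = {}
    for cls in (class_a, class_b):
        sub = scores[scores["class"] == cls]
        try:
            f, p = stage_anova(sub["value"], sub["stage"])
            anova[cls] = {"F": f, "p": p}
        except InsufficientDataError:
            anova[cls] = None
    metrics.anova = anova
    if config.normalizer_assay in cleaned.columns:
        sub = cleaned.dropna(subset=[config.normalizer_assay])
        try:
            metrics.normalizer = normalizer_stability(
                sub[config.normalizer_assay], sub["class"],
                class_a, class_b).to_dict()
        except InsufficientDataError:
            metrics.normalizer = None
    return {"confusion": {"counts": {s: ct.counts.loc[s].to_dict()
                                     for s in ct.counts.index},
                          "class_map": ct.class_map},
            "metrics": metrics.to_dict(),
            "_confusion_obj": ct, "_metrics_obj": metrics}


def _classes_from(scores: pd.DataFrame, model: GaussianClassModel | None):
    if model is not None:
        return model.class_a, model.class_b
    labels = [c for c in scores["class"].unique() if c]
    if len(labels) != 2:
        raise InsufficientDataError(
            f"need exactly 2 class labels for evaluation, got {labels}")
    by_mean = scores.groupby("class")["value"].mean().sort_values()
    return by_mean.index[0], by_mean.index[1]


def _base_report(config: RunConfig) -> dict:
    import datetime
    return {"config": config.to_dict(), "version": __version__,
            "timestamp": datetime.datetime.now().isoformat(timespec="seconds")}


def run_train(config: RunConfig) -> dict:
    """QC → score → fit → solve thresholds → classify and evaluate the training set."""
    config.validate()
    table, cleaned, verdicts, scores = _prepare(config)
    train_scores = scores[~scores["qc_outlier"]] if config.score_outliers else scores
    model = fit_model(train_scores["value"], train_scores["class"],
                      priors=config.priors)
    thresholds = solve_thresholds(model, config.odds_level)
    calls = _calls_for(scores, thresholds, model)
    report = _base_report(config)
    report.update({
        "mode": "train",
        "qc_summary": _qc_summary(verdicts),
        "n_samples_input": int(table["sample_id"].nunique()),
        "n_samples_scored": int(scores["sample_id"].nunique()),
        "excluded_samples": sorted(set(table["sample_id"])
                                   - set(scores["sample_id"])),
        "model": model.to_dict(),
        "thresholds": thresholds.to_dict(),
        "bayes_max_accuracy": bayes_max_accuracy(model),
        "calls": [c.to_dict() for c in calls],
    })
    report.update(_evaluate(scores, calls, cleaned, model, config,
                            model.class_a, model.class_b))
    _write_artifacts(report, config, verdicts, scores, model, thresholds)
    return report


def run_validate(config: RunConfig) -> dict:
    """Apply a previously fitted model/thresholds to a labeled cohort; no refit."""
    config.validate()
    model = GaussianClassModel.from_json(config.model_path) \
        if config.model_path else None
    if config.thresholds is not None:
        thresholds = ThresholdSet(*config.thresholds, odds_level=config.odds_level)
    elif model is not None:
        thresholds = solve_thresholds(model, config.odds_level)
    else:  # unreachable after validate()
        raise ConfigurationError("validate mode requires thresholds or a model")
    table, cleaned, verdicts, scores = _prepare(config)
    calls = _calls_for(scores, thresholds, model)
    class_a, class_b = _classes_from(scores, model)
    report = _base_report(config)
    report.update({
        "mode": "validate",
        "qc_summary": _qc_summary(verdicts),
        "n_samples_input": int(table["sample_id"].nunique()),
        "n_samples_scored": int(scores["sample_id"].nunique()),
        "excluded_samples": sorted(set(table["sample_id"])
                                   - set(scores["sample_id"])),
        "model": model.to_dict() if model else None,
        "thresholds": thresholds.to_dict(),
        "calls": [c.to_dict() for c in calls],
    })
    report.update(_evaluate(scores, calls, cleaned, model, config, class_a, class_b))
    _write_artifacts(report, config, verdicts, scores, model, thresholds)
    return report


def run_classify(config: RunConfig) -> dict:
    """Assign odds boxes to unlabeled (or third-class) samples; no metrics.

    The per-box fractions summarise whether the cohort clusters in any
    decision region (a dispersed spread across boxes means the classifier
    does not resolve the group).
    """
    config.validate()
    model = GaussianClassModel.from_json(config.model_path) \
        if config.model_path else None
    if config.thresholds is not None:
        thresholds = ThresholdSet(*config.thresholds, odds_level=config.odds_level)
    else:
        thresholds = solve_thresholds(model, config.odds_level)
    table, cleaned, verdicts, scores = _prepare(config)
    calls = _calls_for(scores, thresholds, model)
    n = len(calls)
    fractions = {box: sum(c.box == box for c in calls) / n for box in
                 ("strong_a", "weak_a", "weak_b", "strong_b")} if n else {}
    report = _base_report(config)
    report.update({
        "mode": "classify",
        "qc_summary": _qc_summary(verdicts),
        "n_samples_input": int(table["sample_id"].nunique()),
        "n_samples_scored": int(scores["sample_id"].nunique()),
        "excluded_samples": sorted(set(table["sample_id"])
                                   - set(scores["sample_id"])),
        "model": model.to_dict() if model else None,
        "thresholds": thresholds.to_dict(),
        "calls": [c.to_dict() for c in calls],
        "box_fractions": fractions,
    })
    _write_artifacts(report, config, verdicts, scores, model, thresholds)
    return report


def run(config: RunConfig) -> dict:
    return {"train": run_train, "validate": run_validate,
            "classify": run_classify}[config.mode](config)


def report_without_timestamp(report: dict) -> dict:
    out = dict(report)
    out.pop("timestamp", None)
    out.pop("_confusion_obj", None)
    out.pop("_metrics_obj", None)
    return out


def write_report_json(report: dict, path: str | Path) -> None:
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    Path(path).write_text(json.dumps(clean, indent=2, default=float) + "\n")


def render_report_text(report: dict) -> str:
    """Human-readable one-page summary of a run."""
    lines = [f"mirdiag {report.get('version', '')} — {report.get('mode', '?')} run",
             f"input: {report['config']['input_path']}",
             f"samples: {report.get('n_samples_input')} in, "
             f"{report.get('n_samples_scored')} scored"]
    qc = report.get("qc_summary", {})
    lines.append(f"QC triplicates: {qc.get('pass', 0)} pass, "
                 f"{qc.get('pass_after_removal', 0)} repaired, "
                 f"{qc.get('outlier', 0)} outlier")
    thr = report.get("thresholds")
    if thr:
        lines.append(f"thresholds: chi10:90={thr['chi_low']:.3f}  "
                     f"chi={thr['chi_mid']:.3f}  chi90:10={thr['chi_high']:.3f}")
    if report.get("model"):
        m = report["model"]
        lines.append(f"model: {m['class_a']} N({m['mu_a']:.2f}, {m['sigma_a']:.2f}^2)"
                     f" vs {m['class_b']} N({m['mu_b']:.2f}, {m['sigma_b']:.2f}^2)")
    if report.get("bayes_max_accuracy") is not None:
        lines.append(f"predicted maximum (Bayes) accuracy: "
                     f"{100 * report['bayes_max_accuracy']:.1f}%")
    met = report.get("metrics")
    if met:
        lines.append(f"accuracy: {met['accuracy_all']:.1f}%  "
                     f"rate(class a): {met['rate_class_a']:.1f}%  "
                     f"rate(class b): {met['rate_class_b']:.1f}%")
        lines.append(f"high-reliability accuracy: "
                     f"{met['accuracy_high_reliability']:.1f}% "
                     f"({met['n_high_reliability']} confident calls)")
        if met.get("auc") is not None:
            lines.append(f"AUC: {met['auc']:.3f}")
    if report.get("box_fractions"):
        frac = "  ".join(f"{k}={v:.2f}" for k, v in report["box_fractions"].items())
        lines.append(f"box fractions: {frac}")
    return "\n".join(lines) + "\n"


def _write_artifacts(report: dict, config: RunConfig, verdicts, scores,
                     model, thresholds) -> None:
    if not config.outdir:
        return
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_report_json(report, outdir / "report.json")
    (outdir / "report.txt").write_text(render_report_text(report))
    verdicts_to_frame(verdicts).to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
    if model is not None:
        model.to_json(outdir / "model.json")
    thresholds.to_json(outdir / "thresholds.json")
    if "calls" in report:
        pd.DataFrame(report["calls"]).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    if "_confusion_obj" in report:
        report["_confusion_obj"].to_tsv(outdir / "confusion.tsv")
    if report.get("metrics") and report["metrics"].get("auc") is not None:
        labels = scores["class"].to_numpy()
        points, _ = empirical_roc_auc(scores["value"].to_numpy(), labels,
                                      pos_label=_classes_from(scores, model)[1])
        points.to_csv(outdir / "roc.tsv", sep="\t", index=False)
    if config.write_figures:
        from . import plots
        plots.write_run_figures(report, scores, outdir)
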