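"""Optional figures: ranked score scatter with threshold lines, per-class
Gaussian density fits, and the empirical ROC curve."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from scipy.stats import norm  # noqa: E402

from .classifier import GaussianClassModel, ThresholdSet  # noqa: E402
from .evaluation import empirical_roc_auc  # noqa: E402


def rank_scatter(scores, classes, thresholds: ThresholdSet, ax=None):
    """Samples ordered by decreasing score with the three cut lines."""
    ax = ax or plt.gca()
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    x = np.arange(1, len(order) + 1)
    y = np.asarray(scores, dtype=float)[order]
    cls = np.asarray(classes)[order]
    for c, color in zip(np.unique(cls), ("tab:blue", "tab:red", "tab:green")):
        m = cls == c
        ax.scatter(x[m], y[m], s=18, label=str(c), color=color)
    for value, name in ((thresholds.chi_low, "chi 10:90"),
                        (thresholds.chi_mid, "chi"),
                        (thresholds.chi_high, "chi 90:10")):
        ax.axhline(value, ls="--", lw=0.8, color="gray")
        ax.annotate(name, (len(x), value), fontsize=7, va="bottom")
    ax.set_xlabel("sample rank (decreasing score)")
    ax.set_ylabel("score")
    ax.legend(fontsize=8)
    return ax


def density_fit(scores, classes, model: GaussianClassModel | None = None, ax=None):
    """Per-class histograms with fitted Gaussian curves."""
    ax = ax or plt.gca()
    scores = np.asarray(scores, dtype=float)
    classes = np.asarray(classes)
    grid = np.linspace(scores.min() - 1, scores.max() + 1, 400)
    for c, color in zip(np.unique(classes), ("tab:blue", "tab:red")):
        vals = scores[classes == c]
        ax.hist(vals, bins="auto", density=True, alpha=0.35, color=color, label=str(c))
        if model is not None:
            mu, sd = ((model.mu_a, model.sigma_a) if str(c) == model.class_a
                      else (model.mu_b, model.sigma_b))
            ax.plot(grid, norm.pdf(grid, mu, sd), color=color, lw=1.5)
    ax.set_xlabel("score")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    return ax


def roc_plot(scores, labels, pos_label, ax=None):
    ax = ax or plt.gca()
    points, auc = empirical_roc_auc(scores, labels, pos_label)
    ax.plot(points["fpr"], points["tpr"], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls=":", color="gray", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"AUC = {auc:.2f}", fontsize=9)
    return ax


def write_run_figures(report: dict, scores, outdir) -> None:
    """Write the scatter/density/ROC panels for a pipeline run."""
    outdir = Path(outdir)
    thr = ThresholdSet.from_dict(report["thresholds"])
    model = (GaussianClassModel.from_dict(report["model"])
             if report.get("model") else None)
    values = scores["value"].to_numpy()
    classes = scores["class"].to_numpy()

    fig, ax = plt.subplots(figsize=(5, 3.2))
    rank_scatter(values, classes, thr, ax=ax)
    fig.tight_layout()
    fig.savefig(outdir / "rank_scatter.png", dpi=120)
    plt.close(fig)

    labeled = classes != ""
    if labeled.sum() and len(np.unique(classes[labeled])) == 2:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        density_fit(values[labeled], classes[labeled], model, ax=ax)
        fig.tight_layout()
        fig.savefig(outdir / "density_fit.png", dpi=120)
        plt.close(fig)

        if model is not None:
            fig, ax = plt.subplots(figsize=(3.6, 3.4))
            roc_plot(values[labeled], classes[labeled], model.class_b, ax=ax)
            fig.tight_layout()
            fig.savefig(outdir / "roc.png", dpi=120)
            plt.close(fig)
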