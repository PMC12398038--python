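"""Kaplan–Meier and ROC plots (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .score_application import KMEstimate, RocResult

__all__ = ["plot_km", "plot_roc"]


def plot_km(estimates: dict[str, KMEstimate], path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, est in estimates.items():
        ax.step([0, *est.times], [1.0, *est.survival], where="post", label=name)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title="group")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(roc: RocResult, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(roc.fpr, roc.tpr, label=f"AUC = {roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
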