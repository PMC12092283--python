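"""Simple score and trajectory figures (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .containers import ARMS, VISIT_WEEKS
from .score_stats import SlopeFit

ARM_COLORS = {"placebo": "black", "felzartamab": "crimson"}


def plot_trajectories(table, fit: SlopeFit, out_path=None):
    """Per-patient score trajectories with the fitted population lines and
    95% confidence bands, one color per arm."""
    d = table.long(fit.score)
    fig, ax = plt.subplots(figsize=(5, 4))
    for pat, grp in d.groupby("patient_id"):
        grp = grp.sort_values("week")
        ax.plot(grp["week"], grp["score"], color=ARM_COLORS[grp["arm"].iloc[0]], alpha=0.3, lw=0.8)
    traj = fit.predict()
    for arm in ARMS:
        sub = traj[traj["arm"] == arm]
        ax.plot(sub["week"], sub["fit"], color=ARM_COLORS[arm], lw=2.2, label=arm)
        ax.fill_between(sub["week"], sub["lo"], sub["hi"], color=ARM_COLORS[arm], alpha=0.15)
    ax.set_xlabel("weeks since trial start")
    ax.set_ylabel(fit.score)
    ax.set_xticks(sorted(VISIT_WEEKS.values()))
    ax.legend(frameon=False)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def plot_score_by_visit(table, score: str, out_path=None):
    """Individual scores per arm and visit with per-arm medians joined."""
    d = table.long(score)
    fig, ax = plt.subplots(figsize=(5, 4))
    offsets = {"placebo": -1.5, "felzartamab": 1.5}
    for arm, grp in d.groupby("arm"):
        weeks = grp["week"] + offsets[arm]
        ax.scatter(weeks, grp["score"], s=14, color=ARM_COLORS[arm], alpha=0.6, label=arm)
        med = grp.groupby("week")["score"].median()
        ax.plot(med.index + offsets[arm], med.values, color=ARM_COLORS[arm], ls="--", lw=1.5)
    ax.set_xlabel("weeks since trial start")
    ax.set_ylabel(score)
    ax.set_xticks(sorted(VISIT_WEEKS.values()))
    ax.legend(frameon=False)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
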