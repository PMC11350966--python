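"""Report figures: session means, contrasting-groups curves, box plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats as sps

from .scoring import participant_mean_composites

_COLORS = {"novice": "tab:red", "experienced": "black"}


def plot_session_means(score_table, path) -> None:
    """Composite EM means per group per session with 95% CIs."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for grp, sub in score_table.groupby("group"):
        xs, ms, los, his = [], [], [], []
        for sess, s2 in sub.groupby("session"):
            pm = s2.groupby("participant_id")["composite"].mean()
            m = pm.mean()
            se = pm.std(ddof=1) / np.sqrt(len(pm))
            t = sps.t.ppf(0.975, len(pm) - 1)
            xs.append(sess)
            ms.append(m)
            los.append(m - t * se)
            his.append(m + t * se)
        ax.errorbar(
            xs,
            ms,
            yerr=[np.array(ms) - np.array(los), np.array(his) - np.array(ms)],
            marker="o",
            capsize=4,
            label=grp,
            color=_COLORS.get(grp),
        )
    ax.set_xticks([1, 2])
    ax.set_xlabel("Session")
    ax.set_ylabel("Composite z-score (EM mean)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_contrasting_groups(report, path) -> None:
    """Fitted group densities of mean composites and the standard."""
    std = report.standard
    mn, sn = std.novice_fit
    me, se = std.experienced_fit
    lo = min(me - 3.5 * se, mn - 3.5 * sn)
    hi = max(me + 3.5 * se, mn + 3.5 * sn)
    x = np.linspace(lo, hi, 400)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(x, sps.norm.pdf(x, mn, sn), color=_COLORS["novice"], label="novice")
    ax.plot(
        x, sps.norm.pdf(x, me, se), color=_COLORS["experienced"], label="experienced"
    )
    ax.axvline(std.cutpoint, ls=":", lw=2, color="k", label=f"standard {std.cutpoint:.2f}")
    for b in std.ci95:
        ax.axvline(b, ls=":", lw=0.8, color="gray")
    ax.set_xlabel("Mean composite z-score")
    ax.set_ylabel("Density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mean_composite_box(score_table, report, path) -> None:
    """Box plot of participant mean composites by group, with the standard."""
    means = participant_mean_composites(score_table)
    fig, ax = plt.subplots(figsize=(4, 4))
    data, labels = [], []
    for grp in ("novice", "experienced"):
        data.append(means[means["group"] == grp]["mean_composite"].dropna().to_numpy())
        labels.append(grp)
    ax.boxplot(data, tick_labels=labels)
    ax.axhline(report.standard.cutpoint, ls=":", lw=2, color="k")
    ax.set_ylabel("Mean composite z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
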