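"""Standard figures for a webRDS run: recruitment-chain trees, cumulative
submissions over time, composition-stabilisation curves, and sample-vs-
estimate bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .forest import RecruitmentForest

_PNG_META = {"Software": None}  # reproducible bytes across runs


def _save(fig, path):
    fig.savefig(path, dpi=110, metadata=_PNG_META)
    plt.close(fig)


def plot_recruitment_chains(forest: RecruitmentForest, path) -> None:
    """Fan-out view of every recruitment chain, one colour per chain,
    node depth = wave."""
    fig, ax = plt.subplots(figsize=(9, 5))
    roots = sorted(forest.seeds, key=str)
    cmap = plt.get_cmap("tab20")
    children = forest.children()
    x_cursor = [0.0]

    def layout(node, depth, positions):
        kids = sorted(children[node], key=str)
        if not kids:
            positions[node] = (x_cursor[0], depth)
            x_cursor[0] += 1.0
            return positions[node][0]
        xs = [layout(c, depth + 1, positions) for c in kids]
        positions[node] = (float(np.mean(xs)), depth)
        return positions[node][0]

    for i, root in enumerate(roots):
        positions: dict = {}
        layout(root, 0, positions)
        color = cmap(i % 20)
        for node, (x, y) in positions.items():
            p = forest.parent[node]
            if p is not None:
                px, py = positions[p]
                ax.plot([px, x], [py, y], color=color, lw=0.6, zorder=1)
        xs = [p[0] for p in positions.values()]
        ys = [p[1] for p in positions.values()]
        ax.scatter(xs, ys, s=6, color=color, zorder=2)
        x_cursor[0] += 2.0
    ax.invert_yaxis()
    ax.set_ylabel("wave")
    ax.set_xticks([])
    ax.set_title("Recruitment chains")
    _save(fig, path)


def plot_cumulative_submissions(cumulative_by_day: dict, path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    days = sorted(cumulative_by_day)
    ax.step(days, [cumulative_by_day[d] for d in days], where="post")
    ax.set_xlabel("day of study")
    ax.set_ylabel("cumulative submissions")
    ax.set_title("Cumulative submissions over time")
    _save(fig, path)


def plot_running_composition(curves: pd.DataFrame, path, max_panels: int = 6) -> None:
    """Stabilisation curves: RDSII estimate per category vs sample size."""
    variables = sorted(curves["variable"].unique())[:max_panels]
    ncols = min(3, len(variables))
    nrows = int(np.ceil(len(variables) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4.5 * ncols, 3.2 * nrows), squeeze=False)
    for ax, var in zip(axes.ravel(), variables):
        sub = curves[curves["variable"] == var]
        for cat, grp in sub.groupby("category"):
            ax.plot(grp["sample_size"], grp["rdsii_estimate"], label=str(cat)[:14], lw=1.2)
        ax.set_title(var, fontsize=9)
        ax.set_ylim(0, 1)
        ax.legend(fontsize=6)
    for ax in axes.ravel()[len(variables):]:
        ax.axis("off")
    fig.supxlabel("sample size")
    fig.supylabel("RDSII estimated proportion")
    fig.tight_layout()
    _save(fig, path)


def plot_sample_vs_estimate(estimates: pd.DataFrame, path, max_panels: int = 6) -> None:
    """Grouped bars: raw sample proportion vs RDSII population estimate."""
    variables = sorted(estimates["variable"].unique())[:max_panels]
    ncols = min(3, len(variables))
    nrows = int(np.ceil(len(variables) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4.5 * ncols, 3.2 * nrows), squeeze=False)
    for ax, var in zip(axes.ravel(), variables):
        sub = estimates[estimates["variable"] == var]
        x = np.arange(len(sub))
        ax.bar(x - 0.2, sub["sample_proportion"], width=0.4, label="sample")
        ax.bar(x + 0.2, sub["rdsii_estimate"], width=0.4, label="RDSII")
        ax.set_xticks(x, [str(c)[:10] for c in sub["category"]], rotation=30, fontsize=6)
        ax.set_title(var, fontsize=9)
        ax.legend(fontsize=6)
    for ax in axes.ravel()[len(variables):]:
        ax.axis("off")
    fig.tight_layout()
    _save(fig, path)
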