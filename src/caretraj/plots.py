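"""Sequence-analysis graphics: state distribution, index and frequency plots.

Every plot writes a companion CSV with the numbers behind it, so plotted
quantities are testable without parsing images.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model import DEAD, INCAP, NR, Cohort

# Overlays drawn on top of the utilization bands, darkest last.
_OVERLAY_COLOURS = {"NR": "#d9d9d9", "INCAP": "#8c6bb1", "DEAD": "#252525"}
_LEVEL_CMAP = plt.get_cmap("YlOrRd")


def _state_order(spec):
    return [spec.decode(c) for c in range(spec.k)] + ["NR", "INCAP", "DEAD"]


def state_distribution_table(cohort: Cohort) -> pd.DataFrame:
    """Per-channel, per-wave shares of every state (levels + overlays)."""
    rows = []
    for j, spec in enumerate(cohort.specs):
        ch = cohort.states[:, :, j]
        for code, label in [(c, spec.decode(c)) for c in range(spec.k)] + [
            (NR, "NR"),
            (INCAP, "INCAP"),
            (DEAD, "DEAD"),
        ]:
            share = (ch == code).mean(axis=0)
            for w, v in enumerate(share, start=1):
                rows.append(
                    {"channel": spec.name, "state": label, "wave": w, "share": float(v)}
                )
    return pd.DataFrame(rows)


def _colours(spec):
    cols = [_LEVEL_CMAP(0.15 + 0.7 * i / max(spec.k - 1, 1)) for i in range(spec.k)]
    cols[0] = "#c7e9c0"  # "none" stands apart from the utilization gradient
    return cols + [_OVERLAY_COLOURS["NR"], _OVERLAY_COLOURS["INCAP"], _OVERLAY_COLOURS["DEAD"]]


def plot_state_distribution(
    cohort: Cohort, out_path, labels=None, title: str | None = None
) -> Path:
    """Stacked per-wave state shares, one panel per channel.

    With cluster ``labels`` given, one row of panels per cluster (the
    per-cluster analogue used to describe a trajectory typology).
    """
    out_path = Path(out_path)
    groups = [(None, cohort)]
    if labels is not None:
        labels = np.asarray(labels)
        groups = [
            (g, cohort.subset(np.flatnonzero(labels == g))) for g in np.unique(labels)
        ]
    nrow, ncol = len(groups), len(cohort.specs)
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3.0 * ncol, 2.4 * nrow), squeeze=False, sharey=True
    )
    tables = []
    for r, (g, sub) in enumerate(groups):
        table = state_distribution_table(sub)
        if g is not None:
            table.insert(0, "cluster", g)
        tables.append(table)
        for c, spec in enumerate(sub.specs):
            ax = axes[r][c]
            tt = table[table.channel == spec.name]
            waves = np.arange(1, sub.n_waves + 1)
            bottom = np.zeros(sub.n_waves)
            for state, colour in zip(_state_order(spec), _colours(spec)):
                share = tt[tt.state == state].sort_values("wave")["share"].values
                ax.bar(waves, share, bottom=bottom, width=1.0, color=colour,
                       label=state if r == 0 else None)
                bottom += share
            if r == 0:
                ax.set_title(spec.name, fontsize=9)
            if c == 0:
                ax.set_ylabel(f"cluster {g}" if g is not None else "share", fontsize=8)
            ax.set_xlim(0.5, sub.n_waves + 0.5)
            ax.set_ylim(0, 1)
            ax.tick_params(labelsize=7)
    fig.suptitle(title or "State distribution by wave", fontsize=11)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    pd.concat(tables).to_csv(out_path.with_suffix(".csv"), index=False)
    return out_path


def sequence_frequency_table(cohort: Cohort, channel: str, top: int = 10) -> pd.DataFrame:
    """The ``top`` most frequent single-channel sequences and their shares."""
    j = [s.name for s in cohort.specs].index(channel)
    spec = cohort.specs[j]
    seqs = ["-".join(spec.decode(c) for c in row) for row in cohort.states[:, :, j]]
    counts = pd.Series(seqs).value_counts()
    out = counts.head(top).rename("count").to_frame()
    out["share"] = out["count"] / cohort.n
    out.index.name = "sequence"
    return out.reset_index()


def plot_index_and_frequency(
    cohort: Cohort,
    out_prefix,
    top: int = 10,
    order: np.ndarray | None = None,
) -> list[Path]:
    """Index plot (one row per individual) and sequence frequency plot.

    ``order`` optionally reorders individuals (e.g. by cluster then by
    distance to the cluster medoid); default is cohort order.
    """
    out_prefix = Path(out_prefix)
    order = np.arange(cohort.n) if order is None else np.asarray(order)
    paths = []

    ncol = len(cohort.specs)
    fig, axes = plt.subplots(1, ncol, figsize=(3.0 * ncol, 4.0), squeeze=False)
    for c, spec in enumerate(cohort.specs):
        ax = axes[0][c]
        img = cohort.states[order, :, c].astype(float)
        img[img == NR] = spec.k
        img[img == INCAP] = spec.k + 1
        img[img == DEAD] = spec.k + 2
        cmap = matplotlib.colors.ListedColormap(_colours(spec))
        ax.imshow(img, aspect="auto", interpolation="nearest", cmap=cmap,
                  vmin=-0.5, vmax=spec.k + 2.5)
        ax.set_title(spec.name, fontsize=9)
        ax.set_xticks([0, cohort.n_waves - 1], [1, cohort.n_waves])
        ax.set_yticks([])
    fig.suptitle("Index plot (one row per individual)", fontsize=11)
    fig.tight_layout()
    p = out_prefix.with_name(out_prefix.name + "_index.png")
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)

    fig, axes = plt.subplots(1, ncol, figsize=(3.2 * ncol, 3.2), squeeze=False)
    tables = []
    for c, spec in enumerate(cohort.specs):
        tt = sequence_frequency_table(cohort, spec.name, top=top)
        tt.insert(0, "channel", spec.name)
        tables.append(tt)
        ax = axes[0][c]
        ax.barh(np.arange(len(tt))[::-1], tt["share"].values, color="#6baed6")
        ax.set_title(spec.name, fontsize=9)
        ax.set_xlabel("share", fontsize=8)
        ax.set_yticks([])
        ax.tick_params(labelsize=7)
    fig.suptitle(f"{top} most frequent sequences per channel", fontsize=11)
    fig.tight_layout()
    p = out_prefix.with_name(out_prefix.name + "_freq.png")
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)
    pd.concat(tables).to_csv(out_prefix.with_name(out_prefix.name + "_freq.csv"), index=False)
    return paths
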