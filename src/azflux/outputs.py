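"""Presentation surfaces: heat-map panels, time-course profiles, volcanoes.

Each figure is a thin rendering of a serialized table; the tables are the
tested artifact and re-rendering from a table is deterministic.  Heat-map
panels show the log2 AZ/NAZ block followed by the log2 time/0 block with
marker flags for >8-fold AZ-specific and >8-fold up-regulated genes;
time-course profiles plot category percent-of-transcriptome per tissue;
the volcano table carries WT/mutant log2 folds against -log10 p-values
capped at 4 (p floored at 0.0001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import differential as _diff
from .categories import CategoryProfile
from .types import AzfluxError

__all__ = [
    "HeatmapPanel",
    "VolcanoTable",
    "build_heatmap_panel",
    "build_timecourse_profile",
    "build_volcano",
    "render_heatmap",
    "render_timecourse",
    "render_volcano",
]

logger = logging.getLogger(__name__)


@dataclass
class HeatmapPanel:
    """One category's heat-map block: ratio columns plus marker flags."""

    table: pd.DataFrame  # genes x (AZ/NAZ block, then t/0 block)
    markers: pd.DataFrame  # genes x (az_specific, changed_up)
    color_bound: float  # scale is symmetric: [-bound, +bound]


@dataclass
class VolcanoTable:
    """Capped volcano coordinates for a two-genotype contrast."""

    table: pd.DataFrame  # columns: log2_fold, neg_log10_p
    cap: float
    significance_line: float  # -log10 of the significance threshold


def build_heatmap_panel(
    diff: pd.DataFrame,
    members,
    ordering: str = "max_t0_desc",
    color_bound: float = 6.0,
) -> HeatmapPanel:
    """Assemble a category's panel from the differential table.

    Columns are the AZ/NAZ-per-time block followed by the time/0 block;
    rows sorted by the ordering rule (default: descending max log2(t/0),
    ties by gene id).  Marker flags are copied from the differential flags.
    """
    members = [g for g in members if g in diff.index]
    if not members:
        logger.info("empty heat-map panel")
    az_cols = _diff.azspec_columns(diff)
    t0_cols = _diff.t0_ratio_columns(diff)
    sub = diff.loc[members, az_cols + t0_cols].astype(float)
    if ordering == "max_t0_desc" and len(sub) and t0_cols:
        key = sub[t0_cols].max(axis=1)
        sub = sub.loc[sorted(sub.index, key=lambda g: (-key[g], g))]
    markers = diff.loc[sub.index, ["az_specific", "changed_up"]].astype(bool)
    return HeatmapPanel(table=sub, markers=markers, color_bound=float(color_bound))


def build_timecourse_profile(
    profile: CategoryProfile, design, tissues: tuple[str, str]
) -> pd.DataFrame:
    """Tidy (category, time, tissue, percent) table averaging replicate samples."""
    for tissue in tissues:
        if tissue not in design.tissues:
            raise AzfluxError(f"tissue {tissue!r} missing from design")
    rows = []
    table = design.table
    for cat in profile.percent.index:
        for tissue in tissues:
            for time_h in design.timepoints:
                samples = table.loc[
                    (table["tissue"] == tissue) & (table["time_h"].astype(float) == time_h),
                    "sample_id",
                ]
                samples = [s for s in samples if s in profile.percent.columns]
                if not samples:
                    continue
                rows.append(
                    (cat, time_h, tissue, float(profile.percent.loc[cat, samples].mean()))
                )
    return pd.DataFrame(rows, columns=["category", "time_h", "tissue", "percent"])


def build_volcano(
    diff: pd.DataFrame, cap: float = 4.0, significance_p: float = 0.015
) -> VolcanoTable:
    """Volcano coordinates with -log10 p capped (p floored at 10^-cap)."""
    if cap <= 0:
        raise AzfluxError("volcano cap must be positive")
    log2_cols = _diff.t0_ratio_columns(diff)
    if len(log2_cols) != 1:
        raise AzfluxError("volcano requires a single-contrast differential table")
    fold_col = log2_cols[0]
    p_col = "p_" + fold_col[len("log2_"):]
    if p_col not in diff.columns:
        raise AzfluxError(f"missing p-value column {p_col!r}")
    neg_log_p = -np.log10(diff[p_col].astype(float))
    table = pd.DataFrame(
        {
            "log2_fold": diff[fold_col].astype(float),
            "neg_log10_p": np.minimum(neg_log_p, cap),
        },
        index=diff.index,
    )
    return VolcanoTable(
        table=table, cap=float(cap), significance_line=float(-np.log10(significance_p))
    )


# --- rendering (matplotlib; figures are a thin layer over the tables) ---


def _agg_backend():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def render_heatmap(panel: HeatmapPanel, path, title: str = "") -> None:
    plt = _agg_backend()
    n = max(len(panel.table), 1)
    fig, ax = plt.subplots(figsize=(6, max(1.5, 0.12 * n)))
    if len(panel.table):
        im = ax.imshow(
            panel.table.to_numpy(),
            aspect="auto",
            cmap="RdBu_r",
            vmin=-panel.color_bound,
            vmax=panel.color_bound,
        )
        fig.colorbar(im, ax=ax, label="log2 ratio")
        ax.set_xticks(range(panel.table.shape[1]))
        ax.set_xticklabels(panel.table.columns, rotation=90, fontsize=6)
        ax.set_yticks([])
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_timecourse(profile_table: pd.DataFrame, path, category: str | None = None) -> None:
    plt = _agg_backend()
    data = profile_table
    if category is not None:
        data = data[data["category"] == category]
    fig, ax = plt.subplots(figsize=(5, 4))
    for (cat, tissue), grp in data.groupby(["category", "tissue"], sort=False):
        marker = "o" if tissue == data["tissue"].iloc[0] else "^"
        ax.plot(grp["time_h"], grp["percent"], marker=marker, label=f"{cat} {tissue}")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("% of transcriptome")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_volcano(volcano: VolcanoTable, path) -> None:
    plt = _agg_backend()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(volcano.table["log2_fold"], volcano.table["neg_log10_p"], s=4, alpha=0.5)
    ax.axhline(volcano.significance_line, color="grey", lw=1)
    ax.set_xlabel("log2 fold change (WT/mutant)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
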