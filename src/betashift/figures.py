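"""Figure-style outputs: PCoA scatters, the site × time LCBD bubble grid,
ternary triangle plots and per-site species-contribution bars."""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .community import CommunityTable
from .dissimilarity import DecomposedDissimilarity
from .spacetime import embed_for_tests
from .strata import triangle_coordinates

__all__ = ["render_figures"]

# one fixed palette so group colors agree between the PCoA and ternary plots
_PALETTE = plt.cm.tab10.colors


def _fig_pcoa(coords, groups, path):
    fig, ax = plt.subplots(figsize=(6, 5))
    levels = pd.unique(groups)
    for i, lev in enumerate(levels):
        m = groups == lev
        ax.scatter(coords[m, 0], coords[m, 1], s=12, alpha=0.7,
                   color=_PALETTE[i % len(_PALETTE)], label=str(lev))
    ax.set_xlabel("PCoA 1")
    ax.set_ylabel("PCoA 2")
    ax.legend(title="group", fontsize=8)
    ax.set_title("PCoA of √(percentage difference)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig_lcbd(lcbd_df, meta, path, alpha=0.05):
    df = lcbd_df.join(meta[["site", "time"]])
    cell = df.groupby(["site", "time"])[["LCBD"]].mean().reset_index()
    if "p_value" in df.columns:
        cell = cell.merge(
            df.groupby(["site", "time"])["p_value"].min().reset_index(),
            on=["site", "time"],
        )
    sites = sorted(cell["site"].unique())
    times = sorted(cell["time"].unique())
    si = {s: i for i, s in enumerate(sites)}
    ti = {t: i for i, t in enumerate(times)}
    fig, ax = plt.subplots(figsize=(1.2 + 0.5 * len(times), 1.2 + 0.4 * len(sites)))
    max_l = cell["LCBD"].max()
    for _, row in cell.iterrows():
        x, y = ti[row["time"]], si[row["site"]]
        # circle *area* proportional to the LCBD value
        size = 300.0 * row["LCBD"] / max_l
        edge = "black" if "p_value" in cell.columns and row["p_value"] <= alpha else "none"
        ax.scatter(x, y, s=size, color="#3b7fb6", edgecolors=edge, linewidths=1.2)
    # marginal means, ×1000 as in the usual display convention
    for t in times:
        v = cell.loc[cell["time"] == t, "LCBD"].mean() * 1000
        ax.text(ti[t], len(sites) + 0.2, f"{v:.1f}", ha="center", fontsize=7)
    for s in sites:
        v = cell.loc[cell["site"] == s, "LCBD"].mean() * 1000
        ax.text(len(times) + 0.2, si[s], f"{v:.1f}", va="center", fontsize=7)
    ax.set_xticks(range(len(times)), [f"{t:g}" for t in times], rotation=90, fontsize=7)
    ax.set_yticks(range(len(sites)), sites, fontsize=7)
    ax.set_xlim(-0.8, len(times) + 1.2)
    ax.set_ylim(-0.8, len(sites) + 1.0)
    ax.set_title("LCBD per site and time (×1000 in margins)", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig_triangle(summaries, path):
    scopes = summaries["scope"].unique()
    fig, axes = plt.subplots(1, len(scopes), figsize=(5.5 * len(scopes), 5))
    axes = np.atleast_1d(axes)
    corners = np.array([[0, 0], [1, 0], [0.5, math.sqrt(3) / 2], [0, 0]])
    for ax, scope in zip(axes, scopes):
        sub = summaries[summaries["scope"] == scope]
        ax.plot(corners[:, 0], corners[:, 1], color="grey", lw=1)
        pts = triangle_coordinates(sub[["mean_sim", "mean_repl", "mean_diff"]].to_numpy())
        for i, (xy, gid) in enumerate(zip(pts, sub["group_id"])):
            ax.scatter(*xy, color=_PALETTE[i % len(_PALETTE)], s=40, zorder=3)
            ax.annotate(str(gid), xy, fontsize=6, xytext=(2, 2), textcoords="offset points")
        ax.text(-0.02, -0.04, "similarity", ha="right", fontsize=8)
        ax.text(1.02, -0.04, "replacement", ha="left", fontsize=8)
        ax.text(0.5, math.sqrt(3) / 2 + 0.03, "abundance difference", ha="center", fontsize=8)
        ax.set_title(f"{scope} groups")
        ax.set_aspect("equal")
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig_species(species, path, top=10):
    order = (
        species.groupby("species")["rda_score"].apply(lambda s: s.abs().mean())
        .sort_values(ascending=False).head(top).index
    )
    sub = species[species["species"].isin(order)]
    sites = sorted(sub["site"].unique())
    fig, axes = plt.subplots(
        1, len(sites), figsize=(1.6 * len(sites) + 2, 4), sharey=True
    )
    axes = np.atleast_1d(axes)
    for ax, site in zip(axes, sites):
        rows = sub[sub["site"] == site].set_index("species").reindex(order)
        colors = ["#2166ac" if v > 0 else "#b2182b" for v in rows["rda_score"].fillna(0)]
        ax.barh(range(len(order)), rows["rda_score"].fillna(0), color=colors)
        ax.axvline(0, color="grey", lw=0.5)
        ax.set_title(site, fontsize=8)
        ax.tick_params(labelsize=7)
    axes[0].set_yticks(range(len(order)), order, fontsize=7)
    fig.suptitle("Species RDA scores per site (blue = increase, red = decrease)", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_figures(
    bundle: dict, table: CommunityTable, dec: DecomposedDissimilarity, out: Path
) -> dict:
    """Render whichever figures the completed stages support; a missing
    stage output skips its figure with a note in the returned dict."""
    out = Path(out)
    made, skipped = [], []

    coords = embed_for_tests(dec)
    groups_path = out / "meta_with_groups.csv"
    groups = (
        pd.read_csv(groups_path, index_col=0)["mrt_group"].to_numpy()
        if groups_path.exists()
        else table.meta["site"].to_numpy()
    )
    _fig_pcoa(coords, groups, out / "fig_pcoa.png")
    made.append("fig_pcoa.png")

    lcbd_path = out / "lcbd.csv"
    if lcbd_path.exists():
        _fig_lcbd(pd.read_csv(lcbd_path, index_col=0), table.meta, out / "fig_lcbd.png")
        made.append("fig_lcbd.png")
    else:
        skipped.append("fig_lcbd.png (no lcbd stage output)")

    summ_path = out / "group_summaries.csv"
    if summ_path.exists():
        _fig_triangle(pd.read_csv(summ_path), out / "fig_triangle.png")
        made.append("fig_triangle.png")
    else:
        skipped.append("fig_triangle.png (no strata stage output)")

    sp_path = out / "shift_species.csv"
    if sp_path.exists():
        species = pd.read_csv(sp_path)
        if len(species):
            _fig_species(species, out / "fig_species.png")
            made.append("fig_species.png")
        else:
            skipped.append("fig_species.png (no species selected)")
    else:
        skipped.append("fig_species.png (no shift stage output)")
    return {"made": made, "skipped": skipped}
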