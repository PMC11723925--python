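"""Minimal rendering of an exported result bundle.

Reads the CSV exports written by :func:`morphodist.pipeline.export_bundle`
and produces static figures plus a markdown report.  Rendering never
recomputes statistics; tables reproduce the CSV values verbatim.  Missing
exports are listed in the report instead of aborting it.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Ellipse

PANELS = {
    "eigenvalues": "eigenvalues.csv",
    "ordination": "object_centroids.csv",
    "hetcor": "hetcor_matrix.csv",
    "arrows": "arrows.csv",
    "dispersion": "dispersion.csv",
    "tests": "tests.csv",
}


def _plot_eigenvalues(df: pd.DataFrame, ax) -> None:
    ax.bar(df["pc"], df["variance_pct"], color="grey")
    ax.set_xlabel("PC")
    ax.set_ylabel("% variance")


def _plot_ordination(cent: pd.DataFrame, gcent: pd.DataFrame | None,
                     gell: pd.DataFrame | None, ax) -> None:
    for g, sub in cent.groupby("group", sort=False):
        ax.scatter(sub["pc1"], sub["pc2"], s=8, alpha=0.6, label=str(g))
    if gcent is not None:
        ax.scatter(gcent["pc1"], gcent["pc2"], marker="s", s=60, c="black", zorder=5)
        if gell is not None:
            for (_, c), (_, e) in zip(gcent.iterrows(), gell.iterrows()):
                ax.add_patch(
                    Ellipse((c["pc1"], c["pc2"]), 2 * e["semi_major"], 2 * e["semi_minor"],
                            angle=e["angle_deg"], fill=False, lw=1.2)
                )
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=7, title="group")


def _plot_hetcor(mat: pd.DataFrame, ax) -> None:
    im = ax.imshow(mat.to_numpy(dtype=float), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(mat.columns)))
    ax.set_xticklabels(mat.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(len(mat.index)))
    ax.set_yticklabels(mat.index, fontsize=5)
    plt.colorbar(im, ax=ax, shrink=0.7)


def _plot_arrows(arrows: pd.DataFrame, ax) -> None:
    for _, row in arrows.iterrows():
        ax.annotate("", xy=(row["pc1_corr"], row["pc2_corr"]), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", lw=0.8))
        ax.text(row["pc1_corr"], row["pc2_corr"], row["column"], fontsize=5)
    circle = plt.Circle((0, 0), 1.0, fill=False, ls="--", color="grey")
    ax.add_patch(circle)
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_aspect("equal")
    ax.set_xlabel("corr with PC1")
    ax.set_ylabel("corr with PC2")


def _plot_dispersion(disp: pd.DataFrame, ax, rng=None) -> None:
    """Density-spread jitter strips of distance-to-centroid per group."""
    rng = rng or np.random.default_rng(0)
    groups = list(dict.fromkeys(disp["group"]))
    for k, g in enumerate(groups):
        d = disp.loc[disp["group"] == g, "distance"].to_numpy()
        if len(d) > 1 and d.std() > 0:
            from scipy.stats import gaussian_kde

            dens = gaussian_kde(d)(d)
            dens = dens / dens.max()
        else:
            dens = np.ones_like(d)
        x = k + 0.35 * dens * rng.uniform(-1, 1, size=len(d))
        ax.scatter(x, d, s=4, alpha=0.5)
        ax.errorbar(
            [k], [np.median(d)],
            yerr=[[np.median(d) - np.percentile(d, 2.5)], [np.percentile(d, 97.5) - np.median(d)]],
            fmt="o", color="black", capsize=3, zorder=5,
        )
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels([str(g) for g in groups])
    ax.set_xlabel("group")
    ax.set_ylabel("distance to group centroid")


def make_report(bundle_dir: str | Path, out_name: str = "report") -> Path:
    """Render the six standard panels and a markdown report from a bundle."""
    bundle_dir = Path(bundle_dir)
    missing = [f for f in PANELS.values() if not (bundle_dir / f).exists()]
    fig, axes = plt.subplots(2, 3, figsize=(15, 9))
    axes = axes.ravel()

    if (bundle_dir / "eigenvalues.csv").exists():
        _plot_eigenvalues(pd.read_csv(bundle_dir / "eigenvalues.csv"), axes[0])
    if (bundle_dir / "object_centroids.csv").exists():
        gcent = gell = None
        if (bundle_dir / "group_centroids.csv").exists():
            gcent = pd.read_csv(bundle_dir / "group_centroids.csv")
        if (bundle_dir / "group_ellipses.csv").exists():
            gell = pd.read_csv(bundle_dir / "group_ellipses.csv")
        _plot_ordination(pd.read_csv(bundle_dir / "object_centroids.csv"), gcent, gell, axes[1])
    if (bundle_dir / "hetcor_matrix.csv").exists():
        _plot_hetcor(pd.read_csv(bundle_dir / "hetcor_matrix.csv", index_col=0), axes[2])
    if (bundle_dir / "arrows.csv").exists():
        _plot_arrows(pd.read_csv(bundle_dir / "arrows.csv"), axes[3])
    if (bundle_dir / "dispersion.csv").exists():
        _plot_dispersion(pd.read_csv(bundle_dir / "dispersion.csv"), axes[4])
    axes[5].axis("off")
    fig.tight_layout()
    fig_path = bundle_dir / f"{out_name}.png"
    fig.savefig(fig_path, dpi=120)
    plt.close(fig)

    lines = ["# Analysis report", ""]
    if missing:
        lines += ["## Missing exports", ""] + [f"- `{f}` not found" for f in missing] + [""]
    if (bundle_dir / "tests.csv").exists():
        tests = pd.read_csv(bundle_dir / "tests.csv")
        lines += ["## Permutation tests", "", tests.to_markdown(index=False), ""]
    lines += [f"![panels]({fig_path.name})", ""]
    report_path = bundle_dir / f"{out_name}.md"
    report_path.write_text("\n".join(lines), encoding="utf-8")
    return report_path
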