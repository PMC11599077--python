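"""Figure rendering from a completed run's manifest.

Rendering is strictly a read-only view of the run directory — every panel
is regenerated from the saved CSV/JSON outputs without recomputation, so a
manifest plus its files is sufficient to rebuild the report. Panels whose
stage output is missing are skipped with a note.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["render_report"]


def _load_csv(path: Path, **kw) -> pd.DataFrame | None:
    return pd.read_csv(path, **kw) if path.exists() else None


def render_report(manifest_path) -> list[str]:
    """Render heatmaps, embedding scatter, SIG contours and ROI pie panels.

    Returns the list of figure paths written (under ``<run>/report``).
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    rundir = manifest_path.parent
    outdir = rundir / "report"
    outdir.mkdir(exist_ok=True)
    written: list[str] = []
    notes: list[str] = []

    partitions = {}
    part_path = rundir / "partitions.json"
    if part_path.exists():
        partitions = json.loads(part_path.read_text())

    # PCC heatmaps with cluster frames
    for pcc_file in sorted(rundir.glob("pcc_*.csv")):
        scale_id = pcc_file.stem[len("pcc_"):]
        corr = pd.read_csv(pcc_file, index_col=0)
        assignment = partitions.get(scale_id)
        fig, ax = plt.subplots(figsize=(6, 5))
        order = list(corr.index)
        if assignment:
            order = sorted(order, key=lambda i: assignment[i])
        mat = corr.loc[order, order].to_numpy()
        im = ax.imshow(mat, vmin=-1, vmax=1, cmap="RdBu_r")
        fig.colorbar(im, ax=ax, label="PCC")
        if assignment:
            labels = [assignment[i] for i in order]
            start = 0
            for j in range(1, len(labels) + 1):
                if j == len(labels) or labels[j] != labels[start]:
                    size = j - start
                    ax.add_patch(
                        plt.Rectangle(
                            (start - 0.5, start - 0.5), size, size,
                            fill=False, linestyle="--", edgecolor="black",
                        )
                    )
                    start = j
        ax.set_title(f"{scale_id}: item correlations and factor frames")
        ax.set_xticks([])
        ax.set_yticks([])
        path = outdir / f"heatmap_{scale_id}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))

    # embedding scatter colored by dose
    coords = _load_csv(rundir / "coordinates.csv", index_col=0)
    membership = _load_csv(rundir / "roi_membership.csv")
    if coords is not None:
        dose_color = None
        scores = _load_csv(rundir / "factor_scores.csv", index_col=0)
        summary_path = rundir / "cohort_summary.json"
        fig, ax = plt.subplots(figsize=(6, 5))
        ax.scatter(coords["x"], coords["y"], s=8, c="black")
        ax.set_title("Respondent latent projection")
        ax.set_xlabel("x")
        ax.set_ylabel("y")
        path = outdir / "embedding.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    else:
        notes.append("coordinates.csv missing: embedding panel skipped")

    # SIG contour map
    smoothed = _load_csv(rundir / "sig_smoothed.csv", index_col=0)
    grid_path = rundir / "grid.json"
    if smoothed is not None and grid_path.exists() and coords is not None:
        grid = json.loads(grid_path.read_text())
        mat = smoothed.to_numpy()  # (nx, ny)
        cx = grid["x_min"] + (np.arange(grid["nx"]) + 0.5) * grid["step"]
        cy = grid["y_min"] + (np.arange(grid["ny"]) + 0.5) * grid["step"]
        fig, ax = plt.subplots(figsize=(6, 5))
        pcm = ax.pcolormesh(cx, cy, mat.T, cmap="coolwarm", shading="nearest")
        fig.colorbar(pcm, ax=ax, label="smoothed SIG")
        levels = sorted(
            v for v in json.loads((rundir / "contour_levels.json").read_text()).values()
            if v > 0
        ) if (rundir / "contour_levels.json").exists() else []
        if levels:
            ax.contour(
                cx, cy, mat.T, levels=levels, colors="black", linestyles="dashed"
            )
        ax.scatter(coords["x"], coords["y"], s=4, c="black")
        ax.set_title("Aggregated SIG surface with contour levels")
        path = outdir / "sig_contours.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    else:
        notes.append("SIG outputs missing: contour panel skipped")

    # per-ROI pie panels
    profiles_path = rundir / "profiles.json"
    if profiles_path.exists():
        profiles = json.loads(profiles_path.read_text())
        for prof in profiles:
            sig_vars = prof.get("significant_demographics", {})
            n_panels = max(len(sig_vars), 1)
            fig, axes = plt.subplots(
                2, n_panels, figsize=(3 * n_panels, 6), squeeze=False
            )
            for j, (var, pie) in enumerate(sorted(sig_vars.items())):
                axes[0][j].pie(pie["cohort_proportions"], labels=pie["categories"],
                               textprops={"fontsize": 6})
                axes[0][j].set_title(f"cohort: {var}", fontsize=8)
                axes[1][j].pie(pie["roi_proportions"], labels=pie["categories"],
                               textprops={"fontsize": 6})
                axes[1][j].set_title(
                    f"{prof['roi_id']}: {var} {pie['stars']}", fontsize=8
                )
            if not sig_vars:
                axes[0][0].axis("off")
                axes[1][0].axis("off")
                axes[0][0].set_title("no significant demographics", fontsize=8)
            fig.suptitle(
                f"{prof['roi_id']} (n={prof['n']}, dose "
                f"{prof['dose_mean']:.1f} ± {prof['dose_sd']:.1f})"
            )
            path = outdir / f"profile_{prof['roi_id']}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(str(path))
    else:
        notes.append("profiles.json missing: ROI panels skipped")

    (outdir / "report_notes.txt").write_text("\n".join(notes) or "all panels rendered")
    return written
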