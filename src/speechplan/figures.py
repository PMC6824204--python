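"""Plot rendering: target regions, planning outcomes, preference sweeps.

Plots follow vowel-chart conventions: auditory panels show the (F2, F1) plane
with both axes decreasing (F1 downward, F2 leftward), so open vowels plot low
and front vowels left; somatosensory panels show the first two contour PCs.
Every figure writes its data layer (ellipse parameters or sweep table) as a
CSV next to the image, so regenerating from the same results is byte-identical
in the data layer even if the rendering toolkit changes.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Ellipse

from .planner import dispersion_ellipse

_MODE_COLORS = {"auditory": "tab:red", "somatosensory": "tab:blue", "fusion": "tab:green"}


def ellipse_frame(results_by_key, space: str, dims=(0, 1), order: float = 2.0) -> pd.DataFrame:
    """Dispersion-ellipse parameters for a set of planning results.

    ``results_by_key`` maps (condition, mode) to a CompensationResult whose
    ``results`` field holds the posterior draws.
    """
    rows = []
    for (condition, mode), res in results_by_key.items():
        if res.results is None:
            continue
        pts = res.results.predicted(space)[:, list(dims)]
        center, axes, angle = dispersion_ellipse(pts, order=order)
        rows.append(
            {
                "condition": condition,
                "mode": mode,
                "space": space,
                "cx": center[0],
                "cy": center[1],
                "major": axes[0],
                "minor": axes[1],
                "angle_deg": angle,
            }
        )
    return pd.DataFrame(rows)


def _draw_ellipse(ax, cx, cy, major, minor, angle, **kwargs):
    ax.add_patch(
        Ellipse((cx, cy), 2 * major, 2 * minor, angle=angle, fill=False, lw=1.8, **kwargs)
    )


def plot_conditions(results_by_key, inventory, phoneme: str, outdir, order: float = 2.0):
    """Per-condition panels of planning-outcome ellipses in both spaces.

    Returns the list of files written (PNG figure + CSV data layer).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    target = inventory[phoneme]
    conditions = sorted({k[0] for k in results_by_key})
    written = []

    frames = []
    for space, dims in (("auditory", (1, 0)), ("somatosensory", (0, 1))):
        frames.append(ellipse_frame(results_by_key, space, dims=(0, 1), order=order))
    data = pd.concat(frames, ignore_index=True)
    csv_path = outdir / f"ellipses_{phoneme}.csv"
    data.to_csv(csv_path, index=False, float_format="%.10g")
    written.append(csv_path)

    fig, axes_grid = plt.subplots(2, len(conditions), figsize=(4.2 * len(conditions), 7.5))
    axes_grid = np.atleast_2d(axes_grid)
    for j, condition in enumerate(conditions):
        for i, space in enumerate(("auditory", "somatosensory")):
            ax = axes_grid[i, j]
            mu = target.mean(space)
            cov = target.cov(space)
            # target region (order-2) in plot coordinates
            if space == "auditory":
                pmu = (mu[1], mu[0])
                pcov = np.array([[cov[1, 1], cov[1, 0]], [cov[0, 1], cov[0, 0]]])
            else:
                pmu = (mu[0], mu[1])
                pcov = cov[:2, :2]
            vals, vecs = np.linalg.eigh(pcov)
            ang = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
            _draw_ellipse(ax, *pmu, order * np.sqrt(vals[-1]), order * np.sqrt(vals[0]), ang,
                          edgecolor="black")
            sub = data[(data.condition == condition) & (data.space == space)]
            for _, row in sub.iterrows():
                cx, cy, major, minor, angle = row.cx, row.cy, row.major, row.minor, row.angle_deg
                if space == "auditory":
                    cx, cy = cy, cx
                    angle = 90.0 - angle
                _draw_ellipse(ax, cx, cy, major, minor, angle,
                              edgecolor=_MODE_COLORS.get(row["mode"], "gray"))
            if space == "auditory":
                ax.set_xlabel("F2 (Hz)")
                ax.set_ylabel("F1 (Hz)")
                if not ax.xaxis_inverted():
                    ax.invert_xaxis()
                if not ax.yaxis_inverted():
                    ax.invert_yaxis()
            else:
                ax.set_xlabel("PC1")
                ax.set_ylabel("PC2")
            ax.set_title(f"{condition} — {space}")
            ax.autoscale_view()
    fig.tight_layout()
    png_path = outdir / f"conditions_{phoneme}.png"
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    written.append(png_path)
    return written


def plot_sweep(sweep_table: pd.DataFrame, outdir, reference_ratios: dict | None = None):
    """Compensation-ratio curve over a preference-parameter grid."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    param = sweep_table["param"].iloc[0]
    csv_path = outdir / f"sweep_{param}.csv"
    sweep_table.to_csv(csv_path, index=False, float_format="%.10g")

    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.semilogx(sweep_table["value"], sweep_table["compensation_ratio"], "o-", color="tab:green")
    for name, val in (reference_ratios or {}).items():
        ax.axhline(val, ls="--", lw=1, color=_MODE_COLORS.get(name, "gray"), label=name)
    ax.set_xlabel(param)
    ax.set_ylabel("compensation ratio")
    ax.set_title(f"fusion compensation vs {param}")
    if reference_ratios:
        ax.legend()
    fig.tight_layout()
    png_path = outdir / f"sweep_{param}.png"
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return [csv_path, png_path]
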