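"""Figure builders: derived artifacts only — no numeric result is read back
from a figure."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["displacement_figure", "alignment_figure", "migration_figure"]


def displacement_figure(dispfield, grid_x, grid_y, mag_map, path):
    """Arrow field of bead displacements next to the |u| colour map."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4.5))
    ax1.quiver(dispfield.x0, dispfield.y0, dispfield.ux, -dispfield.uy,
               angles="xy", scale_units="xy", scale=0.2, width=0.003)
    ax1.set_aspect("equal")
    ax1.invert_yaxis()
    ax1.set_title("bead displacements")
    ax1.set_xlabel("x (um)")
    ax1.set_ylabel("y (um)")
    im = ax2.pcolormesh(grid_x, grid_y, mag_map, shading="auto", cmap="viridis")
    ax2.set_aspect("equal")
    ax2.invert_yaxis()
    ax2.set_title("|u| (um)")
    fig.colorbar(im, ax=ax2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def alignment_figure(fit, regression, path):
    """Gamma histogram with its Gaussian fit, and the per-sector regression."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4.5))
    edges = np.asarray(fit["histogram"]["bin_edges"])
    counts = np.asarray(fit["histogram"]["counts"])
    centers = (edges[:-1] + edges[1:]) / 2
    ax1.bar(centers, counts, width=np.diff(edges), color="tab:blue", alpha=0.6)
    if fit["sigma"] > 0:
        xs = np.linspace(-90, 90, 361)
        pdf = np.exp(-0.5 * ((xs - fit["mu"]) / fit["sigma"]) ** 2)
        ax1.plot(xs, pdf * counts.max(), "r-",
                 label=f"mu={fit['mu']:.1f}, sigma={fit['sigma']:.1f}")
        ax1.legend()
    ax1.set_xlabel("angular alignment gamma (deg)")
    ax1.set_ylabel("count")
    per = regression["per_sector"]
    ax2.plot(per.sector_orientation, per.mean_orientation, "ko", ms=4)
    xs = np.linspace(0, 180, 10)
    ax2.plot(xs, regression["intercept"] + regression["slope"] * xs, "r-",
             label=f"slope={regression['slope']:.3f}, r2={regression['r_squared']:.3f}")
    ax2.set_xlabel("sector orientation (deg)")
    ax2.set_ylabel("mean object orientation (deg)")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def migration_figure(panel, path):
    """Per-condition rose diagrams and turning-angle histograms."""
    conditions = list(panel["conditions"])
    n = len(conditions)
    fig = plt.figure(figsize=(4 * n, 8))
    for i, name in enumerate(conditions):
        entry = panel["conditions"][name]
        edges = np.radians(np.asarray(entry["rose_bin_edges"]))
        widths = np.diff(edges)
        ax = fig.add_subplot(2, n, i + 1, projection="polar")
        ax.bar(edges[:-1] + widths / 2, entry["rose_counts"], width=widths,
               alpha=0.7)
        ax.set_title(f"{name}\nsteps", fontsize=9)
        ax2 = fig.add_subplot(2, n, n + i + 1)
        deg_edges = np.degrees(edges)
        ax2.bar((deg_edges[:-1] + deg_edges[1:]) / 2, entry["turning_counts"],
                width=np.diff(deg_edges), alpha=0.7)
        ax2.set_xlabel("turning angle (deg)")
        ax2.set_title(f"persistence={entry['persistence']:.2f}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
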