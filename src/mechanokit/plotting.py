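"""Optional matplotlib views: screen scatter, Z histogram, residency heatmap."""

from __future__ import annotations

import numpy as np


def _axes(ax=None):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    return ax


def plot_screen(ranked, hit_pdockq: float = 0.5, ax=None):
    """Candidate library on the (clashscore, pDockQ) plane; hits annotated."""
    ax = _axes(ax)
    xs = [e.clashscore for e in ranked]
    ys = [e.pdockq for e in ranked]
    front = [e.pareto_rank == 1 for e in ranked]
    ax.scatter(xs, ys, c=["tab:red" if f else "tab:gray" for f in front], s=18)
    for e in ranked:
        if e.pareto_rank == 1 and e.pdockq >= hit_pdockq:
            ax.annotate(e.candidate_id, (e.clashscore, e.pdockq), fontsize=8)
    ax.set_xlabel("clashscore (clashes / 1000 heavy atoms)")
    ax.set_ylabel("pDockQ")
    return ax


def plot_z_histogram(edges, counts, z_min: float = 10.0, ax=None):
    ax = _axes(ax)
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", color="tab:blue")
    ax.axvline(z_min, color="tab:red", linestyle="--", label=f"Z = {z_min:g}")
    ax.set_xlabel("inter-protein coupling Z-score")
    ax.set_ylabel("pair count")
    ax.legend()
    return ax


def plot_residency(grid, ax=None):
    """Residency density heatmap (normalized to the grid maximum)."""
    ax = _axes(ax)
    im = ax.imshow(
        grid.density.T,
        origin="lower",
        extent=(grid.x_edges[0], grid.x_edges[-1], grid.y_edges[0], grid.y_edges[-1]),
        cmap="viridis",
    )
    ax.figure.colorbar(im, ax=ax, label="relative residency")
    ax.set_xlabel("x (Å)")
    ax.set_ylabel("y (Å)")
    return ax
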