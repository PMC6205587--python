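"""Static image export for DREVI surfaces and TIDES curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def save_drevi_surface(surface, path, cmap: str = "Reds") -> None:
    """Render a conditional-mean surface as a 3D surface plot."""
    import numpy as np

    x, y = surface.cond_centers
    xx, yy = np.meshgrid(x, y, indexing="ij")
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    ax.plot_surface(xx, yy, surface.values, cmap=cmap, linewidth=0)
    names = surface.axis_names or ("conditioning axis 1", "conditioning axis 2", "response")
    ax.set_xlabel(names[0])
    ax.set_ylabel(names[1])
    ax.set_zlabel(f"E[{names[2]}]" if len(names) > 2 else "conditional mean")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_tides_curves(curves, path, labels=None) -> None:
    """Line plot of one or more TIDES curves on a shared pseudotime axis."""
    if not isinstance(curves, (list, tuple)):
        curves = [curves]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for i, curve in enumerate(curves):
        label = (labels[i] if labels else f"{curve.edge[0]} → {curve.edge[1]}")
        ax.plot(curve.t_values, curve.scores, label=label)
    ax.set_xlabel("pseudotime")
    ax.set_ylabel("TIDES (bits)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
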