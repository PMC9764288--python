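"""Heat-map rendering of descriptor occupancy maps."""

from __future__ import annotations

from .geometry import NACCriteria
from .pipeline import OccupancyMap


def plot_occupancy(occ: OccupancyMap, path, criteria: NACCriteria = NACCriteria(),
                   cmap: str = "viridis"):
    """Render a (theta2 x d) occupancy heat map with the two-criteria box.

    The red rectangle marks d <= d_max and theta2 > theta2_min; samples
    inside it still need the theta1 window to count as NACs.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(occ.d_edges, occ.theta2_edges, occ.counts, cmap=cmap)
    fig.colorbar(mesh, ax=ax, label="frames")
    d_lo = occ.d_edges[0]
    ax.plot([d_lo, criteria.d_max, criteria.d_max],
            [180.0, 180.0, criteria.theta2_min], color="red", lw=1.5)
    ax.plot([d_lo, criteria.d_max], [criteria.theta2_min, criteria.theta2_min],
            color="red", lw=1.5)
    ax.set_xlabel("O-H distance d (Angstrom)")
    ax.set_ylabel("C-H-O angle theta2 (degrees)")
    ax.set_title(f"{occ.hydrogen_label} (n={occ.n_samples}, "
                 f"box={occ.red_box_count})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
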