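"""Optional plotting: strain communities projected on the budget-share
simplex (p = 3 only).  Requires matplotlib, which is imported lazily."""

from __future__ import annotations

import numpy as np

from .core import CommunityState, TradeoffSpec
from .observe import simplex_coordinates

__all__ = ["plot_simplex_snapshot"]

# vertices of the 2-simplex drawn in the plane
_CORNERS = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])


def _to_plane(shares: np.ndarray) -> np.ndarray:
    return shares @ _CORNERS


def plot_simplex_snapshot(
    state: CommunityState,
    spec: TradeoffSpec,
    ax=None,
    alpha_star=None,
    **scatter_kw,
):
    """Scatter the community on the budget-share simplex.

    Circle areas are proportional to strain density (the conventional
    rendering for three-resource communities).  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if state.p != 3:
        raise ValueError("simplex plot is defined for p = 3")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    tri = np.vstack([_CORNERS, _CORNERS[0]])
    ax.plot(tri[:, 0], tri[:, 1], color="0.6", lw=1)
    shares = np.array(
        [simplex_coordinates(ph, spec) for ph, _ in state.strains]
    )
    dens = state.densities()
    xy = _to_plane(shares)
    size = 300 * np.sqrt(dens / max(dens.max(), 1e-300))
    scatter_kw.setdefault("alpha", 0.7)
    ax.scatter(xy[:, 0], xy[:, 1], s=size, **scatter_kw)
    if alpha_star is not None:
        sx = _to_plane(simplex_coordinates(alpha_star, spec)[None, :])
        ax.scatter(sx[:, 0], sx[:, 1], marker="o", facecolors="none",
                   edgecolors="k", s=120, linewidths=1.5)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"t = {state.time:.0f}, {state.n_strains} strains")
    return ax
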