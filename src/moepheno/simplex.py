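"""Ternary latent-space diagnostics.

The selector's gate vector lives on the (K-1)-simplex; only three components
can be drawn in a ternary plot, so gate mass is truncated to the three
globally heaviest experts (renormalized, with the truncated mass recorded
per patient).  Patients are colored by confusion class at a 50% risk
threshold, and local discrimination is summarized by AUROC/AUPRC computed
within each cell of a uniform barycentric subdivision of the triangle;
cells with too few patients (or one outcome class) take a fill value of 0.5
for AUROC and 0 for AUPRC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .selection import auprc, auroc

__all__ = [
    "TernaryEmbedding",
    "LocalMetricGrid",
    "ternary_project",
    "classify_threshold",
    "local_metric_grid",
    "ternary_to_cartesian",
    "plot_ternary_scatter",
    "plot_local_metric_heatmap",
]

METRIC_FILL = {"auroc": 0.5, "auprc": 0.0}


@dataclass
class TernaryEmbedding:
    """Per-patient coordinates on the 3-simplex over the globally heaviest
    three experts (in weight order: A = heaviest), the per-patient gate mass
    lost to truncation, and indices of rows excluded because they carry zero
    mass on all three selected experts."""

    coords: np.ndarray  # (n_kept, 3), rows sum to 1
    selected_experts: np.ndarray  # (3,) original expert indices, weight order
    truncated_mass: np.ndarray  # (n_kept,)
    kept_rows: np.ndarray  # indices into the original cohort
    excluded_rows: np.ndarray


def ternary_project(
    gates: np.ndarray, expert_order: Sequence[int], renormalize: bool = True
) -> TernaryEmbedding:
    """Project gate vectors onto the top-3 experts' simplex.

    ``expert_order`` is the weight ordering from
    :func:`moepheno.phenotypes.order_experts_by_weight`; its first three
    entries are kept.  With ``renormalize`` the kept mass is rescaled to sum
    to 1 (the truncated mass is recorded separately); without it the raw
    3-vector is returned, which lies inside the triangle but below the
    edge when mass was truncated.  For K=3 the embedding is the (reordered)
    gate vector itself.  Rows with zero mass on all three kept experts have
    no defined coordinates and are listed in ``excluded_rows``.
    """
    g = np.atleast_2d(np.asarray(gates, dtype=float))
    K = g.shape[1]
    if K < 3:
        raise ValueError("ternary projection needs at least 3 experts")
    top3 = np.asarray(expert_order)[:3]
    raw = g[:, top3]
    mass = raw.sum(axis=1)
    kept = np.flatnonzero(mass > 0)
    excluded = np.flatnonzero(mass <= 0)
    coords = raw[kept]
    if renormalize:
        coords = coords / coords.sum(axis=1, keepdims=True)
    return TernaryEmbedding(
        coords=coords,
        selected_experts=top3,
        truncated_mass=1.0 - mass[kept],
        kept_rows=kept,
        excluded_rows=excluded,
    )


def classify_threshold(y: Sequence[int], y_hat: Sequence[float], threshold: float = 0.5) -> np.ndarray:
    """Confusion class per patient ("TP"/"FP"/"TN"/"FN"); predicted positive
    iff the risk estimate is >= threshold (the boundary counts as positive)."""
    y = np.asarray(y)
    p = np.asarray(y_hat, dtype=float)
    pred = p >= threshold
    out = np.empty(len(y), dtype=object)
    out[(y == 1) & pred] = "TP"
    out[(y == 0) & pred] = "FP"
    out[(y == 0) & ~pred] = "TN"
    out[(y == 1) & ~pred] = "FN"
    return out


# --- barycentric grid ------------------------------------------------------


def _cell_index_array(coords: np.ndarray, resolution: int) -> list[tuple[int, int, int]]:
    """Map simplex points to triangular cells of a uniform subdivision.

    Scaling coordinates by the resolution r, the integer floors (i, j, k) of
    the three scaled coordinates identify the cell: fractional parts summing
    to 1 give an upward cell (orientation 0, i+j+k = r-1), summing to 2 a
    downward cell (orientation 1, i+j+k = r-2).  Lattice points (fractional
    sum 0) are assigned to an adjacent upward cell by decrementing the
    largest coordinate — a half-open convention that makes edge membership
    deterministic.
    """
    u = coords * resolution
    f = np.floor(u + 1e-9).astype(int)
    f = np.minimum(f, resolution)
    s = f.sum(axis=1)
    # lattice points: fractional sum 0 -> decrement the largest coordinate(s)
    for _ in range(2):
        over = s > resolution - 1
        if not over.any():
            break
        rows = np.flatnonzero(over)
        largest = f[rows].argmax(axis=1)
        f[rows, largest] -= 1
        s = f.sum(axis=1)
    out = []
    for (i, j, _k), ssum in zip(f, s):
        orient = 0 if ssum == resolution - 1 else 1
        out.append((int(i), int(j), orient))
    return out


@dataclass
class LocalMetricGrid:
    """Per-cell local metric over a uniform barycentric subdivision with
    ``resolution`` cells per triangle edge."""

    resolution: int
    metric: str
    min_per_cell: int
    fill: float
    cells: pd.DataFrame  # columns: i, j, orientation, count, scorable, value

    @property
    def n_cells(self) -> int:
        return self.resolution**2


def local_metric_grid(
    embedding: TernaryEmbedding,
    y: Sequence[int],
    y_hat: Sequence[float],
    metric: str = "auroc",
    resolution: int = 10,
    min_per_cell: int = 10,
) -> LocalMetricGrid:
    """Compute a local-discrimination heatmap over the ternary simplex.

    ``y`` and ``y_hat`` are aligned to the embedding's kept rows.  Each cell
    with at least ``min_per_cell`` patients and both outcome classes gets the
    metric of its own patients; every other cell takes the fill value
    (0.5 for AUROC — chance level; 0 for AUPRC).
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    if metric not in METRIC_FILL:
        raise ValueError(f"metric must be one of {sorted(METRIC_FILL)}")
    y = np.asarray(y)
    p = np.asarray(y_hat, dtype=float)
    if len(y) != len(embedding.coords) or len(p) != len(embedding.coords):
        raise ValueError("outcomes not aligned to embedding")
    fill = METRIC_FILL[metric]
    score = auroc if metric == "auroc" else auprc

    assignments = _cell_index_array(embedding.coords, resolution)
    members: dict[tuple[int, int, int], list[int]] = {}
    for row, cell in enumerate(assignments):
        members.setdefault(cell, []).append(row)

    rows = []
    for i in range(resolution):
        for j in range(resolution - i):
            for orient in (0, 1):
                if orient == 1 and i + j > resolution - 2:
                    continue
                idx = members.get((i, j, orient), [])
                count = len(idx)
                scorable = count >= min_per_cell and len(np.unique(y[idx])) == 2
                value = score(y[idx], p[idx]) if scorable else fill
                rows.append({"i": i, "j": j, "orientation": orient, "count": count,
                             "scorable": scorable, "value": value})
    return LocalMetricGrid(resolution=resolution, metric=metric, min_per_cell=min_per_cell,
                           fill=fill, cells=pd.DataFrame(rows))


# --- plotting --------------------------------------------------------------

_SQ3 = np.sqrt(3.0)


def ternary_to_cartesian(coords: np.ndarray) -> np.ndarray:
    """Map simplex coordinates (a, b, c) to 2D: corner A (heaviest expert) at
    bottom right (1, 0), B at top (1/2, sqrt(3)/2), C at bottom left (0, 0)."""
    c3 = np.atleast_2d(np.asarray(coords, dtype=float))
    a, b, c = c3[:, 0], c3[:, 1], c3[:, 2]
    x = a + 0.5 * b
    yy = (_SQ3 / 2) * b
    return np.column_stack([x, yy])


_CLASS_COLORS = {"TP": "#c0392b", "FP": "#e67e22", "TN": "#2980b9", "FN": "#8e44ad"}


def plot_ternary_scatter(embedding: TernaryEmbedding, classes: Sequence[str], path: str,
                         labels: Sequence[str] = ("A", "B", "C")) -> None:
    """Scatter patients inside the ternary triangle, colored by confusion
    class at the 50% threshold; corner A is the heaviest expert."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = ternary_to_cartesian(embedding.coords)
    fig, ax = plt.subplots(figsize=(6, 5.5))
    tri = np.array([[0, 0], [1, 0], [0.5, _SQ3 / 2], [0, 0]])
    ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1)
    cls = np.asarray(classes, dtype=object)
    for name, color in _CLASS_COLORS.items():
        sel = cls == name
        if sel.any():
            ax.scatter(xy[sel, 0], xy[sel, 1], s=4, alpha=0.4, color=color, label=name)
    for lab, pos in zip(labels, [(1.03, -0.03), (0.5, _SQ3 / 2 + 0.03), (-0.06, -0.03)]):
        ax.annotate(lab, pos, fontsize=12)
    ax.legend(loc="upper right", markerscale=3)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_local_metric_heatmap(grid: LocalMetricGrid, path: str,
                              labels: Sequence[str] = ("A", "B", "C")) -> None:
    """Draw the per-cell local metric as filled triangles."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection
    from matplotlib.cm import ScalarMappable
    from matplotlib.colors import Normalize

    r = grid.resolution
    polys, vals = [], []
    for _, row in grid.cells.iterrows():
        i, j, orient = int(row.i), int(row.j), int(row.orientation)
        k = r - 1 - i - j if orient == 0 else r - 2 - i - j
        if orient == 0:
            corners = [(i + 1, j, k), (i, j + 1, k), (i, j, k + 1)]
        else:
            corners = [(i, j + 1, k + 1), (i + 1, j, k + 1), (i + 1, j + 1, k)]
        pts = ternary_to_cartesian(np.array(corners, dtype=float) / r)
        polys.append(pts)
        vals.append(row.value)
    norm = Normalize(vmin=0.0, vmax=1.0)
    pc = PolyCollection(polys, array=np.array(vals), cmap="viridis", norm=norm, edgecolor="white",
                        linewidth=0.3)
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    ax.add_collection(pc)
    for lab, pos in zip(labels, [(1.03, -0.03), (0.5, _SQ3 / 2 + 0.03), (-0.06, -0.03)]):
        ax.annotate(lab, pos, fontsize=12)
    ax.set_xlim(-0.1, 1.15)
    ax.set_ylim(-0.1, _SQ3 / 2 + 0.1)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.colorbar(ScalarMappable(norm=norm, cmap="viridis"), ax=ax, label=grid.metric.upper())
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
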