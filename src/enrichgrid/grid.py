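"""Static rendering of the enrichment grid map.

Columns are experimental conditions (group-ordered, or cluster-ordered when
a clustering has been computed); rows are terms or categories grouped by
their level-1 hierarchy class, with a colour strip marking the class.
P-values use a sequential scale (darker = smaller), signed values a
diverging scale centred at zero, and sign mode exactly three colours with a
three-entry legend (negative, zero, positive).  Undefined cells are blank.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import BoundaryNorm, ListedColormap, TwoSlopeNorm
from matplotlib.patches import Patch

from .hierarchy import ThreeLevelHierarchy
from .matrices import LevelMatrix, TermMatrix

__all__ = ["render_grid"]

SIGN_COLORS = {"negative": "#2166ac", "zero": "#f7f7f7", "positive": "#b2182b"}


def _row_class(m: TermMatrix | LevelMatrix, h: ThreeLevelHierarchy, col: str) -> str:
    """Level-1 class used to group and colour a row of the grid."""
    if isinstance(m, LevelMatrix):
        return m.parents.get(col, col)
    pairs = h.memberships.get(col)
    if not pairs:
        return "unmapped"
    return sorted(pairs)[0][0]


def render_grid(
    m: TermMatrix | LevelMatrix,
    h: ThreeLevelHierarchy,
    out: str | Path | None = None,
    column_order: Sequence[str] | None = None,
    group_labels: dict[str, str] | None = None,
    title: str | None = None,
):
    """Draw the grid map and optionally save it (SVG/PNG by extension).

    Returns the matplotlib Figure, or ``None`` for an empty matrix.
    """
    if m.data.size == 0:
        warnings.warn("empty matrix: nothing to render", stacklevel=2)
        return None

    if column_order is not None:
        conds = [c for c in column_order if c in m.data.index]
    else:
        conds = list(m.data.index)
    grid = m.data.loc[conds].T  # rows: terms/categories, columns: conditions

    # group rows by their level-1 class, keeping current column order stable
    classes = {row: _row_class(m, h, row) for row in grid.index}
    class_order: list[str] = []
    for row in grid.index:
        if classes[row] not in class_order:
            class_order.append(classes[row])
    row_order = [r for c in class_order for r in grid.index if classes[r] == c]
    grid = grid.loc[row_order]

    values = np.ma.masked_invalid(grid.to_numpy(dtype=float))
    n_rows, n_cols = grid.shape
    fig_h = max(2.5, 0.28 * n_rows + 1.5)
    fig_w = max(4.0, 0.45 * n_cols + 3.5)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))

    legend_handles = None
    if m.mode == "sign":
        cmap = ListedColormap(list(SIGN_COLORS.values()))
        norm = BoundaryNorm([-1.5, -0.5, 0.5, 1.5], cmap.N)
        legend_handles = [
            Patch(facecolor=c, edgecolor="0.4", label=lab)
            for lab, c in SIGN_COLORS.items()
        ]
    elif m.mode in ("modification", "combined"):
        cmap = plt.get_cmap("RdBu_r").copy()
        vmax = float(np.abs(values).max()) or 1.0
        norm = TwoSlopeNorm(vmin=-vmax, vcenter=0.0, vmax=vmax)
    else:  # p-values: smaller = stronger = darker
        cmap = plt.get_cmap("viridis_r").copy()
        norm = None
    cmap.set_bad("white")

    im = ax.imshow(values, aspect="auto", cmap=cmap, norm=norm, interpolation="nearest")
    ax.set_xticks(range(n_cols))
    labels = [
        f"{c}\n{group_labels[c]}" if group_labels and c in group_labels else c
        for c in grid.columns
    ]
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_yticks(range(n_rows))
    ax.set_yticklabels([h.name_of(r) for r in grid.index], fontsize=7)

    # level-1 class colour strip on the left edge
    palette = plt.get_cmap("tab20")
    class_color = {c: palette(i % 20) for i, c in enumerate(class_order)}
    for i, row in enumerate(grid.index):
        ax.add_patch(
            plt.Rectangle(
                (-0.9, i - 0.5), 0.35, 1.0,
                facecolor=class_color[classes[row]],
                clip_on=False, linewidth=0,
            )
        )
    ax.set_xlim(-1.0, n_cols - 0.5)

    if legend_handles is not None:
        ax.legend(
            handles=legend_handles, loc="upper left", bbox_to_anchor=(1.01, 1.0),
            fontsize=7, frameon=False, title="sign",
        )
    else:
        fig.colorbar(im, ax=ax, shrink=0.6, label=m.mode)
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, metadata={"Date": None} if str(out).endswith(".svg") else None)
    return fig
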