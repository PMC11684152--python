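"""Optional static rendering of plot tables with matplotlib.

The plot-data tables in :mod:`ftmseda.plottables` are the primary product;
this thin layer turns them into PNG/SVG files for quick inspection.
Requires matplotlib (``pip install ftmseda[plot]``).
"""

from __future__ import annotations

from pathlib import Path

from .plottables import PlotTable


def render(table: PlotTable, path: str | Path, dpi: int = 150) -> Path:
    """Render a plot table to an image file (format from the extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    df = table.data
    if table.kind == "density":
        for unit, sub in df.groupby("unit"):
            ax.plot(sub[table.x], sub[table.y], label=str(unit))
        ax.legend(fontsize=8)
    elif table.color and table.color in df.columns:
        sc = ax.scatter(df[table.x], df[table.y], c=df[table.color], s=8, alpha=0.7)
        fig.colorbar(sc, ax=ax, label=table.meta.get("color_by") or table.color)
    else:
        ax.scatter(df[table.x], df[table.y], s=8, alpha=0.7)
    ax.set_xlabel(table.meta.get("xlabel", table.x))
    ax.set_ylabel(table.meta.get("ylabel", table.y))
    ax.set_title(table.kind.replace("_", " "))
    path = Path(path)
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return path
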