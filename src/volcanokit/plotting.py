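"""Volcano figure rendering and export.

The figure is a scatter of all points colored by threshold category, with
dashed guide lines at the three cutoffs and the top-ranked hits labeled
by name.  Labels are placed by a bounded greedy repulsion pass so they do
not overlap each other or the plot edge.  Figures export to PNG (bitmap),
PDF (vector) or a standalone interactive HTML document in which hovering
a point reveals its name and coordinates.

An optional 90-degree rotation puts the fold change on the vertical axis
and the significance on the horizontal axis, which suits tall gene lists.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import matplotlib.pyplot as plt
from matplotlib.figure import Figure

from .errors import NothingToPlotError, UnsupportedFormatError
from .hits import HitTable, Thresholds, classify_data
from .io import VolcanoData

#: Numbered palettes: 1 = grey/red/blue (default), 2 = grey/blue/green.
COLOR_SCHEMES: dict[int, dict[str, str]] = {
    1: {"unchanged": "grey", "increased": "red", "decreased": "blue"},
    2: {"unchanged": "grey", "increased": "blue", "decreased": "green"},
}

EXPORT_FORMATS = ("png", "pdf", "html")


@dataclass
class PlotStyle:
    """Visual settings for one volcano figure.

    ``dot_size`` matches the app-style size slider (default 4);
    ``font_sizes`` is (title, axis title, tick label, point label) in
    points; the default canvas is 800x600 px rendered at 100 dpi.
    """

    dot_size: float = 4.0
    alpha: float = 0.8
    colors: dict[str, str] = field(
        default_factory=lambda: dict(COLOR_SCHEMES[1])
    )
    show_legend: bool = True
    rotated: bool = False
    title: str = ""
    x_label: str = ""
    y_label: str = ""
    font_sizes: tuple[int, int, int, int] = (24, 24, 18, 6)
    width: int = 800
    height: int = 600

    def __post_init__(self) -> None:
        missing = {"unchanged", "increased", "decreased"} - set(self.colors)
        if missing:
            raise ValueError(f"colors mapping lacks categories: {sorted(missing)}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.dot_size <= 0:
            raise ValueError("dot_size must be positive")


@dataclass
class LabelPlacement:
    """Final position of one text label in axes-fraction coordinates."""

    anchor: tuple[float, float]
    offset: tuple[float, float]
    box: tuple[float, float, float, float]  # (x0, y0, x1, y1)
    text: str


def _boxes_overlap(
    a: tuple[float, float, float, float], b: tuple[float, float, float, float]
) -> bool:
    return not (a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1])


def place_labels(
    anchors: Sequence[tuple[float, float]],
    texts: Sequence[str],
    bounds: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 1.0),
    max_iter: int = 100,
    char_width: float = 0.011,
    line_height: float = 0.035,
) -> list[LabelPlacement]:
    """Greedy pairwise label repulsion.

    Each label starts slightly above-right of its anchor.  Overlapping
    pairs are pushed apart along the vector joining their centers (a
    deterministic sideways nudge resolves exactly coincident centers),
    and boxes are clamped inside ``bounds`` each sweep.  The pass stops
    at convergence or after ``max_iter`` sweeps; any overlaps left are
    permitted and reported on the returned placements.

    Coordinates are axes fractions; box sizes are estimated from text
    length via ``char_width`` and ``line_height``.
    """
    if len(anchors) != len(texts):
        raise ValueError("anchors and texts must have equal length")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    x0b, y0b, x1b, y1b = bounds
    n = len(anchors)
    sizes = [(max(1, len(t)) * char_width, line_height) for t in texts]
    # initial center: above-right of the anchor
    centers = [
        [ax + sizes[i][0] / 2 + 0.01, ay + sizes[i][1] / 2 + 0.01]
        for i, (ax, ay) in enumerate(anchors)
    ]

    def clamp(i: int) -> None:
        w, h = sizes[i]
        centers[i][0] = min(max(centers[i][0], x0b + w / 2), x1b - w / 2)
        centers[i][1] = min(max(centers[i][1], y0b + h / 2), y1b - h / 2)

    def box(i: int) -> tuple[float, float, float, float]:
        w, h = sizes[i]
        cx, cy = centers[i]
        return (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)

    for i in range(n):
        clamp(i)
    for _ in range(max_iter):
        moved = False
        for i in range(n):
            for j in range(i + 1, n):
                bi, bj = box(i), box(j)
                if not _boxes_overlap(bi, bj):
                    continue
                dx = centers[j][0] - centers[i][0]
                dy = centers[j][1] - centers[i][1]
                if dx == 0.0 and dy == 0.0:
                    dx, dy = 0.0, 1e-3 * (j - i)  # deterministic tie-break
                # required separation along each axis
                need_x = (sizes[i][0] + sizes[j][0]) / 2 - abs(dx)
                need_y = (sizes[i][1] + sizes[j][1]) / 2 - abs(dy)
                if need_y <= need_x:
                    step = (need_y / 2 + 1e-4)
                    sign = 1.0 if dy >= 0 else -1.0
                    centers[i][1] -= sign * step
                    centers[j][1] += sign * step
                else:
                    step = (need_x / 2 + 1e-4)
                    sign = 1.0 if dx >= 0 else -1.0
                    centers[i][0] -= sign * step
                    centers[j][0] += sign * step
                clamp(i)
                clamp(j)
                moved = True
        if not moved:
            break
    placements = []
    for i in range(n):
        cx, cy = centers[i]
        placements.append(
            LabelPlacement(
                anchor=tuple(anchors[i]),
                offset=(cx - anchors[i][0], cy - anchors[i][1]),
                box=box(i),
                text=texts[i],
            )
        )
    return placements


def count_overlaps(placements: Sequence[LabelPlacement]) -> int:
    """Exhaustive pairwise overlap count (0 means all labels legible)."""
    n = len(placements)
    return sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if _boxes_overlap(placements[i].box, placements[j].box)
    )


@dataclass
class VolcanoFigure:
    """A rendered figure plus the inputs needed for interactive export."""

    figure: Figure
    data: VolcanoData
    thresholds: Thresholds
    hits: HitTable
    style: PlotStyle
    placements: list[LabelPlacement]

    def close(self) -> None:
        plt.close(self.figure)


def _axis_titles(data: VolcanoData, style: PlotStyle) -> tuple[str, str]:
    x_title = style.x_label or f"{data.x_label} (effect size)"
    y_title = style.y_label or f"{data.y_label} (significance)"
    return x_title, y_title


def render(
    data: VolcanoData,
    t: Thresholds,
    hits: Optional[HitTable] = None,
    style: Optional[PlotStyle] = None,
) -> VolcanoFigure:
    """Draw the volcano plot.

    All records are drawn colored by category (classification is applied
    if missing), dashed lines mark the three cutoffs, and each hit-table
    entry gets a repelled text label.  With ``style.rotated`` the effect
    size moves to the vertical axis.
    """
    if not data.records:
        raise NothingToPlotError("nothing to plot: the dataset has no records")
    style = style or PlotStyle()
    hits = hits if hits is not None else HitTable([], "manhattan", t)
    if any(r.category is None for r in data.records):
        classify_data(data, t)

    dpi = 100.0
    fig, ax = plt.subplots(
        figsize=(style.width / dpi, style.height / dpi), dpi=dpi
    )
    title_fs, axis_fs, tick_fs, label_fs = style.font_sizes

    def coords(x: float, y: float) -> tuple[float, float]:
        return (y, x) if style.rotated else (x, y)

    marker_area = style.dot_size ** 2  # slider value ~ marker radius in pt
    for cat in ("unchanged", "decreased", "increased"):
        pts = [r for r in data.records if r.category == cat]
        xs = [coords(r.x, r.y)[0] for r in pts]
        ys = [coords(r.x, r.y)[1] for r in pts]
        ax.scatter(
            xs,
            ys,
            s=marker_area,
            c=style.colors[cat],
            alpha=style.alpha,
            label=cat,
            linewidths=0,
        )

    if style.rotated:
        ax.axhline(t.fc_low, linestyle="--", color="black", linewidth=1)
        ax.axhline(t.fc_high, linestyle="--", color="black", linewidth=1)
        ax.axvline(t.sig, linestyle="--", color="black", linewidth=1)
    else:
        ax.axvline(t.fc_low, linestyle="--", color="black", linewidth=1)
        ax.axvline(t.fc_high, linestyle="--", color="black", linewidth=1)
        ax.axhline(t.sig, linestyle="--", color="black", linewidth=1)

    x_title, y_title = _axis_titles(data, style)
    if style.rotated:
        x_title, y_title = y_title, x_title
    ax.set_xlabel(x_title, fontsize=axis_fs)
    ax.set_ylabel(y_title, fontsize=axis_fs)
    ax.tick_params(labelsize=tick_fs)
    if style.title:
        ax.set_title(style.title, fontsize=title_fs)
    if style.show_legend:
        ax.legend(loc="best", fontsize=tick_fs)

    # labels are placed in axes-fraction space so repulsion is aspect-aware
    placements: list[LabelPlacement] = []
    if hits.entries:
        ax.autoscale_view()
        trans = ax.transLimits  # data -> axes fraction
        anchors = []
        for e in hits.entries:
            px, py = coords(e.record.x, e.record.y)
            fx, fy = trans.transform((px, py))
            anchors.append((float(fx), float(fy)))
        texts = [e.record.name for e in hits.entries]
        placements = place_labels(anchors, texts)
        for p in placements:
            ax.annotate(
                p.text,
                xy=p.anchor,
                xycoords="axes fraction",
                xytext=(p.anchor[0] + p.offset[0], p.anchor[1] + p.offset[1]),
                textcoords="axes fraction",
                fontsize=label_fs,
                ha="center",
                va="center",
            )
    fig.tight_layout()
    return VolcanoFigure(fig, data, t, hits, style, placements)


def export(vfig: VolcanoFigure, fmt: str, path) -> Path:
    """Write the figure to disk as png, pdf or interactive html."""
    path = Path(path)
    fmt = fmt.lower()
    if fmt == "png":
        vfig.figure.savefig(path, format="png", dpi=vfig.figure.dpi)
    elif fmt == "pdf":
        vfig.figure.savefig(path, format="pdf")
    elif fmt == "html":
        path.write_text(render_html(vfig), encoding="utf-8")
    else:
        raise UnsupportedFormatError(
            f"unsupported format {fmt!r}: choose from {EXPORT_FORMATS}"
        )
    return path


def export_auto(vfig: VolcanoFigure, path) -> Path:
    """Export with the format taken from the path's extension."""
    suffix = Path(path).suffix.lstrip(".").lower()
    return export(vfig, suffix, path)


# --------------------------------------------------------------------------
# standalone interactive HTML (SVG with native hover tooltips)

def _linmap(v: float, lo: float, hi: float, plo: float, phi: float) -> float:
    if hi == lo:
        return (plo + phi) / 2
    return plo + (v - lo) * (phi - plo) / (hi - lo)


def render_html(vfig: VolcanoFigure) -> str:
    """Build a self-contained HTML document with one hover entry per point.

    Each record becomes an SVG circle whose ``<title>`` child shows the
    name and the x/y coordinates rounded to 3 decimals — the browser
    displays it on hover with no JavaScript dependency.
    """
    data, t, style = vfig.data, vfig.thresholds, vfig.style
    W, H = style.width, style.height
    m = 60  # margin in px

    def pt(r):
        return (r.y, r.x) if style.rotated else (r.x, r.y)

    xs = [pt(r)[0] for r in data.records]
    ys = [pt(r)[1] for r in data.records]
    xlo, xhi = min(xs), max(xs)
    ylo, yhi = min(ys), max(ys)
    pad_x = 0.05 * (xhi - xlo or 1.0)
    pad_y = 0.05 * (yhi - ylo or 1.0)
    xlo, xhi = xlo - pad_x, xhi + pad_x
    ylo, yhi = ylo - pad_y, yhi + pad_y

    def sx(v: float) -> float:
        return _linmap(v, xlo, xhi, m, W - m)

    def sy(v: float) -> float:
        return _linmap(v, ylo, yhi, H - m, m)  # SVG y grows downward

    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        f"<title>{_html.escape(style.title or 'volcano plot')}</title>",
        "</head><body>",
        f"<svg width='{W}' height='{H}' xmlns='http://www.w3.org/2000/svg'>",
        f"<rect width='{W}' height='{H}' fill='white'/>",
    ]
    dash = "stroke='black' stroke-dasharray='6,4' stroke-width='1'"
    if style.rotated:
        guide_v = [t.sig]
        guide_h = [t.fc_low, t.fc_high]
    else:
        guide_v = [t.fc_low, t.fc_high]
        guide_h = [t.sig]
    for gv in guide_v:
        parts.append(
            f"<line x1='{sx(gv):.1f}' y1='{m}' x2='{sx(gv):.1f}' "
            f"y2='{H - m}' {dash}/>"
        )
    for gh in guide_h:
        parts.append(
            f"<line x1='{m}' y1='{sy(gh):.1f}' x2='{W - m}' "
            f"y2='{sy(gh):.1f}' {dash}/>"
        )
    radius = max(1.0, style.dot_size)
    for r in data.records:
        px, py = pt(r)
        color = style.colors.get(r.category or "unchanged", "grey")
        tip = _html.escape(f"{r.name}\nx: {r.x:.3f}\ny: {r.y:.3f}")
        parts.append(
            f"<circle cx='{sx(px):.1f}' cy='{sy(py):.1f}' r='{radius:.1f}' "
            f"fill='{color}' fill-opacity='{style.alpha}'>"
            f"<title>{tip}</title></circle>"
        )
    label_fs = style.font_sizes[3] + 4  # slightly larger for screen reading
    for e in vfig.hits.entries:
        px, py = pt(e.record)
        parts.append(
            f"<text x='{sx(px):.1f}' y='{sy(py) - radius - 2:.1f}' "
            f"font-size='{label_fs}' text-anchor='middle'>"
            f"{_html.escape(e.record.name)}</text>"
        )
    x_title, y_title = _axis_titles(data, style)
    if style.rotated:
        x_title, y_title = y_title, x_title
    parts.append(
        f"<text x='{W / 2:.0f}' y='{H - 15}' text-anchor='middle' "
        f"font-size='14'>{_html.escape(x_title)}</text>"
    )
    parts.append(
        f"<text x='15' y='{H / 2:.0f}' text-anchor='middle' font-size='14' "
        f"transform='rotate(-90 15 {H / 2:.0f})'>{_html.escape(y_title)}</text>"
    )
    if style.title:
        parts.append(
            f"<text x='{W / 2:.0f}' y='30' text-anchor='middle' "
            f"font-size='20'>{_html.escape(style.title)}</text>"
        )
    parts.append("</svg></body></html>")
    return "\n".join(parts)
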