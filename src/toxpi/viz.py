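"""Deterministic rendering of radial profiles, rank plots, and dendrograms.

Figures are built as a flat list of geometric primitives in pixel
coordinates (y down).  The SVG backend serialises the primitives with fixed
decimal formatting and no generated ids or timestamps, so output bytes are
a pure function of the inputs.  The PNG backend paints the same primitive
list through matplotlib Agg at a configurable DPI.

Profile anatomy: slices are laid out in model order starting at 12 o'clock
and proceeding clockwise; a slice's angular width is its weight share
(2π·w_i/Σw) and its arc radius is its unit-interval score.  An optional
confidence band is drawn as a lighter annulus between the lower and upper
interval radii, and an inner circle shades each slice's wedge by its
fraction of missing data (darker = more missing).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .data import DataError

__all__ = [
    "ProfileGeometry",
    "Figure",
    "profile_geometry",
    "render_profiles",
    "render_rank_plot",
    "render_dendrogram",
    "render_pca_scatter",
]

logger = logging.getLogger(__name__)

TAU = 2.0 * math.pi

#: inner-circle (missingness) radius as a fraction of the profile radius
INNER_FRAC = 0.18


# -- primitives ------------------------------------------------------------


@dataclass
class Wedge:
    """Annular sector; angles in radians clockwise from 12 o'clock."""

    cx: float
    cy: float
    r_inner: float
    r_outer: float
    a0: float
    a1: float
    fill: str
    stroke: str = "none"
    stroke_width: float = 0.0
    cls: str = ""


@dataclass
class Line:
    x0: float
    y0: float
    x1: float
    y1: float
    stroke: str = "#000000"
    width: float = 1.0
    cls: str = ""


@dataclass
class Polyline:
    points: list
    stroke: str = "#000000"
    width: float = 1.0
    cls: str = ""


@dataclass
class Arc:
    """Circular arc (no fill); angles clockwise from 12 o'clock."""

    cx: float
    cy: float
    r: float
    a0: float
    a1: float
    stroke: str = "#000000"
    width: float = 1.0
    cls: str = ""


@dataclass
class Rect:
    x: float
    y: float
    w: float
    h: float
    fill: str = "none"
    stroke: str = "none"
    stroke_width: float = 0.0
    cls: str = ""


@dataclass
class Circle:
    cx: float
    cy: float
    r: float
    fill: str = "none"
    stroke: str = "none"
    stroke_width: float = 0.0
    cls: str = ""


@dataclass
class Text:
    x: float
    y: float
    text: str
    size: float = 10.0
    anchor: str = "middle"  # start | middle | end
    fill: str = "#000000"
    cls: str = ""


@dataclass
class Figure:
    width: float
    height: float
    elements: list = field(default_factory=list)
    background: str = "#FFFFFF"

    def add(self, *prims) -> None:
        self.elements.extend(prims)

    # -- SVG backend ------------------------------------------------------

    def to_svg(self) -> str:
        out = [
            '<?xml version="1.0" encoding="UTF-8"?>',
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{_f(self.width)}" height="{_f(self.height)}" '
            f'viewBox="0 0 {_f(self.width)} {_f(self.height)}">',
            f'<rect x="0" y="0" width="{_f(self.width)}" '
            f'height="{_f(self.height)}" fill="{self.background}"/>',
        ]
        for e in self.elements:
            out.append(_svg_element(e))
        out.append("</svg>")
        return "\n".join(out) + "\n"

    def save(self, path, format: str = "svg", dpi: int = 300) -> None:
        if format == "svg":
            with open(path, "w", encoding="utf-8", newline="\n") as fh:
                fh.write(self.to_svg())
        elif format == "png":
            _paint_png(self, path, dpi)
        else:
            raise ValueError(f"unknown format {format!r} (svg or png)")


def _f(v: float) -> str:
    return f"{v:.6f}".rstrip("0").rstrip(".") if v == v else "0"


def _pt(cx: float, cy: float, r: float, a: float) -> tuple[float, float]:
    """Point at clockwise angle ``a`` from 12 o'clock (SVG coords, y down)."""
    return cx + r * math.sin(a), cy - r * math.cos(a)


def _arc_steps(a0: float, a1: float):
    """Split [a0, a1] into sub-arcs of at most a quarter turn."""
    span = a1 - a0
    n = max(1, int(math.ceil(abs(span) / (math.pi / 2) - 1e-9)))
    return [(a0 + span * k / n, a0 + span * (k + 1) / n) for k in range(n)]


def _arc_path(cx, cy, r, a0, a1, sweep: int) -> str:
    segs = []
    for _s0, s1 in _arc_steps(a0, a1):
        x, y = _pt(cx, cy, r, s1)
        segs.append(f"A {_f(r)} {_f(r)} 0 0 {sweep} {_f(x)} {_f(y)}")
    return " ".join(segs)


def _wedge_path(w: Wedge) -> str:
    x0, y0 = _pt(w.cx, w.cy, w.r_outer, w.a0)
    outer = _arc_path(w.cx, w.cy, w.r_outer, w.a0, w.a1, sweep=1)
    if w.r_inner <= 0:
        return f"M {_f(w.cx)} {_f(w.cy)} L {_f(x0)} {_f(y0)} {outer} Z"
    xi0, yi0 = _pt(w.cx, w.cy, w.r_inner, w.a0)
    xi1, yi1 = _pt(w.cx, w.cy, w.r_inner, w.a1)
    inner = _arc_path(w.cx, w.cy, w.r_inner, w.a1, w.a0, sweep=0)
    return (
        f"M {_f(xi0)} {_f(yi0)} L {_f(x0)} {_f(y0)} {outer} "
        f"L {_f(xi1)} {_f(yi1)} {inner} Z"
    )


def _svg_element(e) -> str:
    cls = f' class="{e.cls}"' if getattr(e, "cls", "") else ""
    if isinstance(e, Wedge):
        stroke = (
            f' stroke="{e.stroke}" stroke-width="{_f(e.stroke_width)}"'
            if e.stroke != "none"
            else ""
        )
        if e.r_outer <= 0:
            return f'<path d="M {_f(e.cx)} {_f(e.cy)} Z" fill="none"{cls}/>'
        return f'<path d="{_wedge_path(e)}" fill="{e.fill}"{stroke}{cls}/>'
    if isinstance(e, Arc):
        x0, y0 = _pt(e.cx, e.cy, e.r, e.a0)
        path = f"M {_f(x0)} {_f(y0)} " + _arc_path(e.cx, e.cy, e.r, e.a0, e.a1, 1)
        return (
            f'<path d="{path}" fill="none" stroke="{e.stroke}" '
            f'stroke-width="{_f(e.width)}"{cls}/>'
        )
    if isinstance(e, Line):
        return (
            f'<line x1="{_f(e.x0)}" y1="{_f(e.y0)}" x2="{_f(e.x1)}" '
            f'y2="{_f(e.y1)}" stroke="{e.stroke}" stroke-width="{_f(e.width)}"{cls}/>'
        )
    if isinstance(e, Polyline):
        pts = " ".join(f"{_f(x)},{_f(y)}" for x, y in e.points)
        return (
            f'<polyline points="{pts}" fill="none" stroke="{e.stroke}" '
            f'stroke-width="{_f(e.width)}"{cls}/>'
        )
    if isinstance(e, Rect):
        stroke = (
            f' stroke="{e.stroke}" stroke-width="{_f(e.stroke_width)}"'
            if e.stroke != "none"
            else ""
        )
        return (
            f'<rect x="{_f(e.x)}" y="{_f(e.y)}" width="{_f(e.w)}" '
            f'height="{_f(e.h)}" fill="{e.fill}"{stroke}{cls}/>'
        )
    if isinstance(e, Circle):
        stroke = (
            f' stroke="{e.stroke}" stroke-width="{_f(e.stroke_width)}"'
            if e.stroke != "none"
            else ""
        )
        return (
            f'<circle cx="{_f(e.cx)}" cy="{_f(e.cy)}" r="{_f(e.r)}" '
            f'fill="{e.fill}"{stroke}{cls}/>'
        )
    if isinstance(e, Text):
        return (
            f'<text x="{_f(e.x)}" y="{_f(e.y)}" font-size="{_f(e.size)}" '
            f'font-family="sans-serif" text-anchor="{e.anchor}" '
            f'fill="{e.fill}"{cls}>{_xml_escape(e.text)}</text>'
        )
    raise TypeError(f"unknown primitive: {e!r}")


def _xml_escape(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def _paint_png(fig: Figure, path, dpi: int) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.patches as mpatches
    import matplotlib.pyplot as plt

    f, ax = plt.subplots(figsize=(fig.width / 96, fig.height / 96), dpi=dpi)
    ax.set_xlim(0, fig.width)
    ax.set_ylim(fig.height, 0)
    ax.set_aspect("equal")
    ax.axis("off")
    f.patch.set_facecolor(fig.background)
    for e in fig.elements:
        if isinstance(e, Wedge):
            if e.r_outer <= 0:
                continue
            t1 = math.degrees(e.a0 - math.pi / 2)
            t2 = math.degrees(e.a1 - math.pi / 2)
            ax.add_patch(
                mpatches.Wedge(
                    (e.cx, e.cy), e.r_outer, t1, t2,
                    width=e.r_outer - e.r_inner if e.r_inner > 0 else None,
                    facecolor=e.fill,
                    edgecolor=e.stroke if e.stroke != "none" else "none",
                    linewidth=e.stroke_width,
                )
            )
        elif isinstance(e, Arc):
            t1 = math.degrees(e.a0 - math.pi / 2)
            t2 = math.degrees(e.a1 - math.pi / 2)
            ax.add_patch(
                mpatches.Arc(
                    (e.cx, e.cy), 2 * e.r, 2 * e.r, theta1=min(t1, t2),
                    theta2=max(t1, t2), edgecolor=e.stroke, linewidth=e.width,
                )
            )
        elif isinstance(e, Line):
            ax.plot([e.x0, e.x1], [e.y0, e.y1], color=e.stroke, linewidth=e.width)
        elif isinstance(e, Polyline):
            xs, ys = zip(*e.points)
            ax.plot(xs, ys, color=e.stroke, linewidth=e.width)
        elif isinstance(e, Rect):
            ax.add_patch(
                mpatches.Rectangle(
                    (e.x, e.y), e.w, e.h,
                    facecolor=e.fill if e.fill != "none" else "none",
                    edgecolor=e.stroke if e.stroke != "none" else "none",
                    linewidth=e.stroke_width,
                )
            )
        elif isinstance(e, Circle):
            ax.add_patch(
                mpatches.Circle(
                    (e.cx, e.cy), e.r,
                    facecolor=e.fill if e.fill != "none" else "none",
                    edgecolor=e.stroke if e.stroke != "none" else "none",
                    linewidth=e.stroke_width,
                )
            )
        elif isinstance(e, Text):
            ha = {"start": "left", "middle": "center", "end": "right"}[e.anchor]
            ax.text(e.x, e.y, e.text, fontsize=e.size * 0.75, ha=ha, va="center",
                    color=e.fill)
    f.savefig(path, dpi=dpi, facecolor=fig.background)
    plt.close(f)


# -- color helpers ---------------------------------------------------------


def _blend_white(color: str, frac: float = 0.55) -> str:
    """Lighter shade of a #RRGGBB color (frac toward white)."""
    r, g, b = (int(color[i : i + 2], 16) for i in (1, 3, 5))
    mix = lambda c: int(round(c + (255 - c) * frac))
    return f"#{mix(r):02X}{mix(g):02X}{mix(b):02X}"


def _gray(level: float) -> str:
    """Grayscale with luminance ``level`` in [0, 1]."""
    v = int(round(255 * min(max(level, 0.0), 1.0)))
    return f"#{v:02X}{v:02X}{v:02X}"


# -- profile geometry ------------------------------------------------------


@dataclass
class SliceGeometry:
    name: str
    start_angle: float
    end_angle: float
    arc_radius: float  # == slice score, fraction of max radius
    color: str
    missingness: float
    ci_lo: float | None = None
    ci_hi: float | None = None


@dataclass
class ProfileGeometry:
    entity_id: str
    slices: list


def profile_geometry(scores, model, entity_id: str, ci=None) -> ProfileGeometry:
    """Angular layout for one entity: model order, 12 o'clock start, clockwise."""
    i = scores.row(entity_id)
    w = model.weights
    frac = w / w.sum()
    angles = np.concatenate([[0.0], np.cumsum(frac)]) * TAU
    out = []
    for k, s in enumerate(model.slices):
        lo = hi = None
        if ci is not None:
            lo = float(np.clip(ci.slice_lo[i, k], 0.0, 1.0))
            hi = float(np.clip(ci.slice_hi[i, k], 0.0, 1.0))
        out.append(
            SliceGeometry(
                name=s.name,
                start_angle=float(angles[k]),
                end_angle=float(angles[k + 1]),
                arc_radius=float(scores.slice_scores[i, k]),
                color=s.color,
                missingness=float(scores.missingness[i, k]),
                ci_lo=lo,
                ci_hi=hi,
            )
        )
    return ProfileGeometry(entity_id=entity_id, slices=out)


def _draw_profile(fig, geom: ProfileGeometry, cx, cy, R, contrast_bg=False):
    if contrast_bg:
        fig.add(Circle(cx, cy, R * 1.02, fill="#F0F0F0", cls="profile-bg"))
    fig.add(Circle(cx, cy, R, fill="none", stroke="#CCCCCC", stroke_width=0.5,
                   cls="profile-outline"))
    r0 = INNER_FRAC * R
    for g in geom.slices:
        if g.ci_lo is not None and g.ci_hi > g.ci_lo:
            fig.add(
                Wedge(cx, cy, max(g.ci_lo * R, 1e-9), g.ci_hi * R,
                      g.start_angle, g.end_angle,
                      fill=_blend_white(g.color), cls="ci-band")
            )
        if g.arc_radius > 0:
            fig.add(
                Wedge(cx, cy, 0.0, g.arc_radius * R, g.start_angle, g.end_angle,
                      fill=g.color, stroke="#FFFFFF", stroke_width=0.5,
                      cls="slice-arc")
            )
        # separators make zero-score slices legible
        x1, y1 = _pt(cx, cy, R, g.start_angle)
        fig.add(Line(cx, cy, x1, y1, stroke="#DDDDDD", width=0.4, cls="separator"))
        # inner circle: darker = more missing
        fig.add(
            Wedge(cx, cy, 0.0, r0, g.start_angle, g.end_angle,
                  fill=_gray(1.0 - g.missingness), stroke="#999999",
                  stroke_width=0.3, cls="missingness")
        )


def render_profiles(
    entity_ids,
    scores,
    model,
    path,
    ci=None,
    n_cols: int = 4,
    cell: float = 160.0,
    format: str = "svg",
    contrast_bg: bool = False,
    dpi: int = 300,
) -> Figure:
    """Grid of radial profiles with entity labels underneath."""
    entity_ids = list(entity_ids)
    if not entity_ids:
        raise DataError("render_profiles requires at least one entity")
    n = len(entity_ids)
    n_cols = max(1, min(n_cols, n))
    n_rows = (n + n_cols - 1) // n_cols
    label_h = 18.0
    fig = Figure(width=n_cols * cell, height=n_rows * (cell + label_h))
    R = cell * 0.42
    for idx, e in enumerate(entity_ids):
        geom = profile_geometry(scores, model, e, ci=ci)
        r, c = divmod(idx, n_cols)
        cx = c * cell + cell / 2
        cy = r * (cell + label_h) + cell / 2
        _draw_profile(fig, geom, cx, cy, R, contrast_bg=contrast_bg)
        fig.add(Text(cx, cy + R + 14, e, size=10, cls="entity-label"))
    if path is not None:
        fig.save(path, format=format, dpi=dpi)
    return fig


# -- rank plot -------------------------------------------------------------


def render_rank_plot(
    scores,
    path,
    ci=None,
    ci_mode: str = "score",
    highlight=(),
    format: str = "svg",
    dpi: int = 300,
    n_bins: int = 20,
) -> Figure:
    """Overall score vs priority rank (rank 1 topmost) with a score histogram.

    ``ci_mode`` selects score-wise (horizontal) or rank-wise (vertical)
    whiskers when a ConfidenceResult is given; highlighted entities are
    drawn as larger blue dots and as vertical lines on the histogram.
    """
    highlight = list(highlight)
    for e in highlight:
        scores.row(e)  # raises for unscored ids
    n = len(scores.entity_ids)
    W, Hs, Hh, m = 520.0, 340.0, 130.0, 45.0
    fig = Figure(width=W, height=Hs + Hh + 3 * m)

    def sx(v: float) -> float:
        return m + v * (W - 2 * m)

    def sy(rank: float) -> float:
        return m + (rank - 1) / max(n - 1, 1) * (Hs - 2 * 10.0)

    # axes
    fig.add(Line(m, m - 10, m, m + Hs - 20, stroke="#333333", cls="axis"))
    fig.add(Line(m, m + Hs - 20, W - m, m + Hs - 20, stroke="#333333", cls="axis"))
    fig.add(Text(W / 2, m + Hs + 5, "ToxPi score", size=11, cls="axis-label"))
    fig.add(Text(12, m + Hs / 2, "rank", size=11, cls="axis-label"))

    hset = set(highlight)
    if ci is not None:
        for i in range(n):
            if ci_mode == "score":
                fig.add(Line(sx(float(ci.overall_lo[i])), sy(int(scores.rank[i])),
                             sx(float(ci.overall_hi[i])), sy(int(scores.rank[i])),
                             stroke="#BBBBBB", width=1.0, cls="ci-whisker"))
            elif ci_mode == "rank":
                fig.add(Line(sx(float(scores.overall[i])), sy(int(ci.rank_lo[i])),
                             sx(float(scores.overall[i])), sy(int(ci.rank_hi[i])),
                             stroke="#BBBBBB", width=1.0, cls="ci-whisker"))
    for i, e in enumerate(scores.entity_ids):
        hl = e in hset
        fig.add(
            Circle(sx(float(scores.overall[i])), sy(int(scores.rank[i])),
                   4.5 if hl else 2.5,
                   fill="#1F77B4" if hl else "#555555",
                   cls="rank-point-highlight" if hl else "rank-point")
        )

    # histogram of scores
    top = Hs + 2 * m
    counts, edges = np.histogram(scores.overall, bins=n_bins, range=(0.0, 1.0))
    cmax = max(int(counts.max()), 1)
    for b in range(n_bins):
        h = counts[b] / cmax * (Hh - 10)
        fig.add(
            Rect(sx(float(edges[b])), top + (Hh - 10) - h,
                 (W - 2 * m) / n_bins - 1.0, h,
                 fill="#888888", cls="hist-bar")
        )
    fig.add(Line(m, top + Hh - 10, W - m, top + Hh - 10, stroke="#333333",
                 cls="axis"))
    for e in highlight:
        i = scores.row(e)
        x = sx(float(scores.overall[i]))
        fig.add(Line(x, top, x, top + Hh - 10, stroke="#1F77B4", width=1.5,
                     cls="hist-highlight"))
    if path is not None:
        fig.save(path, format=format, dpi=dpi)
    return fig


# -- dendrograms -----------------------------------------------------------


def render_dendrogram(
    dend,
    path,
    scores=None,
    model=None,
    layout: str = "hanging",
    color_map=None,
    leaf_style: str = "label",
    distribute: bool = True,
    format: str = "svg",
    dpi: int = 300,
) -> Figure:
    """Draw a merge tree with heights to scale.

    ``layout`` is ``hanging`` (root on top) or ``circular`` (leaves on a
    circle; ``distribute=True`` spaces them uniformly at 2π/n).  Leaves carry
    text labels or miniature profiles (``leaf_style='profile'``, requires
    scores + model).  Edge colors follow ``color_map`` (node id → color),
    e.g. from :func:`toxpi.hier_cluster.auto_color`.
    """
    n = dend.n_leaves
    if leaf_style == "profile" and (scores is None or model is None):
        raise DataError("leaf_style='profile' requires scores and model")
    if leaf_style == "profile" and n > 500:
        logger.warning("%d leaves: downgrading profile leaves to labels", n)
        leaf_style = "label"
    color_map = color_map or {}
    names = dend.entity_ids or [str(i) for i in range(n)]
    hmax = float(dend.heights.max()) if len(dend.heights) else 1.0
    hmax = hmax if hmax > 0 else 1.0
    order = dend.leaf_order
    pos_of = {leaf: i for i, leaf in enumerate(order)}

    def edge_color(node: int) -> str:
        return color_map.get(node, "#333333")

    node_h = dend.node_height
    children = dend.children

    if layout == "hanging":
        leaf_gap = 46.0 if leaf_style == "profile" else 22.0
        W = 2 * 60.0 + (n - 1) * leaf_gap
        Ht, top, bottom = 420.0, 30.0, 90.0 if leaf_style == "profile" else 60.0
        fig = Figure(width=max(W, 240.0), height=Ht)

        def x_of(i: int) -> float:
            return 60.0 + i * leaf_gap

        def y_of(h: float) -> float:
            return top + (1.0 - h / hmax) * (Ht - top - bottom)

        xpos: dict[int, float] = {}

        def place(node: int) -> float:
            ch = children(node)
            if ch is None:
                xpos[node] = x_of(pos_of[node])
            else:
                xpos[node] = 0.5 * (place(ch[0]) + place(ch[1]))
            return xpos[node]

        place(dend.root)
        for k in range(n - 1):
            a, b = dend.merges[k]
            node = n + k
            y = y_of(node_h(node))
            fig.add(Line(xpos[a], y, xpos[b], y, stroke=edge_color(node),
                         width=1.2, cls="junction"))
            for chn in (a, b):
                fig.add(Line(xpos[chn], y, xpos[chn], y_of(node_h(chn)),
                             stroke=edge_color(chn), width=1.2, cls="stem"))
        for leaf in order:
            x, y = xpos[leaf], y_of(0.0)
            if leaf_style == "profile":
                geom = profile_geometry(scores, model, names[leaf])
                _draw_profile(fig, geom, x, y + 24, 18.0)
            else:
                fig.add(Text(x, y + 14, names[leaf], size=9, cls="leaf-label"))
    elif layout == "circular":
        R_leaf, pad = 190.0, 110.0 if leaf_style == "profile" else 70.0
        size = 2 * (R_leaf + pad)
        cx = cy = size / 2
        fig = Figure(width=size, height=size)
        r_root = 20.0

        def r_of(h: float) -> float:
            return r_root + (1.0 - h / hmax) * (R_leaf - r_root)

        span = TAU if distribute else TAU * (n - 1) / n * 0.875
        ang: dict[int, float] = {}
        for leaf in order:
            i = pos_of[leaf]
            ang[leaf] = (i * TAU / n) if distribute else (
                i * span / max(n - 1, 1)
            )

        def place(node: int) -> float:
            ch = children(node)
            if ch is None:
                return ang[node]
            ang[node] = 0.5 * (place(ch[0]) + place(ch[1]))
            return ang[node]

        place(dend.root)
        for k in range(n - 1):
            a, b = dend.merges[k]
            node = n + k
            r = r_of(node_h(node))
            a0, a1 = sorted((ang[a], ang[b]))
            fig.add(Arc(cx, cy, r, a0, a1, stroke=edge_color(node), width=1.2,
                        cls="junction"))
            for chn in (a, b):
                x0, y0 = _pt(cx, cy, r, ang[chn])
                x1, y1 = _pt(cx, cy, r_of(node_h(chn)), ang[chn])
                fig.add(Line(x0, y0, x1, y1, stroke=edge_color(chn), width=1.2,
                             cls="stem"))
        for leaf in order:
            if leaf_style == "profile":
                x, y = _pt(cx, cy, R_leaf + 45.0, ang[leaf])
                geom = profile_geometry(scores, model, names[leaf])
                _draw_profile(fig, geom, x, y, min(18.0, TAU / n * R_leaf))
            else:
                x, y = _pt(cx, cy, R_leaf + 16.0, ang[leaf])
                fig.add(Text(x, y, names[leaf], size=8, cls="leaf-label"))
    else:
        raise DataError(f"unknown layout {layout!r} (hanging or circular)")

    if path is not None:
        fig.save(path, format=format, dpi=dpi)
    return fig


# -- k-means / PCA display -------------------------------------------------

_MARKER_COLORS = (
    "#1F77B4", "#FF7F0E", "#2CA02C", "#D62728", "#9467BD",
    "#8C564B", "#E377C2", "#7F7F7F", "#BCBD22", "#17BECF",
)


def render_pca_scatter(
    projection,
    path,
    labels=None,
    entity_ids=None,
    highlight=(),
    format: str = "svg",
    dpi: int = 300,
) -> Figure:
    """Entities on the top-2 principal-component plane, colored by cluster."""
    coords = np.asarray(projection.coords, dtype=float)
    n = coords.shape[0]
    W = H = 440.0
    m = 50.0
    fig = Figure(width=W, height=H)
    span = max(float(np.abs(coords).max()), 1e-9) * 1.1

    def sx(v: float) -> float:
        return W / 2 + v / span * (W / 2 - m)

    def sy(v: float) -> float:
        return H / 2 - v / span * (H / 2 - m)

    fig.add(Line(m, H / 2, W - m, H / 2, stroke="#DDDDDD", cls="axis"))
    fig.add(Line(W / 2, m, W / 2, H - m, stroke="#DDDDDD", cls="axis"))
    vx, vy = projection.var_explained
    fig.add(Text(W / 2, H - 14, f"PC1 ({100 * vx:.1f}%)", size=10, cls="axis-label"))
    fig.add(Text(16, H / 2, f"PC2 ({100 * vy:.1f}%)", size=10, cls="axis-label"))
    hset = set(highlight)
    for i in range(n):
        color = "#555555"
        if labels is not None:
            color = _MARKER_COLORS[(int(labels[i]) - 1) % len(_MARKER_COLORS)]
        eid = entity_ids[i] if entity_ids else str(i)
        hl = eid in hset
        fig.add(
            Circle(sx(coords[i, 0]), sy(coords[i, 1]), 5.0 if hl else 3.0,
                   fill=color, stroke="#1F77B4" if hl else "none",
                   stroke_width=1.5 if hl else 0.0, cls="pca-point")
        )
    if path is not None:
        fig.save(path, format=format, dpi=dpi)
    return fig
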