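"""Realize a PlotSpec as static SVG/PNG or a self-contained interactive HTML.

The SVG backend is a small purpose-built emitter: every point becomes one
``<g class="point">`` holding a halo ``<circle class="halo">`` (diameter =
the encoded case-count size, fill = category color), a central dot, an
optional dark ``<circle class="ring">`` for fine-mapped traits, and a
``<title>`` tooltip with the association statistics.  Hulls are literal
``<polygon>`` elements.  Output is byte-deterministic — fixed element
order (points are pre-sorted by trait_id in the spec), fixed number
formatting, no timestamps — so figures can be golden-file tested and
mark counts asserted by parsing.

PNG export goes through matplotlib (Agg); the HTML export embeds the same
SVG in a minimal page, where browsers show the ``<title>`` tooltips on
hover (no JavaScript dependency).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union
from xml.sax.saxutils import escape, quoteattr

from .plotspec import PlotSpec
from .transforms import PlotPoint

__all__ = ["render_static", "render_html", "plot_spec_svg"]

# canvas geometry (px)
_W, _H = 880, 620
_ML, _MR, _MT, _MB = 80, 230, 50, 70


def _fmt(v: float) -> str:
    """Fixed decimal formatting for coordinates: deterministic, no exponents."""
    return f"{v:.2f}"


def _tick_values(lo: float, hi: float, n: int = 5) -> list[float]:
    """Round-numbered axis ticks covering [lo, hi] (1/2/5 ladder)."""
    span = hi - lo
    if span <= 0:
        return [lo]
    import math

    raw = span / max(n - 1, 1)
    mag = 10.0 ** math.floor(math.log10(raw))
    for mult in (1.0, 2.0, 2.5, 5.0, 10.0):
        step = mult * mag
        if span / step <= n + 1:
            break
    first = math.ceil(lo / step) * step
    ticks = []
    t = first
    while t <= hi + 1e-9 * span:
        ticks.append(0.0 if abs(t) < 1e-12 else t)
        t += step
    return ticks


def _tooltip(p: PlotPoint) -> str:
    rec = p.source
    pval = rec.resolved_pval()
    cases = rec.n_cases if rec.n_cases is not None else "NA"
    return f"{p.label} | beta={p.x:g} | P={pval:.3g} | cases={cases}"


def plot_spec_svg(spec: PlotSpec) -> str:
    """Serialize a PlotSpec to a standalone SVG 1.1 document."""
    x0, x1 = spec.x_range
    y0, y1 = spec.y_range
    pw = _W - _ML - _MR
    ph = _H - _MT - _MB

    def sx(x: float) -> float:
        return _ML + (x - x0) / (x1 - x0) * pw if x1 > x0 else _ML + pw / 2

    def sy(y: float) -> float:
        return _MT + (1.0 - (y - y0) / (y1 - y0)) * ph if y1 > y0 else _MT + ph / 2

    out: list[str] = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_W}" height="{_H}" viewBox="0 0 {_W} {_H}">'
    )
    out.append(f'<rect width="{_W}" height="{_H}" fill="#ffffff"/>')
    out.append(
        f'<text x="{_fmt(_ML + pw / 2)}" y="28" text-anchor="middle" '
        f'font-family="sans-serif" font-size="16">{escape(spec.title)}</text>'
    )

    # axes
    ax_y = _MT + ph
    out.append(
        f'<line x1="{_ML}" y1="{ax_y}" x2="{_ML + pw}" y2="{ax_y}" stroke="#000" stroke-width="1"/>'
    )
    out.append(
        f'<line x1="{_ML}" y1="{_MT}" x2="{_ML}" y2="{ax_y}" stroke="#000" stroke-width="1"/>'
    )
    for t in _tick_values(x0, x1):
        px = sx(t)
        out.append(
            f'<line x1="{_fmt(px)}" y1="{ax_y}" x2="{_fmt(px)}" y2="{ax_y + 5}" stroke="#000" stroke-width="1"/>'
        )
        out.append(
            f'<text x="{_fmt(px)}" y="{ax_y + 20}" text-anchor="middle" '
            f'font-family="sans-serif" font-size="11">{t:g}</text>'
        )
    for t in _tick_values(y0, y1):
        py = sy(t)
        out.append(
            f'<line x1="{_ML - 5}" y1="{_fmt(py)}" x2="{_ML}" y2="{_fmt(py)}" stroke="#000" stroke-width="1"/>'
        )
        out.append(
            f'<text x="{_ML - 9}" y="{_fmt(py + 4)}" text-anchor="end" '
            f'font-family="sans-serif" font-size="11">{t:g}</text>'
        )
    out.append(
        f'<text x="{_fmt(_ML + pw / 2)}" y="{_H - 18}" text-anchor="middle" '
        f'font-family="sans-serif" font-size="13">{escape(spec.x_label)}</text>'
    )
    out.append(
        f'<text x="22" y="{_fmt(_MT + ph / 2)}" text-anchor="middle" '
        f'font-family="sans-serif" font-size="13" '
        f'transform="rotate(-90 22 {_fmt(_MT + ph / 2)})">{escape(spec.y_label)}</text>'
    )

    # genome-wide significance line, labeled with its rounded value
    if y0 <= spec.threshold_line <= y1:
        ty = sy(spec.threshold_line)
        out.append(
            f'<line class="threshold" x1="{_ML}" y1="{_fmt(ty)}" x2="{_ML + pw}" y2="{_fmt(ty)}" '
            f'stroke="#b22222" stroke-width="1" stroke-dasharray="6,4"/>'
        )
        out.append(
            f'<text x="{_ML + pw + 4}" y="{_fmt(ty + 4)}" font-family="sans-serif" '
            f'font-size="11" fill="#b22222">{round(spec.threshold_line, 1):g}</text>'
        )

    # category hulls under the points
    for h in spec.hulls:
        color = dict(spec.legend).get(h.category, "#999999")
        pts = " ".join(f"{_fmt(sx(v.x))},{_fmt(sy(v.y))}" for v in h.vertices)
        out.append(
            f'<polygon class="hull" data-category={quoteattr(h.category)} points="{pts}" '
            f'fill="{color}" fill-opacity="0.15" stroke="{color}" stroke-width="1.5"/>'
        )

    labelled = set(spec.labels)
    for p in spec.points:
        cx, cy = _fmt(sx(p.x)), _fmt(sy(p.y))
        r_halo = _fmt(p.halo_diameter / 2.0)
        out.append(f"<g class=\"point\" data-trait-id={quoteattr(p.source.trait_id)}>")
        out.append(f"<title>{escape(_tooltip(p))}</title>")
        out.append(
            f'<circle class="halo" cx="{cx}" cy="{cy}" r="{r_halo}" '
            f'fill="{p.color}" fill-opacity="0.45"/>'
        )
        if p.fine_mapped:
            out.append(
                f'<circle class="ring" cx="{cx}" cy="{cy}" r="5" '
                f'fill="none" stroke="#111111" stroke-width="1.8"/>'
            )
        out.append(f'<circle class="dot" cx="{cx}" cy="{cy}" r="2.5" fill="#222222"/>')
        if p.source.trait_id in labelled:
            out.append(
                f'<text class="pin" x="{_fmt(sx(p.x) + 8)}" y="{_fmt(sy(p.y) - 8)}" '
                f'font-family="sans-serif" font-size="10">{escape(_tooltip(p))}</text>'
            )
        out.append("</g>")

    # legend: category colors, then the halo-size key
    lx = _ML + pw + 36
    ly = _MT + 10
    out.append(
        f'<text x="{lx}" y="{ly}" font-family="sans-serif" font-size="12" '
        f'font-weight="bold">Category</text>'
    )
    for i, (cat, color) in enumerate(spec.legend):
        cy = ly + 18 + i * 18
        out.append(
            f'<circle class="legend-swatch" cx="{lx + 6}" cy="{cy - 4}" r="6" '
            f'fill="{color}" fill-opacity="0.45"/>'
        )
        shown = cat if len(cat) <= 28 else cat[:27] + "…"
        out.append(
            f'<text x="{lx + 18}" y="{cy}" font-family="sans-serif" font-size="11">{escape(shown)}</text>'
        )
    if spec.halo_key:
        ky = ly + 18 * (len(spec.legend) + 2)
        out.append(
            f'<text x="{lx}" y="{ky}" font-family="sans-serif" font-size="12" '
            f'font-weight="bold">Cases</text>'
        )
        for i, (n, d) in enumerate(spec.halo_key):
            cy = ky + 20 + i * 24
            out.append(
                f'<circle class="legend-halo" cx="{lx + 15}" cy="{cy - 4}" r="{_fmt(d / 2)}" '
                f'fill="none" stroke="#555555" stroke-width="1"/>'
            )
            out.append(
                f'<text x="{lx + 36}" y="{cy}" font-family="sans-serif" font-size="11">{n}</text>'
            )

    out.append("</svg>")
    return "\n".join(out) + "\n"


def _render_png(spec: PlotSpec, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon

    fig, ax = plt.subplots(figsize=(8.8, 6.2), dpi=100)
    for h in spec.hulls:
        color = dict(spec.legend).get(h.category, "#999999")
        ax.add_patch(
            MplPolygon(
                [(v.x, v.y) for v in h.vertices],
                closed=True, facecolor=color, alpha=0.15,
                edgecolor=color, linewidth=1.5,
            )
        )
    for p in spec.points:
        ax.scatter([p.x], [p.y], s=p.halo_diameter ** 2, c=p.color, alpha=0.45,
                   linewidths=0, zorder=2)
        if p.fine_mapped:
            ax.scatter([p.x], [p.y], s=100, facecolors="none", edgecolors="#111111",
                       linewidths=1.8, zorder=3)
        ax.scatter([p.x], [p.y], s=10, c="#222222", zorder=4)
    ax.axhline(spec.threshold_line, color="#b22222", linewidth=1, linestyle="--")
    ax.text(spec.x_range[1], spec.threshold_line, f"{round(spec.threshold_line, 1):g}",
            color="#b22222", fontsize=9, va="bottom", ha="right")
    ax.set_xlim(*spec.x_range)
    ax.set_ylim(*spec.y_range)
    ax.set_xlabel(spec.x_label)
    ax.set_ylabel(spec.y_label)
    ax.set_title(spec.title)
    handles = [
        plt.Line2D([], [], marker="o", linestyle="", markersize=8,
                   markerfacecolor=color, alpha=0.45, markeredgewidth=0, label=cat)
        for cat, color in spec.legend
    ]
    if handles:
        ax.legend(handles=handles, loc="center left", bbox_to_anchor=(1.02, 0.5),
                  fontsize=8, frameon=False)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def render_static(spec: PlotSpec, path: Union[str, Path], format: str = "svg") -> Path:
    """Write the figure as SVG (deterministic, structurally testable) or PNG."""
    path = Path(path)
    if format == "svg":
        path.write_text(plot_spec_svg(spec), encoding="utf-8")
    elif format == "png":
        _render_png(spec, path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'svg' or 'png')")
    return path


_HTML_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8"/>
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 1em; }}
svg .point:hover .halo {{ fill-opacity: 0.85; }}
svg .point .dot {{ cursor: crosshair; }}
</style>
</head>
<body>
{svg}
<p>Hover a dot for trait name, effect size (beta), P-value and case count.
Dark rings mark traits fine-mapped to this variant; shaded polygons are
per-category convex hulls; the dashed line is genome-wide significance.</p>
</body>
</html>
"""


def render_html(spec: PlotSpec, path: Union[str, Path]) -> Path:
    """Write a single self-contained interactive HTML file.

    The embedded SVG carries a ``<title>`` per point, which browsers show
    as a hover tooltip with the trait name, beta, P-value and case count.
    """
    path = Path(path)
    html = _HTML_TEMPLATE.format(title=escape(spec.title), svg=plot_spec_svg(spec))
    path.write_text(html, encoding="utf-8")
    return path
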