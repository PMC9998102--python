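"""Renderer-independent description of a complete PheWAS volcano figure.

:func:`build_plot_spec` turns validated association records into a
:class:`PlotSpec` — axes, encoded points, per-category hulls, legend and
the genome-wide significance line — which the backends in
:mod:`phewas_volcano.render` realize as SVG, PNG or interactive HTML.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .hulls import HullPolygon, Point2D, category_hulls, expand_hull
from .records import (
    AssociationRecord,
    CategoryPalette,
    assign_colors,
    mark_finemapped,
)
from .transforms import (
    GENOME_WIDE_P,
    PlotPoint,
    SignificanceFilter,
    filter_significant,
    halo_diameter,
    linear_halo_diameter,
)

__all__ = ["PlotSpec", "build_plot_spec"]


@dataclass
class PlotSpec:
    """Everything a renderer needs to draw the figure, and nothing backend-specific."""

    title: str
    x_label: str
    x_range: tuple[float, float]
    y_label: str
    y_range: tuple[float, float]
    points: list[PlotPoint]
    hulls: list[HullPolygon]
    legend: list[tuple[str, str]]
    halo_key: list[tuple[int, float]]  # (reference case count, diameter)
    threshold_line: float
    labels: list[str] = field(default_factory=list)  # pinned trait_ids

    def to_dict(self) -> dict:
        """JSON-safe form (used for golden-file testing); the record behind
        each point is referenced by trait_id, not embedded."""
        return {
            "title": self.title,
            "x_axis": {"label": self.x_label, "range": list(self.x_range)},
            "y_axis": {"label": self.y_label, "range": list(self.y_range)},
            "points": [
                {
                    "trait_id": p.source.trait_id,
                    "x": p.x,
                    "y": p.y,
                    "halo_diameter": p.halo_diameter,
                    "color": p.color,
                    "fine_mapped": p.fine_mapped,
                    "label": p.label,
                }
                for p in self.points
            ],
            "hulls": [
                {
                    "category": h.category,
                    "vertices": [[v.x, v.y] for v in h.vertices],
                    "padding": h.padding,
                }
                for h in self.hulls
            ],
            "legend": [list(pair) for pair in self.legend],
            "halo_key": [list(pair) for pair in self.halo_key],
            "threshold_line": self.threshold_line,
            "labels": list(self.labels),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def build_plot_spec(
    records: Sequence[AssociationRecord],
    *,
    sig_filter: Optional[SignificanceFilter] = None,
    hulls_on: bool = False,
    palette: Optional[CategoryPalette] = None,
    pip_threshold: float = 0.5,
    d_min: float = 6.0,
    d_max: float = 30.0,
    hull_min_points: int = 3,
    hull_padding: float = 0.05,
    halo_scale: str = "sqrt",
    p_threshold: float = GENOME_WIDE_P,
    title: Optional[str] = None,
    labels: Sequence[str] = (),
) -> PlotSpec:
    """Assemble a volcano-plot description from association records.

    When ``sig_filter`` is given the plot zooms to the records it keeps
    (and, per the zoom semantics, halo diameters and hulls are recomputed
    on the displayed subset).  ``hulls_on`` adds one convex hull per
    category with at least ``hull_min_points`` non-degenerate displayed
    points, padded outward by ``hull_padding`` data units.  ``halo_scale``
    is ``"sqrt"`` (halo area tracks case count; default) or ``"linear"``
    (diameter tracks case count).  The genome-wide significance line is
    always drawn, at -log10 of the active P threshold.

    The x-axis is symmetric about 0 for all-dichotomous inputs (risk and
    protective effects read symmetrically); tables containing continuous
    traits get a data-driven asymmetric range.

    Raises ValueError when filtering leaves nothing to plot.
    """
    if halo_scale not in ("sqrt", "linear"):
        raise ValueError(f"unknown halo_scale {halo_scale!r}")
    shown = list(records)
    active_p = sig_filter.p_threshold if sig_filter is not None else p_threshold
    if sig_filter is not None:
        shown = filter_significant(shown, sig_filter)
    if not shown:
        raise ValueError("empty plot: no records survive filtering")

    shown = mark_finemapped(shown, pip_threshold)
    if palette is None:
        palette = assign_colors(r.category for r in shown)

    # halo scaling range from the *displayed* subset; continuous traits
    # (no case count) always get the minimum halo
    counts = [r.n_cases for r in shown if r.n_cases is not None]
    n_min = min(counts) if counts else 0
    n_max = max(counts) if counts else 0
    scale = halo_diameter if halo_scale == "sqrt" else linear_halo_diameter

    def diameter(rec: AssociationRecord) -> float:
        if rec.n_cases is None or not counts:
            return d_min
        return scale(rec.n_cases, n_min, n_max, d_min, d_max)

    points = [
        PlotPoint(
            x=rec.beta,
            y=rec.resolved_mlogp(),
            halo_diameter=diameter(rec),
            color=palette[rec.category],
            fine_mapped=rec.fine_mapped,
            label=rec.trait_name,
            source=rec,
        )
        for rec in sorted(shown, key=lambda r: r.trait_id)
    ]

    max_abs_x = max(abs(p.x) for p in points) or 1.0
    if all(p.source.is_binary for p in points):
        x_range = (-1.05 * max_abs_x, 1.05 * max_abs_x)
    else:
        lo = min(p.x for p in points)
        hi = max(p.x for p in points)
        pad = 0.05 * (hi - lo) if hi > lo else 0.05 * max_abs_x
        x_range = (lo - pad, hi + pad)
    max_y = max(p.y for p in points)
    y_range = (0.0, 1.05 * max_y if max_y > 0 else 1.0)

    hulls: list[HullPolygon] = []
    if hulls_on:
        hulls = category_hulls(
            [(Point2D(p.x, p.y), p.source.category) for p in points],
            min_points=hull_min_points,
        )
        if hull_padding > 0:
            hulls = [expand_hull(h, hull_padding) for h in hulls]

    present = sorted({p.source.category for p in points})
    legend = [(cat, palette[cat]) for cat in present]

    if counts and n_max > n_min:
        mid = int(round(math.sqrt(n_min * n_max))) if n_min > 0 else (n_min + n_max) // 2
        refs = sorted({n_min, mid, n_max})
    elif counts:
        refs = [n_min]
    else:
        refs = []
    halo_key = [(n, scale(n, n_min, n_max, d_min, d_max)) for n in refs]

    return PlotSpec(
        title=title or "PheWAS volcano plot",
        x_label="effect size (beta)",
        x_range=x_range,
        y_label="-log10(P)",
        y_range=y_range,
        points=points,
        hulls=hulls,
        legend=legend,
        halo_key=halo_key,
        threshold_line=-math.log10(active_p),
        labels=list(labels),
    )
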