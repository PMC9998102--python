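"""Numeric encodings and filters that map association records to plot space.

The volcano plot places each trait at (beta, -log10 P) and encodes case
count as the diameter of a halo around the dot.  Everything here is pure
and in-memory; rendering lives in :mod:`phewas_volcano.render`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .records import AssociationRecord

__all__ = [
    "PlotPoint",
    "SignificanceFilter",
    "GENOME_WIDE_P",
    "neglog10",
    "or_to_beta",
    "halo_diameter",
    "filter_significant",
    "select_region",
    "max_effect_significant",
]

#: Conventional genome-wide significance threshold, P < 5e-8.
GENOME_WIDE_P = 5e-8


@dataclass(frozen=True)
class PlotPoint:
    """A fully encoded volcano-plot mark.

    x is the effect size (beta), y is -log10(P), ``halo_diameter`` is in
    display units (px), ``color`` encodes the trait category and
    ``fine_mapped`` asks the renderer for a dark ring around the dot.
    """

    x: float
    y: float
    halo_diameter: float
    color: str
    fine_mapped: bool
    label: str
    source: AssociationRecord


@dataclass(frozen=True)
class SignificanceFilter:
    """Significance cut on the P-value scale (strict: keep P < p_threshold)."""

    p_threshold: float = GENOME_WIDE_P

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError(
                f"p_threshold must be in (0, 1), got {self.p_threshold}"
            )

    @property
    def mlogp_threshold(self) -> float:
        """The equivalent y-axis cut, -log10(p_threshold) (~7.3 by default)."""
        return -math.log10(self.p_threshold)


def neglog10(p: float) -> float:
    """-log10 of a P-value; the volcano plot's y-coordinate.

    Strictly decreasing in p; only defined on (0, 1].
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"P out of range (0, 1]: {p}")
    return -math.log10(p)


def or_to_beta(odds_ratio: float) -> float:
    """Natural log of an odds ratio: the log-odds effect size (beta)."""
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    return math.log(odds_ratio)


def halo_diameter(
    n_cases: float,
    n_min: float,
    n_max: float,
    d_min: float,
    d_max: float,
) -> float:
    """Map a case count to a halo diameter in display units.

    Square-root normalization, so halo *area* is proportional to the case
    count within the displayed range::

        d = d_min + (d_max - d_min) * sqrt((n - n_min) / (n_max - n_min))

    Monotone non-decreasing in ``n_cases``; when the displayed counts are
    all equal (n_min == n_max) every halo gets the midpoint diameter.
    """
    if d_min >= d_max:
        raise ValueError(f"need d_min < d_max, got [{d_min}, {d_max}]")
    if n_min == n_max:
        if n_cases != n_min:
            raise ValueError(
                f"n_cases {n_cases} outside degenerate range [{n_min}, {n_max}]"
            )
        return 0.5 * (d_min + d_max)
    if not (n_min <= n_cases <= n_max):
        raise ValueError(f"n_cases {n_cases} outside [{n_min}, {n_max}]")
    frac = (n_cases - n_min) / (n_max - n_min)
    return d_min + (d_max - d_min) * math.sqrt(frac)


def linear_halo_diameter(
    n_cases: float,
    n_min: float,
    n_max: float,
    d_min: float,
    d_max: float,
) -> float:
    """Linear-diameter alternative to :func:`halo_diameter` (config switch)."""
    if d_min >= d_max:
        raise ValueError(f"need d_min < d_max, got [{d_min}, {d_max}]")
    if n_min == n_max:
        if n_cases != n_min:
            raise ValueError(
                f"n_cases {n_cases} outside degenerate range [{n_min}, {n_max}]"
            )
        return 0.5 * (d_min + d_max)
    if not (n_min <= n_cases <= n_max):
        raise ValueError(f"n_cases {n_cases} outside [{n_min}, {n_max}]")
    return d_min + (d_max - d_min) * (n_cases - n_min) / (n_max - n_min)


def filter_significant(
    records: Sequence[AssociationRecord],
    f: SignificanceFilter = SignificanceFilter(),
) -> list[AssociationRecord]:
    """Keep exactly the genome-wide significant records (P < threshold).

    Comparison runs on the -log10 scale (mlogp > -log10 threshold), which is
    equivalent for representable P but also correct for records whose P-value
    underflowed and only carry mlogp.  Idempotent; input order preserved.
    """
    cut = f.mlogp_threshold
    return [rec for rec in records if rec.resolved_mlogp() > cut]


def select_region(
    records: Sequence[AssociationRecord],
    x_range: tuple[float, float],
    y_range: tuple[float, float],
) -> list[AssociationRecord]:
    """Sweep-select: records whose (beta, -log10 P) lies in a closed rectangle.

    This is the programmatic form of dragging a selection box on the plot;
    the result feeds :func:`phewas_volcano.io_tsv.write_selection_table`.
    """
    x_lo, x_hi = x_range
    y_lo, y_hi = y_range
    if x_lo > x_hi:
        raise ValueError(f"inverted x interval [{x_lo}, {x_hi}]")
    if y_lo > y_hi:
        raise ValueError(f"inverted y interval [{y_lo}, {y_hi}]")
    return [
        rec
        for rec in records
        if x_lo <= rec.beta <= x_hi and y_lo <= rec.resolved_mlogp() <= y_hi
    ]


def max_effect_significant(
    records: Sequence[AssociationRecord],
    f: SignificanceFilter = SignificanceFilter(),
) -> Optional[AssociationRecord]:
    """The significant association with the largest absolute effect size.

    As cohorts grow, the biologically most informative trait at a variant is
    often not the one with the smallest P but the one with the largest
    effect among the significant ones; this picks it out.  Ties on |beta|
    break toward larger mlogp, then lexicographically smaller trait_id.
    Returns None when nothing is significant.
    """
    survivors = filter_significant(records, f)
    if not survivors:
        return None
    return max(
        survivors,
        key=lambda r: (abs(r.beta), r.resolved_mlogp(), _neg_str(r.trait_id)),
    )


class _neg_str:
    """Ordering adapter: larger under max() == lexicographically smaller."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_neg_str") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_str) and self.s == other.s
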