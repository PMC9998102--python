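"""Domain types and validation for per-variant, per-trait association records.

A PheWAS ("phenome-wide association scan") summarizes, for one genetic
variant, the association statistics against every trait in a biobank: the
effect size (beta; for dichotomous traits the natural log of the odds
ratio), the P-value, case/control counts, a trait-category label and,
optionally, a fine-mapping posterior inclusion probability (PIP).  These
types are the in-memory row model for such tables; TSV serialization lives
in :mod:`phewas_volcano.io_tsv`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "VariantContext",
    "AssociationRecord",
    "CategoryPalette",
    "Finding",
    "validate_records",
    "assign_colors",
    "mark_finemapped",
    "MLOGP_CONSISTENCY_TOL",
    "QUALITATIVE_PALETTE",
]

#: Tolerance, on the -log10 scale, for agreement between a stored pval and a
#: stored mlogp.  Absorbs rounding in exported TSVs.
MLOGP_CONSISTENCY_TOL = 0.01

#: Fixed 12-color qualitative cycle (ColorBrewer "Paired").  Categories are
#: sorted lexicographically and assigned in order, wrapping when exhausted,
#: so the same category set always yields the same figure colors.
QUALITATIVE_PALETTE: tuple[str, ...] = (
    "#a6cee3", "#1f78b4", "#b2df8a", "#33a02c",
    "#fb9a99", "#e31a1c", "#fdbf6f", "#ff7f00",
    "#cab2d6", "#6a3d9a", "#ffff99", "#b15928",
)


@dataclass(frozen=True)
class VariantContext:
    """The focal variant of a PheWAS table (chrom-pos-ref-alt, GRCh38-style)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def label(self) -> str:
        """Hyphenated identifier, e.g. ``2-27508073-T-C``."""
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"


@dataclass
class AssociationRecord:
    """One trait's association statistics at the focal variant.

    ``beta`` is the regression coefficient: log-odds for dichotomous
    (case/control) traits, standardized units for continuous traits.  At
    least one of ``pval`` / ``mlogp`` must be present; when both are, they
    must agree to :data:`MLOGP_CONSISTENCY_TOL` on the -log10 scale.
    """

    trait_id: str
    trait_name: str
    category: str
    beta: float
    se: Optional[float] = None
    pval: Optional[float] = None
    mlogp: Optional[float] = None
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    pip: Optional[float] = None
    is_binary: bool = True
    fine_mapped: bool = False

    def resolved_mlogp(self) -> float:
        """-log10(P), preferring a stored mlogp over recomputation from pval.

        Stored mlogp survives P-value underflow (P < 1e-308), which is why it
        takes precedence.
        """
        if self.mlogp is not None:
            return self.mlogp
        if self.pval is None:
            raise ValueError(f"record {self.trait_id!r} has neither pval nor mlogp")
        return -math.log10(self.pval)

    def resolved_pval(self) -> float:
        """P-value, recomputed as 10**(-mlogp) when only mlogp is stored.

        May underflow to 0.0 for extreme mlogp; callers that filter should
        compare on the -log10 scale instead (see transforms.filter_significant).
        """
        if self.pval is not None:
            return self.pval
        return 10.0 ** (-self.resolved_mlogp())


@dataclass(frozen=True)
class Finding:
    """One validation finding: which record, which field, what is wrong."""

    index: int
    trait_id: str
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.index}:{self.trait_id}] {self.field}: {self.message}"


@dataclass(frozen=True)
class CategoryPalette:
    """Deterministic ordered mapping from trait-category label to hex color."""

    colors: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __getitem__(self, category: str) -> str:
        for label, color in self.colors:
            if label == category:
                return color
        raise KeyError(category)

    def __contains__(self, category: str) -> bool:
        return any(label == category for label, _ in self.colors)

    def __len__(self) -> int:
        return len(self.colors)

    def items(self) -> tuple[tuple[str, str], ...]:
        return self.colors

    def as_dict(self) -> dict[str, str]:
        return dict(self.colors)


def validate_records(
    records: Sequence[AssociationRecord],
    n_total: Optional[int] = None,
) -> list[Finding]:
    """Check every record against the domain invariants.

    Returns one :class:`Finding` per violated invariant (findings, not
    exceptions; an empty list means all records are valid).  ``n_total``,
    when given, is the cohort size that ``n_cases + n_controls`` may not
    exceed.
    """
    findings: list[Finding] = []

    def add(i: int, rec: AssociationRecord, field_name: str, msg: str) -> None:
        findings.append(Finding(i, rec.trait_id, field_name, msg))

    for i, rec in enumerate(records):
        if rec.pval is None and rec.mlogp is None:
            add(i, rec, "pval", "neither pval nor mlogp present")
        if rec.pval is not None:
            if rec.pval == 0:
                if rec.mlogp is None:
                    add(i, rec, "pval", "pval underflow, no mlogp")
                # pval == 0 with mlogp present: mlogp is authoritative
            elif not (0.0 < rec.pval <= 1.0):
                add(i, rec, "pval", f"pval {rec.pval} outside (0, 1]")
        if rec.mlogp is not None and rec.mlogp < 0:
            add(i, rec, "mlogp", f"mlogp {rec.mlogp} < 0")
        if (
            rec.pval is not None
            and rec.mlogp is not None
            and 0.0 < rec.pval <= 1.0
            and rec.mlogp >= 0
        ):
            expected = -math.log10(rec.pval)
            if abs(rec.mlogp - expected) > MLOGP_CONSISTENCY_TOL:
                add(
                    i, rec, "mlogp",
                    f"pval/mlogp inconsistent: -log10({rec.pval}) = "
                    f"{expected:.4f} but mlogp = {rec.mlogp}",
                )
        if rec.se is not None and rec.se < 0:
            add(i, rec, "se", f"se {rec.se} < 0")
        if rec.pip is not None and not (0.0 <= rec.pip <= 1.0):
            add(i, rec, "pip", f"pip {rec.pip} outside [0, 1]")
        if rec.n_cases is not None and rec.n_cases < 0:
            add(i, rec, "n_cases", f"n_cases {rec.n_cases} < 0")
        if rec.n_controls is not None and rec.n_controls < 0:
            add(i, rec, "n_controls", f"n_controls {rec.n_controls} < 0")
        if (
            n_total is not None
            and rec.n_cases is not None
            and rec.n_controls is not None
            and rec.n_cases + rec.n_controls > n_total
        ):
            add(
                i, rec, "n_cases",
                f"n_cases + n_controls = {rec.n_cases + rec.n_controls} "
                f"exceeds cohort size {n_total}",
            )
        if not math.isfinite(rec.beta):
            add(i, rec, "beta", "beta is not finite")
    return findings


def assign_colors(categories: Iterable[str]) -> CategoryPalette:
    """Assign a deterministic color to every category label.

    Categories are sorted lexicographically and assigned from the fixed
    12-color qualitative cycle; the mapping is a pure function of the
    category *set*, so any input order (or duplication) yields the same
    palette and figures remain reproducible without a stored legend.
    """
    unique = sorted(set(categories))
    if not unique:
        raise ValueError("no categories")
    n = len(QUALITATIVE_PALETTE)
    return CategoryPalette(
        tuple((cat, QUALITATIVE_PALETTE[i % n]) for i, cat in enumerate(unique))
    )


def mark_finemapped(
    records: Sequence[AssociationRecord],
    pip_threshold: float = 0.5,
) -> list[AssociationRecord]:
    """Flag records whose fine-mapping posterior reaches ``pip_threshold``.

    A trait counts as fine-mapped to the focal variant when its PIP is
    present and >= the threshold (inclusive, so behavior is stable under
    threshold equality); records without a PIP are flagged False.  Returns
    new records; the inputs are not mutated.
    """
    if not (0.0 <= pip_threshold <= 1.0):
        raise ValueError(f"pip_threshold must be in [0, 1], got {pip_threshold}")
    return [
        replace(rec, fine_mapped=(rec.pip is not None and rec.pip >= pip_threshold))
        for rec in records
    ]
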