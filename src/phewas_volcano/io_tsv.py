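"""Read and write per-variant association tables (TSV with a header row).

The default column mapping follows the public FinnGen variant-export
convention (``phenocode``, ``phenostring``, ``category``, ``pval``,
``mlogp``, ``beta``, ``sebeta``, ``n_case``, ``n_control``, ``pip``), but
the mapping is data-driven config so the same reader serves tables exported
from other portals (e.g. OpenGWAS downloads renamed via a config file).

Dialect: hard TAB delimiter, decimal point, UTF-8, one header row.  The
variant context (chrom/pos/ref/alt) is not part of the per-trait columns;
it may travel in leading comment lines (``# variant=2-27508073-T-C``,
``# rsid=rs1260326``) or in the config, and may be absent.

Malformed data rows are skipped with a logged reason (real exports contain
NA rows); only structural problems — a missing required column, an empty
data section — abort.
"""

from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .records import AssociationRecord, VariantContext
from .transforms import or_to_beta

__all__ = [
    "ColumnMapping",
    "DEFAULT_MAPPING",
    "ReadResult",
    "read_associations",
    "write_selection_table",
    "load_config",
]

logger = logging.getLogger(__name__)

#: mlogp beyond which 10**(-mlogp) underflows double precision.
_MLOGP_REPRESENTABLE = 307.0


@dataclass(frozen=True)
class ColumnMapping:
    """Canonical field name -> source column header.

    ``trait_id`` and ``category`` must be mapped, as must at least one of
    {beta, or_value} and one of {pval, mlogp}; every other field is
    optional and may be None (unmapped).
    """

    trait_id: str = "phenocode"
    trait_name: Optional[str] = "phenostring"
    category: str = "category"
    beta: Optional[str] = "beta"
    or_value: Optional[str] = None
    pval: Optional[str] = "pval"
    mlogp: Optional[str] = "mlogp"
    se: Optional[str] = "sebeta"
    n_cases: Optional[str] = "n_case"
    n_controls: Optional[str] = "n_control"
    pip: Optional[str] = "pip"

    def __post_init__(self) -> None:
        if not self.trait_id or not self.category:
            raise ValueError("trait_id and category columns must be mapped")
        if self.beta is None and self.or_value is None:
            raise ValueError("at least one of beta / or_value must be mapped")
        if self.pval is None and self.mlogp is None:
            raise ValueError("at least one of pval / mlogp must be mapped")

    def mapped(self) -> dict[str, str]:
        """All (canonical field, header) pairs that are mapped."""
        return {
            f.name: getattr(self, f.name)
            for f in dc_fields(self)
            if getattr(self, f.name) is not None
        }


DEFAULT_MAPPING = ColumnMapping()


@dataclass
class ReadResult:
    """Outcome of :func:`read_associations`.

    ``rejected`` lists (1-based data-row number, reason) for every row that
    failed type coercion; ``len(result.rejected)`` is the reject count.
    """

    variant: Optional[VariantContext]
    records: list[AssociationRecord]
    rejected: list[tuple[int, str]]

    def __iter__(self):
        # allow: variant, records = read_associations(...)
        return iter((self.variant, self.records))


def _parse_variant_comments(lines: Sequence[str]) -> Optional[VariantContext]:
    variant_str = None
    rsid = None
    for raw in lines:
        body = raw.lstrip("#").strip()
        if "=" not in body:
            continue
        key, _, val = body.partition("=")
        key, val = key.strip().lower(), val.strip()
        if key == "variant":
            variant_str = val
        elif key == "rsid":
            rsid = val
    if variant_str is None:
        return None
    parts = variant_str.split("-")
    if len(parts) != 4:
        raise ValueError(f"malformed variant comment {variant_str!r}; "
                         "expected CHROM-POS-REF-ALT")
    chrom, pos, ref, alt = parts
    return VariantContext(chrom=chrom, pos=int(pos), ref=ref, alt=alt, rsid=rsid)


def _coerce_float(value: object) -> Optional[float]:
    """Parse a cell to float; NA-ish cells (None, '', 'NA', 'nan') -> None."""
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.upper() in {"NA", "NAN", "NONE", "NULL", "."}:
        return None
    x = float(s)  # ValueError propagates to the caller's reject handler
    if math.isnan(x):
        return None
    return x


def _coerce_int(value: object) -> Optional[int]:
    x = _coerce_float(value)
    if x is None:
        return None
    if x != int(x):
        raise ValueError(f"expected integer count, got {x}")
    return int(x)


def read_associations(
    path: Union[str, Path],
    mapping: ColumnMapping = DEFAULT_MAPPING,
    variant: Optional[VariantContext] = None,
) -> ReadResult:
    """Parse a per-variant association TSV into records.

    One :class:`AssociationRecord` per well-formed data row; rows failing
    type coercion are skipped, each with a logged reason, and reported in
    ``result.rejected``.  When an odds-ratio column is mapped and beta is
    not (or beta is NA in a row), beta is derived as ln(OR).  When a row
    carries only mlogp, pval is recovered as 10**(-mlogp) where that is
    representable, else left absent.

    ``variant`` (e.g. from a config file) takes precedence over any
    ``# variant=`` comment line in the file.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    n_comments = 0
    for line in lines:
        if line.startswith("#"):
            n_comments += 1
        else:
            break
    file_variant = _parse_variant_comments(lines[:n_comments])
    body = "\n".join(lines[n_comments:])
    if not body.strip():
        raise ValueError("no associations: file has no header/data section")

    df = pd.read_csv(io.StringIO(body), sep="\t", dtype=str, keep_default_na=False)

    required = [mapping.trait_id, mapping.category]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing mapped column {col!r}")
    if not any(c in df.columns for c in (mapping.beta, mapping.or_value) if c):
        raise ValueError(
            f"missing mapped column {mapping.beta or mapping.or_value!r}"
        )
    if not any(c in df.columns for c in (mapping.pval, mapping.mlogp) if c):
        raise ValueError(f"missing mapped column {mapping.pval or mapping.mlogp!r}")
    if len(df) == 0:
        raise ValueError("no associations: empty data section")

    def cell(row: pd.Series, header: Optional[str]) -> Optional[str]:
        if header is None or header not in df.columns:
            return None
        return row[header]

    records: list[AssociationRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        trait_id = str(cell(row, mapping.trait_id) or "").strip()
        try:
            if not trait_id:
                raise ValueError("empty trait_id")
            category = str(cell(row, mapping.category) or "").strip()
            if not category:
                raise ValueError("empty category")
            name_cell = cell(row, mapping.trait_name)
            trait_name = str(name_cell).strip() if name_cell else trait_id

            beta = _coerce_float(cell(row, mapping.beta))
            if beta is None and mapping.or_value is not None:
                or_val = _coerce_float(cell(row, mapping.or_value))
                if or_val is not None:
                    beta = or_to_beta(or_val)
            if beta is None:
                raise ValueError("no effect size (beta/OR missing or NA)")

            pval = _coerce_float(cell(row, mapping.pval))
            mlogp = _coerce_float(cell(row, mapping.mlogp))
            if mlogp is not None and mlogp < 0:
                raise ValueError(f"mlogp {mlogp} < 0")
            if pval is not None and (pval < 0 or pval > 1):
                raise ValueError(f"pval {pval} outside [0, 1]")
            if pval == 0.0:
                # cannot place P = 0 on the -log10 axis; trust mlogp if present
                if mlogp is None:
                    raise ValueError("pval underflow, no mlogp")
                pval = None
            if pval is None and mlogp is not None:
                pval = 10.0 ** (-mlogp) if mlogp <= _MLOGP_REPRESENTABLE else None
            if pval is None and mlogp is None:
                raise ValueError("no P information (pval and mlogp missing or NA)")

            se = _coerce_float(cell(row, mapping.se))
            if se is not None and se < 0:
                raise ValueError(f"se {se} < 0")
            n_cases = _coerce_int(cell(row, mapping.n_cases))
            if n_cases is not None and n_cases < 0:
                raise ValueError(f"n_cases {n_cases} < 0")
            n_controls = _coerce_int(cell(row, mapping.n_controls))
            if n_controls is not None and n_controls < 0:
                raise ValueError(f"n_controls {n_controls} < 0")
            pip = _coerce_float(cell(row, mapping.pip))
            if pip is not None and not (0.0 <= pip <= 1.0):
                raise ValueError(f"pip {pip} outside [0, 1]")
        except ValueError as exc:
            logger.warning("rejecting row %d (%s): %s", i, trait_id or "?", exc)
            rejected.append((i, str(exc)))
            continue

        records.append(
            AssociationRecord(
                trait_id=trait_id,
                trait_name=trait_name,
                category=category,
                beta=beta,
                se=se,
                pval=pval,
                mlogp=mlogp,
                n_cases=n_cases,
                n_controls=n_controls,
                pip=pip,
                is_binary=n_cases is not None,
            )
        )
    if rejected:
        logger.info("rejected %d of %d rows", len(rejected), len(df))
    return ReadResult(variant or file_variant, records, rejected)


def _fmt(value: object) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return repr(value)  # shortest string that round-trips the double
    return str(value)


def write_selection_table(
    records: Sequence[AssociationRecord],
    path: Union[str, Path],
    mapping: ColumnMapping = DEFAULT_MAPPING,
    variant: Optional[VariantContext] = None,
) -> Path:
    """Write records as a TSV in the given dialect (default: FinnGen headers).

    Floats are written with ``repr`` so write-then-read reproduces every
    mapped field bit-exactly; missing optional fields become ``NA``.  An
    empty record list yields a header-only file.  This is the sweep-select
    companion: pass it the output of
    :func:`phewas_volcano.transforms.select_region`.
    """
    path = Path(path)
    mapped = mapping.mapped()
    # or_value is an input-only alias for beta; never written
    mapped.pop("or_value", None)
    canon_fields = list(mapped)
    lines = []
    if variant is not None:
        lines.append(f"# variant={variant.label}")
        if variant.rsid:
            lines.append(f"# rsid={variant.rsid}")
    lines.append("\t".join(mapped[f] for f in canon_fields))
    for rec in records:
        lines.append("\t".join(_fmt(getattr(rec, f)) for f in canon_fields))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def load_config(path: Union[str, Path]) -> tuple[ColumnMapping, Optional[VariantContext], dict]:
    """Load a JSON or YAML config carrying a column mapping and defaults.

    Recognized keys: ``columns`` (canonical field -> header; unspecified
    fields fall back to the FinnGen defaults, ``null`` unmaps a field),
    ``variant`` ({chrom, pos, ref, alt, rsid}), and anything else is
    returned verbatim as the options dict (e.g. pip_threshold, d_min).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping at top level")
    columns = data.get("columns", {})
    if not isinstance(columns, dict):
        raise ValueError("config key 'columns' must be a mapping")
    known = {f.name for f in dc_fields(ColumnMapping)}
    unknown = set(columns) - known
    if unknown:
        raise ValueError(f"unknown canonical column fields: {sorted(unknown)}")
    defaults = {f.name: getattr(DEFAULT_MAPPING, f.name) for f in dc_fields(ColumnMapping)}
    defaults.update(columns)
    mapping = ColumnMapping(**defaults)
    variant = None
    if "variant" in data:
        v = dict(data["variant"])
        variant = VariantContext(
            chrom=str(v["chrom"]), pos=int(v["pos"]),
            ref=str(v["ref"]), alt=str(v["alt"]), rsid=v.get("rsid"),
        )
    options = {k: v for k, v in data.items() if k not in {"columns", "variant"}}
    return mapping, variant, options
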