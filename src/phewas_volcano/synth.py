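"""Synthetic per-variant PheWAS tables, plus the published worked example.

The generator emulates the structure of a biobank variant-page export —
thousands of dichotomous traits grouped into disease categories, case
counts varying over orders of magnitude, a small fraction of truly
associated traits — using a Wald-approximation generative model: for each
trait the observed log-odds beta-hat is Normal(true beta, se) with
se = sqrt(1/n_cases + 1/n_controls), and the P-value is the two-sided Wald
test of beta-hat/se.  Under this model significance and effect size are
coupled at fixed case count but decouple when case counts vary, which is
exactly the phenomenon the volcano plot is designed to expose.

No genotypes, LD structure or logistic-regression fitting are simulated;
the generator emits summary statistics directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .records import AssociationRecord, VariantContext

__all__ = [
    "SimParams",
    "DEFAULT_CATEGORIES",
    "simulate_phewas",
    "rs1260326_fixture",
    "rs1260326_variant",
]

#: ICD-chapter-style disease categories with sampling weights, loosely
#: mirroring the composition of a nationwide biobank's endpoint collection.
DEFAULT_CATEGORIES: tuple[tuple[str, float], ...] = (
    ("Diseases of the circulatory system", 0.14),
    ("Endocrine, nutritional and metabolic diseases", 0.10),
    ("Diseases of the musculoskeletal system", 0.12),
    ("Diseases of the digestive system", 0.11),
    ("Mental and behavioural disorders", 0.09),
    ("Diseases of the respiratory system", 0.09),
    ("Neoplasms", 0.10),
    ("Diseases of the nervous system", 0.08),
    ("Diseases of the genitourinary system", 0.08),
    ("Diseases of the skin and subcutaneous tissue", 0.09),
)


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic PheWAS generator.

    Defaults mirror a FinnGen-release-7-sized cohort: 3095 dichotomous
    traits over 309 154 subjects, with case fractions spanning rare
    endpoints (~0.05% of the cohort) to very broad definitions (~40%).
    ``frac_nonnull`` traits carry a true log-odds effect drawn from
    Normal(0, beta_sd_nonnull); of those, a ``pip_frac`` share is given a
    high fine-mapping posterior (>= 0.9), the rest a low one (< 0.1).
    """

    n_traits: int = 3095
    categories: tuple[tuple[str, float], ...] = DEFAULT_CATEGORIES
    frac_nonnull: float = 0.02
    beta_sd_nonnull: float = 0.25
    n_total: int = 309_154
    case_frac_range: tuple[float, float] = (0.0005, 0.4)
    pip_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_traits < 1:
            raise ValueError(f"n_traits must be >= 1, got {self.n_traits}")
        if not (0.0 <= self.frac_nonnull <= 1.0):
            raise ValueError(f"frac_nonnull must be in [0, 1], got {self.frac_nonnull}")
        lo, hi = self.case_frac_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"case fractions must satisfy 0 < lo <= hi < 1, got ({lo}, {hi})")
        if not (0.0 <= self.pip_frac <= 1.0):
            raise ValueError(f"pip_frac must be in [0, 1], got {self.pip_frac}")
        if self.beta_sd_nonnull < 0:
            raise ValueError("beta_sd_nonnull must be >= 0")
        if not self.categories:
            raise ValueError("need at least one category")


_LN10 = math.log(10.0)


def simulate_phewas(p: SimParams) -> list[AssociationRecord]:
    """Draw one synthetic PheWAS table; fully reproducible from ``p.seed``.

    Per trait: n_cases is uniform over ``case_frac_range`` x n_total
    (n_controls the complement); the true beta is 0 with probability
    1 - frac_nonnull, else Normal(0, beta_sd_nonnull); the observed beta is
    Normal(true beta, se) with the Wald se; pval/mlogp come from the
    two-sided normal test of beta-hat/se (mlogp computed in log space so it
    survives P-value underflow).
    """
    rng = np.random.default_rng(p.seed)
    n = p.n_traits

    labels = [c for c, _ in p.categories]
    weights = np.array([w for _, w in p.categories], dtype=float)
    weights /= weights.sum()
    cats = rng.choice(len(labels), size=n, p=weights)

    lo, hi = p.case_frac_range
    case_frac = rng.uniform(lo, hi, size=n)
    n_cases = np.maximum(1, np.rint(case_frac * p.n_total).astype(int))
    n_controls = p.n_total - n_cases

    nonnull = rng.random(n) < p.frac_nonnull
    true_beta = np.where(nonnull, rng.normal(0.0, p.beta_sd_nonnull, size=n), 0.0)
    se = np.sqrt(1.0 / n_cases + 1.0 / n_controls)
    beta_obs = rng.normal(true_beta, se)

    z = np.abs(beta_obs / se)
    # mlogp = -log10(2 * Phi(-|z|)), via logsf to avoid underflow
    mlogp = -(math.log(2.0) + stats.norm.logsf(z)) / _LN10
    mlogp = np.maximum(mlogp, 0.0)
    pval = np.where(mlogp <= 307.0, np.power(10.0, -mlogp), np.nan)

    # fine-mapping posteriors: high for a pip_frac share of non-null traits
    pip = rng.uniform(0.0, 0.1, size=n)
    nonnull_idx = np.flatnonzero(nonnull)
    n_high = int(round(p.pip_frac * len(nonnull_idx)))
    high_idx = rng.choice(nonnull_idx, size=n_high, replace=False) if n_high else []
    pip[high_idx] = rng.uniform(0.9, 1.0, size=n_high)

    width = len(str(n))
    records = []
    for i in range(n):
        records.append(
            AssociationRecord(
                trait_id=f"SYN{i + 1:0{width}d}",
                trait_name=f"synthetic endpoint {i + 1}",
                category=labels[cats[i]],
                beta=float(beta_obs[i]),
                se=float(se[i]),
                pval=float(pval[i]) if np.isfinite(pval[i]) else None,
                mlogp=float(mlogp[i]),
                n_cases=int(n_cases[i]),
                n_controls=int(n_controls[i]),
                pip=float(pip[i]),
                is_binary=True,
            )
        )
    return records


def rs1260326_variant() -> VariantContext:
    """The GCKR missense variant rs1260326 (2-27508073-T-C)."""
    return VariantContext(chrom="2", pos=27_508_073, ref="T", alt="C", rsid="rs1260326")


def rs1260326_fixture() -> list[AssociationRecord]:
    """The two published rs1260326 associations used as a worked example.

    FinnGen release 7, at the GCKR missense variant: the broadest
    'Endocrine, nutritional and metabolic diseases' definition (over
    118 000 cases of 309 154 subjects, here encoded as exactly 118000)
    shows no genome-wide significant association (P = 0.074, beta = 0.01),
    while the much narrower 'mixed hyperlipidemia' endpoint (849 cases) has
    the largest significant effect at the variant: beta = -0.32,
    P = 8e-11.  Trait ids are synthetic placeholders (the published source
    prints names, not phenocodes).
    """
    n_total = 309_154
    category = "Endocrine, nutritional and metabolic diseases"
    broad = AssociationRecord(
        trait_id="ENDO_BROAD",
        trait_name="Endocrine, nutritional and metabolic diseases (broad)",
        category=category,
        beta=0.01,
        pval=0.074,
        n_cases=118_000,
        n_controls=n_total - 118_000,
        is_binary=True,
    )
    mixed_hyperlip = AssociationRecord(
        trait_id="E4_MIXED_HYPERLIP",
        trait_name="Mixed hyperlipidemia",
        category=category,
        beta=-0.32,
        pval=8e-11,
        n_cases=849,
        n_controls=n_total - 849,
        is_binary=True,
    )
    return [broad, mixed_hyperlip]
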