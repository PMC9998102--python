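# phewas-volcano

Volcano plots for phenome-wide association results at a single genetic
variant.

## The problem

A PheWAS ("phenome-wide association scan") asks, for one variant, how it
associates with every trait in a biobank — often thousands of case/control
disease endpoints.  Ranking those associations by P-value alone is
misleading: as cohorts grow, almost everything becomes statistically
significant, and for dichotomous traits the P-value is driven as much by
the case count as by the biology.  A broad endpoint with 100 000+ cases can
show a vanishing effect at a tiny P, while a narrow endpoint with a few
hundred cases carries the largest biological effect at the locus.

`phewas-volcano` renders all associations at a variant simultaneously as a
volcano plot encoding five things per trait:

* **x** — effect size β (for dichotomous traits, β = ln OR from logistic
  regression);
* **y** — −log₁₀ *P*;
* **halo diameter** — case count (square-root scaled, so halo *area* tracks
  the count);
* **halo color** — trait category (e.g. ICD-style disease chapters);
* **dark ring** — the trait's fine-mapping posterior inclusion probability
  (PIP) reaches a threshold, i.e. the signal is fine-mapped to this variant.

On top of the plot: the genome-wide significance line at
−log₁₀(5 × 10⁻⁸) ≈ 7.3, zoom to significant associations, sweep-selection
of an arbitrary (β, −log₁₀ P) rectangle into a TSV table, and per-category
convex hulls (smallest convex polygon around a category's points) that
shift attention from single phenotypes to groups of related ones.

Input is a per-variant TSV export (one row per trait) in the FinnGen
variant-page dialect by default; a small JSON/YAML config remaps columns
for tables from other portals.  Output is deterministic SVG, PNG, or a
self-contained interactive HTML file with hover tooltips.

## Worked example

The GCKR missense variant rs1260326 (2-27508073-T-C) in FinnGen release 7
illustrates why the maximum-effect view matters.  The broadest endocrine
endpoint (>118 000 cases) is not significant there at all, while the
largest significant effect belongs to an endpoint with only 849 cases:

```python
from phewas_volcano import (SignificanceFilter, filter_significant,
                            max_effect_significant, neglog10, rs1260326_fixture)

records = rs1260326_fixture()
print(f"{len(records)} associations at rs1260326 (2-27508073-T-C)")
sig = filter_significant(records, SignificanceFilter())
print(f"genome-wide significant (P < 5e-8): {len(sig)}")
best = max_effect_significant(records)
print(f"largest significant effect: {best.trait_name}")
print(f"  beta = {best.beta}   P = {best.pval:g}   "
      f"-log10(P) = {neglog10(best.pval):.1f}   cases = {best.n_cases}")
```

prints

```
2 associations at rs1260326 (2-27508073-T-C)
genome-wide significant (P < 5e-8): 1
largest significant effect: Mixed hyperlipidemia
  beta = -0.32   P = 8e-11   -log10(P) = 10.1   cases = 849
```

The broad endpoint (P = 0.074, β = 0.01) sits near the origin; mixed
hyperlipidemia sits far left of β = 0 and well above the 7.3 line — the
variant's diabetes risk allele *lowers* lipid-disorder risk.

From the shell, the same engine drives figure export end to end (here on a
synthetic table from the built-in generator):

```sh
$ phewas-volcano simulate --out sim.tsv --n-traits 300 --frac-nonnull 0.2 --seed 11
wrote sim.tsv: 300 synthetic records
$ phewas-volcano plot --input sim.tsv --out sim.svg --hulls --zoom-significant
wrote sim.svg: 52 points, 9 hulls
```

Other subcommands: `phewas-volcano table` (sweep-select a rectangle into a
TSV) and `phewas-volcano validate` (check a table against the record
invariants).

## Acceptance script

`scripts/acceptance.py` re-runs the rs1260326 worked example from scratch —
builds the two-record example table, applies the genome-wide filter,
selects the maximum-|β| survivor — and writes the resulting effect size as
JSON, alongside an end-to-end smoke run of the synthetic generator and
figure assembly:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
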