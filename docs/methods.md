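# Methods

## Data model

One table per variant, one row per trait.  A row must carry an effect size
(β directly, or an odds ratio converted as β = ln OR) and a significance
value (a P-value in (0, 1], a −log₁₀ P, or both).  When both P and
−log₁₀ P are stored they must agree within 0.01 on the −log₁₀ scale; this
tolerance absorbs the rounding in real portal exports.  Stored −log₁₀ P
takes precedence over recomputation from P everywhere, because it survives
double-precision underflow (P < ~1e-308), which genuinely occurs in
biobank-scale results.  A P-value of exactly 0 with no −log₁₀ P cannot be
placed on the y-axis and the row is rejected at read time.

Validation is advisory: `validate_records` returns findings (record, field,
message) rather than raising, so a table with a handful of bad rows can
still be inspected.  Structural problems — a missing required column, an
empty data section — abort the read; malformed individual rows are skipped
and counted.

## Visual encodings

* **y-axis**: −log₁₀ P.  Significance is defined on the P scale as
  P < 5 × 10⁻⁸ (strict), the conventional genome-wide threshold; the line
  is drawn at the exact value −log₁₀(5 × 10⁻⁸) ≈ 7.301 and labeled with
  the rounded "7.3".  There is deliberately no second, independent cutoff
  on the −log₁₀ scale.
* **halo diameter**: d = d_min + (d_max − d_min)·√((n − n_min)/(n_max − n_min)),
  with d_min = 6 px and d_max = 30 px by default.  The square root makes
  halo *area* proportional to case count within the displayed range, which
  is the perceptually honest encoding; a linear-diameter mode is available
  (`halo_scale="linear"`).  When the displayed counts are all equal the
  midpoint diameter is used, and traits without a case count (continuous
  traits) always get d_min so imported biomarker tables stay renderable.
  After a significance zoom, n_min/n_max are recomputed on the displayed
  subset (configurable by pre-filtering yourself if fixed scaling is
  wanted): the zoomed view re-spreads the size encoding over what is
  actually visible.
* **color**: categories are sorted lexicographically and assigned from a
  fixed 12-color qualitative cycle (ColorBrewer Paired), wrapping beyond
  12.  The palette is a pure function of the category set, so figures are
  reproducible without storing a legend.
* **fine-mapping ring**: a trait is flagged when its PIP is present and
  ≥ the threshold (default 0.5, inclusive so behavior is stable under
  exact equality).  No published numeric definition of "fine-mapped to the
  variant" exists for this display, so the threshold is an explicit
  parameter rather than a baked-in constant.

## Selection and ranking

The sweep-select rectangle is closed on all edges — a point lying exactly
on the drawn boundary is visibly inside it.  `max_effect_significant`
returns the significant record maximizing |β|; ties break toward larger
−log₁₀ P, then lexicographically smaller trait id, making the result
deterministic on any input.

## Convex hulls

Hulls are computed from scratch (Andrew's monotone chain) because the
canonical output contract matters here: vertices are emitted
counter-clockwise starting at the lexicographically smallest vertex, and
collinear boundary points are dropped so the polygon is strictly convex.
Fewer than three distinct non-collinear points (per category:
`min_points`, default 3) yield no hull — a zero-area segment would be an
invisible or misleading mark.  Hulls are computed on the currently
displayed subset, so after a significance zoom they enclose only the
significant points; hulls may span β = 0 and are never clipped there.
Optional padding moves each vertex away from the vertex centroid by a
fixed distance (default 0.05 data units, configurable to 0); since each
original vertex then lies on the segment from the centroid to its image,
and the centroid is a convex combination of the moved vertices, the padded
polygon provably contains the original.

## Rendering

`PlotSpec` is a renderer-independent figure description (JSON-serializable
for golden-file tests).  The SVG backend is byte-deterministic: points are
pre-sorted by trait id, numbers are formatted with fixed precision, and
nothing time- or environment-dependent is written.  Each point is a
`<g class="point">` with a halo circle, central dot, optional fine-mapping
ring, and a `<title>` tooltip (trait name, β, P, case count); hulls are
literal `<polygon>` elements — so mark counts are assertable by parsing.
The x-axis is symmetric about 0 when every displayed trait is dichotomous
(risk and protective effects read symmetrically) and data-driven otherwise;
the y-range is [0, 1.05·max].  The interactive export embeds the same SVG
in a single HTML file and relies on native browser tooltips — interaction
(zoom, select) is delivered through the programmatic API, not a bundled
JavaScript application.  Pinned labels are drawn at a fixed offset with no
collision avoidance.

## Synthetic generator

The generator emits summary statistics directly under a Wald approximation:
per trait, n_cases ~ Uniform(case_frac_range) × n_total (default cohort
309 154, 3095 traits, matching a FinnGen-release-7-sized biobank); the true
log-odds effect is 0 with probability 1 − frac_nonnull (default 0.02) and
Normal(0, 0.25) otherwise; se = √(1/n_cases + 1/n_controls); the observed
β ~ Normal(true β, se); P is the two-sided normal tail of β̂/se, with
−log₁₀ P computed in log space so it survives underflow.  A `pip_frac`
share of non-null traits receives a high PIP (≥ 0.9), the rest low
(< 0.1).  All randomness flows from one `numpy` Generator seeded
explicitly.

This stated world reproduces the two phenomena the plot is designed
around — effect/significance coupling at fixed case count, and their
decoupling when case counts vary — and is exactly uniform in P under the
null, which the calibration tests assert (KS band 1.63/√n at n = 10 000).
It does **not** emulate linkage disequilibrium, genotype sampling,
correlated traits, or logistic-regression small-sample artifacts; a green
test establishes the pipeline's encodings and statistics on idealized Wald
summaries, not robustness to those real-data features.  Default effect and
case-count distributions are chosen for visual plausibility, not
calibrated to any particular biobank release.

## Numerical notes

* β from OR: exact `math.log`; P ↔ −log₁₀ P conversions are mutual
  inverses to 1e-10 relative tolerance over (1e-300, 1].
* TSV round trips are bit-exact: floats are written with `repr` (shortest
  round-tripping form), the delimiter is a hard TAB, decimal point only,
  UTF-8.
* Hull geometry uses double-precision cross products with strict
  inequalities; inputs with non-finite coordinates are rejected at
  construction.
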