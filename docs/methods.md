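# Methods

This note records the model, the numerical conventions and the design
choices behind `ivffmcdm`, in the spirit of a statistical package's
methods documentation.  Nothing here states a number that the test
suite or `scripts/acceptance.py` does not itself compute.

## Interval-valued orthopair numbers

An `IVOFN` carries membership and non-membership intervals inside
`[0, 1]` under the rung constraint `μ_U^q + ν_U^q ≤ 1`.  The rung
exponent is carried on every number; `q = 3` (Fermatean) is the package
default, `q = 1` (intuitionistic) and `q = 2` (Pythagorean) exist for
the comparison layer.  Mixing rungs in one operation is an error, never
a silent coercion.  Degenerate intervals (`low = high`) are legal and
represent point-valued fuzzy numbers, which is how single-valued scales
can be loaded.

Derived quantities:

- hesitation interval: `π_L = (1 − μ_U^q − ν_U^q)^{1/q}`,
  `π_U = (1 − μ_L^q − ν_L^q)^{1/q}`, so that `μ^q + ν^q + π^q = 1`
  holds at matched (upper/lower) bounds;
- score function `SF(f) = ½(μ_L^q + μ_U^q − ν_L^q − ν_U^q) ∈ [−1, 1]`,
  the package's only defuzzifier.

Arithmetic uses the algebraic product/probabilistic-sum t-norm pair.
All invariant checks use an absolute tolerance of `1e−9`; q-th roots are
taken on arguments clamped to `[0, 1]`, so closure holds exactly even
when floating-point cancellation drives an intermediate a few ulps
outside the unit interval.

**Aggregation.**  The group-aggregation operator (`ivffwa`) defaults to
the *endpoint-linear* form: each of the four interval endpoints is the
weighted arithmetic mean of the corresponding input endpoints.  This is
the form the emulated study prints and is therefore the default; the
canonical power-mean form
(`μ = (1 − Π(1 − μ_i^q)^{w_i})^{1/q}`, `ν = Π ν_i^{w_i}`) is available
via `form="canonical"` for sensitivity checking.  Both are idempotent
and selective; only the linear form is endpoint-convex.

## Linguistic scales

Scales are data files, not code constants.  Two roles exist: *rating*
scales (VL < L < ML < M < MH < H < VH, strictly increasing score) and
*comparison* scales (terms grouped into more/equal/less importance, with
group-ordered scores).

The study this package emulates defines its scales in unpublished
supplementary material.  The packaged defaults are therefore **stand-in
scales**, built as symmetric ladders with 0.10–0.15-wide intervals
stepping by 0.10–0.15 per term, feasible under the cubic constraint and
labelled synthetic in the data files themselves:

- `rating_ivff_standin.json` — 7 terms, mirror-symmetric about
  M = ([0.45, 0.55], [0.45, 0.55]);
- `comparison_ivff_standin.json` — 9 terms around the 'equal' pivot,
  four 'more' grades above, four 'less' grades below.

Every quantity that depends on a scale is conditional on these files;
the two checks in the acceptance suite that compare criterion weights
and MAIRCA gaps against the published values are run with the stand-ins
and are *expected to deviate* until the original scale definitions are
pasted into files of the same format.  Quantities that do not touch a
scale (the entropy stage, the rank-agreement statistics) are
unconditional.

**Perturbation operator.**  The robustness analysis rescales every
interval about its midpoint by a width multiplier `k` (`[m − kh, m + kh]`
for midpoint `m`, half-width `h`), clips to `[0, 1]` and, if widening
breaks rung feasibility, shrinks `ν_U` (then `ν_L`) to the feasibility
boundary while leaving membership untouched — a deterministic, minimal
repair.  `k = 1` returns the identical scale object; midpoints are
preserved exactly whenever no clipping occurs.  The same repair is used
when a Fermatean scale is reinterpreted at a tighter rung (`with_q`),
which is how the q = 1 and q = 2 comparison runs construct their scales;
because that convention is ours, the cross-rung weight and gap *values*
are reported but only structural properties of them are asserted.

## PIPRECIA weighting

Per non-reference criterion the panel's terms are aggregated with
equal decision-maker weights (the study does not state panel weights;
they are configurable) and defuzzified to `s_j`.  The pivot is
`k_j = 2 − s_j` with the **raw** score `s_j ∈ [−1, 1]`, giving
`k_j ∈ [1, 3]`: weights always decay away from the pass's reference
criterion.  This matches the printed recursion and reproduces the
published structure in which the forward reference (C1) and the inverse
reference (C12) dominate the averaged weights.  The classical variant,
in which scores live in `[0, 2]` and an 'equal' judgment leaves the
running weight unchanged, is available as `score_mode="shift"`; in that
mode (and only in that mode) an all-'equal' panel yields exactly uniform
weights for any criterion order, which the property suite exercises.
The pivot can only become non-positive if a rescaled score reached 2;
this is impossible for a score function bounded by 1 and is guarded by
a loud failure rather than silently clamped.

The inverse pass takes its criteria in the inverse panel's printed
order (last criterion first); final weights are the per-criterion mean
of the two normalized pass vectors, re-indexed to canonical order.

## MAIRCA ranking

Interval arithmetic offers no subtraction or division, so the aggregated
rating matrix is defuzzified with `SF` *before* min-max normalization;
because the theoretical-matrix entries are scalars, defuzzifying before
or after the product `t_P · r` is equivalent, and the crisp route is the
executable one.  Scores may be negative; the normalization is affine, so
this is harmless.  A constant column is mapped to `r = 1` (no
discrimination ⇒ no gap for anyone; any constant leaves the ranking
unchanged).  Ties in the total gap are broken by alternative declaration
order and flagged in the result.

**Criterion directions.**  Directions are configurable per criterion.
The packaged case-study pipeline defaults to *cost* orientation: the
panel's linguistic ratings express the risk level each method registers,
so a lower aggregated rating means a more favorable (lower-burden)
profile.  This is the orientation consistent with the published gap
table, in which the method rated highest nearly everywhere lands
mid-ranking and the lowest-rated method ranks first; a benefit-oriented
reading would invert that.  For adequacy-style ratings, pass
`directions="benefit"`.

## Entropy prioritization

The score matrix keeps each method's native scale (REBA 1–15-ish
integers next to QEC percentages); column normalization over the m
methods cancels scale differences, which is why no prior rescaling is
performed.  The normalization runs over *methods within an operation
column*, the entropy is taken per column, and the constant is
`k = 1/ln(m)` from the method count — the only reading consistent with
the published `k = 1/ln 6` for six methods, given that the printed
index conventions are internally inconsistent.  The per-method weights
of the weighted variant default to the **raw MAIRCA total gaps**
replicated across columns; this reproduces the published per-operation
entropies for every operation except the first one, whose published
value instead equals the *unweighted* entropy of its column.  The test
suite asserts the weighted rule on all other operations (within ±0.002,
covering the 3-decimal rounding of the published gap inputs) and
documents the first-row discrepancy; quantities downstream of that row
(the published final weight column and full ranking string) are treated
as informational only.  Alternative weightings (normalized gaps,
inverse gaps, complement, none) are selectable.  `0·ln 0` is defined as
0; it cannot occur for strictly positive inputs.

Higher entropy weight = higher ergonomic priority.

## Rank agreement

Spearman's ρ uses the closed form `1 − 6Σd²/(n(n²−1))` for untied
ranks and the average-rank (Pearson-on-ranks) formula otherwise; the
suite cross-checks both branches against scipy on random rank pairs.
Reversal counting is strict discordance over unordered pairs (ties in
either vector count as concordant), cross-checked against the
discordant-pair count implied by Kendall's τ.

## Synthetic generator

The generator emulates the study's input *structure*: 12 criteria,
6 alternatives, 3 decision makers, 23 operations by default, with a
concordance parameter governing panel agreement — each judged item has
a latent term drawn uniformly from the scale and each decision maker
copies it with probability `c` or draws an independent uniform term
otherwise (so `c = 1` collapses the panel to one voice and `c = 0`
makes decision makers independent; the default `c = 0.7` reflects the
substantial but imperfect agreement typical of small expert panels).
Score matrices draw integer-like values on [2, 13] with one designated
row on a 60–80 range to mimic the heterogeneous-scale method.  All
randomness flows from a mandatory seed.

What the generator does *not* emulate: correlated criteria, systematic
per-expert bias, ordinal near-miss disagreement (non-concordant draws
are uniform, not adjacent), or any dependence between panel ratings and
the score matrix.  Property tests built on it therefore demonstrate
algebraic and pipeline invariants — closure, weight normalization, gap
identities, reproducibility — not calibration against real expert
behavior.

## Problem sizes and runtime

All packaged computations run on the study-sized inputs (12 criteria,
6 methods, 3 experts, 23 operations); property tests use panels between
2×2 and 10×40 and 60 hypothesis examples per property (derandomized).
The full suite completes in a few seconds on one CPU; the acceptance
script in under a minute.

## Known limitations

- The stand-in scales make all scale-conditional numbers reproducible
  only in structure, not in value, against the emulated study.
- The endpoint-linear aggregation is not closed under the canonical
  IVFF algebra's limit operations; it is used because it is what the
  emulated pipeline computes.
- Rating-panel fixtures were transcribed from run-together extracted
  text; five rows admit more than one 12-token reading and were frozen
  by a deterministic longest-match tokenizer (verbatim strings are kept
  alongside the fixtures for re-inspection).
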