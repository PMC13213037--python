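# ivffmcdm

Uncertainty-aware multi-criteria decision analysis for ergonomic risk
assessment, built on **interval-valued Fermatean fuzzy (IVFF) numbers**.

## The problem

Work-related musculoskeletal disorders are screened with observational
instruments such as REBA, RULA, QEC, OWAS, OCRA and the Strain Index.
Choosing *which* instrument suits a given production environment — and
*which* operations deserve intervention first — is itself a
multi-criteria decision taken by a small expert panel whose judgments
carry hesitation and linguistic ambiguity.  `ivffmcdm` implements a
three-stage decision pipeline that keeps that uncertainty explicit:

1. **PIPRECIA criterion weighting.**  Each expert compares every risk
   criterion with its predecessor in a forward pass (and successor in an
   inverse pass) using linguistic terms.  Terms map to IVFF numbers
   `f = ([μ_L, μ_U], [ν_L, ν_U])` with `μ_U³ + ν_U³ ≤ 1`, are averaged
   across experts, and defuzzified with the score function
   `SF(f) = ½(μ_L³ + μ_U³ − ν_L³ − ν_U³) ∈ [−1, 1]`.  The recursion
   `k_j = 2 − s_j`, `q_j = q_{j−1}/k_j`, `w_j = q_j / Σ q` gives pass
   weights; the final weight is the mean of the two passes.
2. **MAIRCA method ranking.**  Experts rate each assessment method on
   every criterion; ratings are aggregated, defuzzified, min-max
   normalized to `r_ij ∈ [0, 1]` and compared against the theoretical
   equal-preference matrix `t_P[i,j] = w_j/m`.  The total gap
   `Q_i = Σ_j (w_j/m)(1 − r_ij)` ranks the methods (smallest gap wins).
3. **Entropy prioritization of operations.**  The methods' native risk
   scores for each operation form a positive `m × n` matrix; columns are
   normalized over methods, weighted by the MAIRCA gap values, and the
   Shannon entropy `e_j = −(1/ln m) Σ_i M_ij ln M_ij` yields operation
   priorities `w_j = (1 − e_j)/Σ(1 − e_j)`.

A comparison layer re-runs everything under intuitionistic (q=1),
Pythagorean (q=2) and Fermatean (q=3) rungs and under proportional
interval-width perturbation of the linguistic scales, reporting Spearman
rank correlations and pairwise rank-reversal counts.

The emulated case study's panel tables, score matrix and published
result tables ship as checksummed fixtures.  The study's supplementary
linguistic-scale definitions are not published, so the package includes
clearly labelled stand-in scales (`src/ivffmcdm/data/scales/`); replace
those JSON files to use your own.

## Worked example

```python
import ivffmcdm as m

scale = m.builtin_scale("comparison")           # stand-in IVFF scale
fwd = m.load_fixture("piprecia_forward")        # 12 criteria x 3 experts
inv = m.load_fixture("piprecia_inverse")
w = m.weigh_criteria(fwd, inv, scale)
print(round(w["C1"], 4), round(w["C12"], 4))    # 0.2273 0.2824
```

Force requirement (C1) and automation compatibility (C12) dominate the
weight vector — the two most influential ergonomic risk factors for this
panel — with transport/lifting (C2, 0.1232) and scoring precision
(C11, 0.1253) in the next tier.

```python
ent = m.prioritize_operations(m.load_fixture("score_matrix"),
                              m.load_fixture("mairca_Q"))
print(round(ent.k, 4))          # 0.5581  (= 1/ln 6, six methods)
print(round(ent.e["O2"], 4))    # 0.1788  weighted entropy of operation O2
print(ent.ranking_string()[:28])  # 'O12 >> O7 >> O3 >> O2 >> O17'
```

Operation O12 (lowest entropy, most concentrated disagreement among
methods) is the top ergonomic priority.

The same stages are available from the shell:

```bash
ivffmcdm weigh-criteria
ivffmcdm rank-methods
ivffmcdm prioritize-operations
ivffmcdm compare            # q = 1 / 2 / 3 side by side
ivffmcdm robustness         # interval widths k = 0.9 / 1.0 / 1.1
```

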