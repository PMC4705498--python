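# Methods

## The decision model

The package implements the Analytic Hierarchy Process for a two-level
(goal → categories → needs) decision tree, with arbitrary depth supported
by recursive weight propagation. One expert's judgments at one comparison
node form a positive reciprocal matrix **A** of order n with entries on
the discrete scale {1/9, …, 1/2, 1, 2, …, 9}. Intensities are stored as
integers plus an orientation and reciprocals are derived as exact
rationals, so a_ij·a_ji = 1 holds exactly rather than to float tolerance.

**Priority derivation.** The principal right eigenvector of **A**,
normalized to sum 1, is computed by power iteration from the uniform
vector with tolerance 1e-12 on successive normalized iterates (cap
10,000 iterations; the iteration is deterministic — no random start).
λ_max is estimated as the mean over rows of (A·w)_i / w_i. The row
geometric mean, w_i ∝ (Π_j a_ij)^(1/n), is retained as a second, closed-
form derivation: the two coincide exactly on consistent matrices, which
is the main internal correctness check (a dense eigensolver serves as an
independent oracle in the tests only). On noisy matrices the two methods'
weights can swap essentially tied components, so agreement is asserted on
weights pooled over many matrices rather than per-matrix rank vectors.

**Consistency.** CI = (λ_max − n)/(n − 1), CR = CI/RI(n) with the
classical random-index table RI = (0, 0, 0.58, 0.90, 1.12, 1.24, 1.32,
1.41, 1.45, 1.49) for n = 1…10. The table is injectable because published
RI variants differ in the third decimal; orders above the table raise
rather than extrapolate. CR is defined as 0 for n ≤ 2 (all 2×2 reciprocal
matrices are consistent). The acceptability screen is CR ≤ 0.10;
violating respondents are kept with a warning by default or dropped from
the group synthesis with `on_violation="exclude"` — both are exposed
because elicitation practice varies on whether inconsistent responders
are re-interviewed or excluded. The revision suggester returns the pair
maximizing |log(a_ij·w_j/w_i)| under the fitted w and proposes the scale
value log-nearest to w_i/w_j; it is advisory and never applied
automatically.

**Aggregation.** Panel-level weights use aggregation of individual
judgments (AIJ): the entry-wise geometric mean of the respondents'
matrices, which is reciprocal by construction, followed by a single
derivation. Subgroup summaries use aggregation of individual priorities
(AIP): element-wise medians of the per-respondent weight vectors. Medians
of normalized vectors need not sum to one and are *not* renormalized —
the columns stay comparable to individual weights, at the price of not
being a probability vector (an AIP-mean group alternative, renormalized,
is available via `aggregation="aip"`). Global weights multiply local
weights along the root-to-leaf path, so per-category GW sums equal the
category's CW as an exact identity.

**Consensus.** Respondents' priority vectors are read as probability
distributions. With H_α the mean individual Shannon entropy, H_γ the
entropy of the normalized element-wise geometric-mean vector, and
H_β = max(H_γ − H_α, 0), the homogeneity index is
S = (M − exp(H_β))/(M − 1), M = min(#respondents, #criteria), clamped to
[0, 1]. Natural logarithms throughout; the base cancels against the
matching exponential. S = 1 exactly for identical panels. When the
respondents' supports are disjoint the geometric-mean aggregate vanishes
identically; that degenerate case is *defined* as maximal diversity
(S = 0), which realizes the index's documented lower endpoint. The
aggregate (geometric vs arithmetic) and M are configurable because the
diversity-index literature varies in both choices; only the two endpoint
semantics are treated as contractual.

**Subgroup comparison.** Spearman's rank correlation uses average ranks
for ties and the two-sided t-approximation t = ρ√((n−2)/(1−ρ²)) on n−2
degrees of freedom (exact permutation enumeration available for n ≤ 10).
The two-sample t-test defaults to Welch's unequal-variance form with
Welch–Satterthwaite degrees of freedom — the expert groups differ in size
and no variance homogeneity can be assumed — with Student's pooled
variant behind a flag. Boxplot summaries use linear-interpolation
quartiles and the 1.5×IQR fence rule, whiskers at the most extreme
in-fence points.

**System evaluation.** A fulfillment profile assigns each need a score
f ∈ [0, 1]; the coarse canonical labels are 0 (not addressed), 0.5
(partial), 1 (fulfilled), and the mapping is configurable per profile
file since qualitative compliance language quantizes differently across
assessments. The weighted score Σ f_i·GW_i and residuals (1 − f_i)·GW_i
satisfy score + total residual = 1; the gap analysis orders needs by
residual with ties broken by GW and then document order. The single
aggregate score is a convenience extension of the need-by-need weighted
reading; the per-need contributions are the primary output.

## The synthetic-panel generator

The generator emulates the targeted study design: a panel (default 10
technical + 6 clinical experts) answering all pairwise questions of the
PD hierarchy. For ground-truth local priorities w at a node, a
respondent's answer to pair (i, j) is round_to_saaty((w_i/w_j)·e^ε),
ε ~ N(0, σ²) drawn once per unordered pair (exact reciprocity). Rounding
is log-space nearest because the scale is multiplicative, with ties
toward 1. Subgroup divergence δ tilts the two groups' truths by
exp(±δ/2·d) along a fixed zero-sum unit direction d (alternating signs,
centered), renormalized, leaving the panel-level truth unchanged to first
order. One global seed derives a substream per (respondent, node), so any
slice of a panel regenerates identically.

Defaults σ = 0.15, δ = 0.1 were chosen so that simulated panels behave
like a screened expert panel: individual matrices are consistent or
near-consistent (occasional CR slightly above 0.10, as a real panel
produces before revision) and the two subgroups agree broadly while
remaining distinguishable. The study-shaped preset uses the published
group weights as ground truth.

What the generator does *not* model: respondent-level systematic biases
(anchoring, scale compression, acquiescence), question-order effects,
partial questionnaires, and the dependence structure of real expert
opinion (real panels disagree much more than log-normal noise around a
common truth — published consensus values near 0.72–0.87 correspond to
far more heterogeneous priorities than σ = 0.15 produces, where S stays
above 0.99). Passing recovery tests therefore demonstrates correctness
of the estimation machinery under the stated noise model, not robustness
to real-panel heterogeneity.

**Benchmark truths.** Exact rank-order recovery is only a well-posed
target when the true global weights are free of near-ties (the published
weights contain 0.040/0.039/0.038). The designated recovery benchmark
spaces consecutive same-category GWs by the ratio 1.3 and
category-boundary GWs by 2.2: instrument quantization (and the 9-cap on
extreme ratios at the root) compresses contrast, and these gaps keep
every ranking decision resolvable. With that truth set the full pipeline
recovers the exact GW ranking in 50/50 seeded panels at σ ≤ 0.05, and
consolidated node-level weights at σ = 0.1 sit within 0.05 per component
of the study-shaped truths.

## Numerical conventions and problem sizes

- Weight vectors are checked to sum to 1 within 1e-9; entropy inputs
  within 1e-6; 0·log 0 ≡ 0.
- Reported tables round to 3 decimals, matching the reference dataset's
  precision.
- Degenerate inputs raise typed errors rather than returning NaN:
  constant vectors for rank correlation, zero-variance pairs for t-tests,
  single respondents for consensus, incomplete questionnaires for matrix
  assembly (the instrument forces complete questionnaires; no completion
  scheme is implemented).
- A single-child root is allowed (its category takes weight 1); any other
  internal node must have ≥ 2 children for pairwise comparison to be
  defined.
- Stochastic test sizes — 200 oracle matrices, 500 null t-tests, 50
  recovery seeds, 100 consensus panels per divergence level — run the
  whole suite in well under a minute while leaving comfortable margins on
  the asserted bounds (type-I rate asserted in [0.03, 0.07] against a
  binomial standard error of ~0.01 at the nominal 0.05).

## Known limitations

- The published subgroup median columns are reproducible only to their
  printed 3-decimal rounding; their rank correlation computed from the
  printed values is 0.558, whereas the study reports 0.590 from the
  unpublished unrounded medians. The package reports what the printed
  inputs yield.
- Consensus values of the reference study are not reproducible at all
  without the raw judgments; only the index's endpoint semantics and
  monotone response to divergence are tested.
- No fuzzy/interval judgments, incomplete-matrix completion, respondent
  weighting, or network (non-hierarchical) structures.
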