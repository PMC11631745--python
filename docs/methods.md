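# Methods

This document specifies the statistical models and numerical choices in
`comutnet`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the known limitations.

## 1. Cohort model

A cohort is a list of sample records (histology, sex, age, stage,
specimen site, TMB in mutations/Mb, PD-L1 tumor proportion score, MSI
status, and per-assay-component pass flags) plus a list of alteration
records (sample, gene, variant label, alteration class, detection
component, therapy tier). Two inclusion rules are applied before any
analysis:

- **Ultra-hypermutated exclusion**: tumors with TMB strictly above 200
  mut/Mb are removed (TMB = 200 is retained). Such outliers distort
  mean TMB and its group contrasts far beyond their count.
- **Histology restriction**: only adenocarcinoma and squamous-cell
  tumors are kept, since every downstream histology comparison is a
  two-level contrast.

### Assay-aware denominators

The profiling assay has a DNA component and an RNA component, and each
can fail independently per sample. A gene whose pathogenic spectrum is
DNA-only is countable in any DNA-pass sample. A gene whose spectrum
includes RNA-detected events — fusions and exon skipping — can only be
called *negative* in a sample that passed **both** components: an
RNA-failed sample might harbor an undetected fusion. The default list
of such mixed-spectrum genes is ALK, ROS1, RET, MET, NTRK1/2/3 and
FGFR1/2/3; a YAML registry can override the component requirements per
gene. All prevalences, pair tests and dose bins use these per-gene
assayable denominators. An alteration call recorded against a failed
component is contradictory; the cell is masked to "not assayed" with a
warning rather than trusted in either direction.

### Marker bins

PD-L1 TPS: negative < 1 %, low 1–49 %, high ≥ 50 %. TMB: not-high
< 10, high 10–19, very-high ≥ 20 mut/Mb. The bands partition their
ranges, with boundary values belonging to the upper band (TPS = 50 is
high; TMB = 20 is very-high), matching the clinical cutoffs used to
report these markers.

## 2. Cohort summary

The characteristics table reports, per variable, counts and percents in
the full cohort and in each histology. Percents use **per-variable
denominators** (samples with the variable non-missing) and are rounded
**half-up** (ties away from zero) to the printed number of decimals,
because that is how clinical tables are typeset; Python's built-in
banker's rounding would disagree on exact ties (6.25 % prints as 6.3,
not 6.2). A packaged fixture of counts and printed percents verifies
the rule: every printed percent regenerates exactly from its count and
denominator.

Histology contrasts use the two-sided Fisher exact test for categorical
rows (level vs rest × adeno vs squamous) and a least-squares regression
on a squamous indicator for quantitative rows; the latter's t-based
p-value is identical to the pooled-variance two-sample t test, which the
test suite asserts against the textbook formula.

## 3. Pairwise co-occurrence and mutual exclusivity

For each gene pair (both genes at ≥ 1 % prevalence), the 2 × 2 table is
counted over samples assayable for *both* genes.

- **Two-sided Fisher exact p** (probability-mass convention: the sum of
  the probabilities of all tables no more probable than the observed
  one, with a 10⁻⁷ relative tolerance on the comparison). Supplied by
  `scipy.stats.fisher_exact` and verified in the tests against exact
  rational enumeration of the hypergeometric support with
  `fractions.Fraction`.
- **Conditional-MLE odds ratio**: the noncentrality ψ of Fisher's
  noncentral hypergeometric distribution under which the conditional
  expectation of the (1,1) cell equals the observed count. Implemented
  by evaluating the support weights log C(r₁,k) + log C(r₂,c₁−k) + k·log ψ
  with `gammaln` and solving for log ψ by Brent's method. At the
  support boundaries the cMLE does not exist and the conventional 0 and
  ∞ are reported; degenerate margins (single-point support) give NaN.
  The cMLE is preferred to the sample cross-ratio because it is the
  estimate consistent with the conditional (margin-fixed) inference the
  Fisher test performs, and it is finite-sample stable away from the
  boundary.
- **Benjamini–Hochberg** adjustment across all tested pairs
  (`statsmodels.stats.multitest`, verified against the hand-computed
  step-up: q₍ᵢ₎ = min over j ≥ i of p₍ⱼ₎·m/j).

## 4. Network and map-equation modules

Pairs with q < 0.05 form an undirected graph. Each edge carries the
conditional-MLE OR as its **flow weight** (`or_raw`); when that is 0, ∞
or undefined it is replaced by the Haldane–Anscombe-corrected sample OR
((n₁₁+½)(n₀₀+½))/((n₁₀+½)(n₀₁+½)), since flow weights must be positive
and finite. Node **strength** sums the *absolute* OR of incident edges
(max(OR, 1/OR)), so strong exclusivity counts as strong association.
Using the raw (uninverted) OR as flow weight deliberately down-weights
exclusive edges in the random walk: a walker should mostly circulate
inside co-occurring clusters, which is what makes them modules.

Modules minimize the two-level **map equation**: with node visit rates
p_α = s_α / 2W (s_α = strength, W = total edge weight) and module exit
rates q_m = cut_m / 2W,

L(M) = plogp(Σ_m q_m) − 2 Σ_m plogp(q_m) − Σ_α plogp(p_α)
       + Σ_m plogp(q_m + Σ_{α∈m} p_α),   plogp(x) = x·log₂x, 0·log0 = 0.

The search is deterministic: start from all singletons, repeatedly apply
the single-node relocation with the largest description-length decrease
(ties broken by node name), then the best whole-module merge, and
alternate until neither improves. On graphs small enough to enumerate
(≤ 8 nodes, Bell(8) = 4140 partitions) the tests verify the greedy
search reaches the global minimum on 20+ random weighted graphs, and
that two disconnected triangles yield exactly two modules at
L = log₂3 ≈ 1.585 bits. Each module is labeled by its most frequent
non-empty altered-gene combination.

## 5. Driver groups and immunotherapy markers

A YAML taxonomy maps each driver gene's alterations to ordered,
first-match-wins variant groups (e.g. MET exon-14 skip before MET
amplification); unmatched altered samples fall into "other GENE
alteration", and samples with no alteration in any taxonomy gene form
the cohort-wide driver-negative group.

**TMB** contrasts fit one least-squares model per gene — TMB on group
indicators plus a squamous-histology indicator (dropped automatically
when constant) — and test pairwise coefficient differences with t
statistics, Bonferroni-corrected within the gene.

**PD-L1** contrasts dichotomize TPS two ways (≥ 50 % vs rest; ≥ 1 % vs
negative) and use **Firth-penalized logistic regression**: maximize
l(β) + ½·log det I(β). The Newton iteration uses the hat-diagonal-
adjusted score U*_j = Σᵢ (yᵢ − pᵢ + hᵢ(½ − pᵢ)) x_ij with step-halving
that requires the *score norm* to contract — the expected-information
Hessian under-curves the penalized score at very small n, where
plain Newton oscillates. Stopping at max|U*| < 10⁻⁶ is followed by a
terminal refinement loop (a few more contracting steps, targeting
max|U*| < 10⁻¹²), which brings intercept-only fits within 10⁻¹⁰ of the
closed form p̂ = (y+½)/(n+1). P-values come from the **penalized
likelihood-ratio test** of nested Firth fits, with the statistic
2(pl_full − pl_null) clipped at zero (both sides are maximized, so a
negative difference can only be numerical noise). Firth's penalty keeps
estimates finite under complete separation, which genuinely occurs for
rare driver groups with uniformly high or low PD-L1. The Bonferroni
multiplier counts planned tests (contrasts × 2 dichotomies) even when a
degenerate dichotomy (no events or all events) is skipped.

## 6. Dose–response

Per module, tumors are binned by distinct altered member genes: none /
one / two-plus. Tests:

- **Histology**: exact test of the 2 × k adeno/squamous × bin table —
  the Freeman–Halton extension of Fisher's exact test, enumerating all
  margin-compatible tables (vectorized over the free first-row cells)
  when their count is ≤ 10⁷, otherwise a seeded Monte-Carlo estimate
  drawing from the multivariate hypergeometric null and reporting
  (exceedances + 1)/(draws + 1). Empty bins are dropped with a note; a
  single non-empty bin gives p = 1.
- **TMB**: pairwise Welch t tests (none–one, one–two-plus,
  none–two-plus); Welch rather than pooled because bin variances differ
  by construction when alteration count scales TMB.
- **PD-L1**: Pearson chi-squared on the 3-level × bin table without
  continuity correction, warning when any expected count is below 5.

## 7. Synthetic cohort generator

The generator is a study condition, not a convenience: its defaults
define the recovery surface the pipeline is validated on.

- **Randomness**: one global seed keys a counter-based Philox stream
  *per sample* (`counter = [0,0,0,i]`), so enlarging the cohort or the
  gene list never perturbs earlier samples' draws — cohorts are
  extendable and bit-reproducible.
- **Drivers** are mutually exclusive by construction (one categorical
  draw per sample). Defaults: KRAS (adeno 37.5 % / squam 4.6 %;
  variant mix G12C/G12V/G12D), EGFR (17.1 % / 1.3 %; TMB multiplier
  0.5; PD-L1 distribution shifted low), BRAF V600E (7 % / 2 %; PD-L1
  high-level probability 0.6). Prevalences and marker base rates echo a
  large clinical NSCLC profiling cohort.
- **Modules** are latent-Bernoulli mixtures: a latent per-histology
  "on" state (probability λ) switches member genes between p_on and
  p_off, which induces an exact closed-form pairwise odds ratio (the
  cross-ratio of the four mixture cell probabilities, mixed over
  histology). The three default modules (STK11/KEAP1; FGF3/FGF4/CCND1;
  ATRX/GRIN2A/LRP1B) all have implied pairwise OR ≥ 8, asserted in the
  tests. Optional dose effects multiply TMB per altered member gene and
  shift the PD-L1 level distribution by altered-gene count.
- **Markers**: TMB is log-normal per histology, scaled by driver and
  module multipliers, truncated at 200 mut/Mb (mirroring the exclusion
  rule); PD-L1 is a three-level draw with the TPS uniform within the
  band. Assay failures, when enabled, suppress the alteration records a
  failed component would have detected.

Scope: the generator reproduces the statistical structure the pipeline
tests for — exclusivity, module co-occurrence with known ORs, marker
shifts — not biological realism. It does not model stage, specimen
site, MSI variation, intra-gene variant correlation, panel-specific
artifacts, or TMB–PD-L1 correlation beyond what drivers and modules
induce.

## 8. Numerical conventions

- Percents: decimal round-half-up via `decimal.Decimal`, never float
  banker's rounding.
- All log-probability sums use max-subtraction (log-sum-exp); binomial
  coefficients via `gammaln` in the implementation and exact
  `math.comb`/`Fraction` in the test oracles, so implementation and
  oracle never share a code path.
- Map-equation ties are broken deterministically (node-name order,
  improvement threshold 10⁻¹²); `detect_modules` takes a seed for
  interface symmetry but uses no randomness.
- Derived seeds everywhere are drawn below 2³¹.

## 9. Limitations

- The greedy map-equation search is exact on all enumerable graphs we
  test but carries no optimality guarantee on large graphs; it is
  deterministic, so failure modes are at least reproducible.
- The conditional-MLE OR is reported as 0/∞ at the support boundary;
  downstream network weighting substitutes the Haldane–Anscombe OR,
  which is a convention, not an estimate of the same quantity.
- TMB contrasts assume additivity on the raw mut/Mb scale with a single
  histology covariate; heavy right-skew is only partly mitigated by the
  ultra-hypermutated exclusion.
- The Freeman–Halton Monte-Carlo fallback gives a seeded estimate, not
  an exact p; its resolution is bounded by 1/(draws + 1).
- Pairwise exclusivity tests are marginal: they do not condition on
  overall alteration burden, so burden heterogeneity can induce
  apparent co-occurrence among frequently altered genes (visible in the
  synthetic study as a background TP53/KRAS cluster).
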