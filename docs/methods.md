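# Methods

## The question and the three detectors

Given a paired two-condition expression study (each individual measured at
baseline and under stress, log2 scale), the package separates two phenomena:
changes in a gene's expression *level* and changes in its *interactions*
(its statistical relationships with other genes). Levels are tested with
paired t-tests; interactions with two independent detectors — a pairwise one
(Fisher homogeneity of correlations) and a multivariate one (per-gene SVR
models evaluated across conditions) — plus network-level summaries.

### Paired differential expression

Per gene, differences d_i = x_stress,i − x_baseline,i across the n paired
individuals give t = mean(d)/(sd(d)/√n) with df = n − 1 and a two-sided p.
Multiplicity is controlled by Bonferroni over the m genes actually tested
(after presence filtering), P_c = min(1, m·p). Genes with zero-variance
differences are assigned t = 0, p = 1 when the mean difference is zero, and
raise an error otherwise (that situation is impossible for continuous data
and indicates degenerate input). The modest-change classifier keeps genes
with P_c < α, linear fold 2^|mean d| inside [fc_low, fc_high] (inclusive)
and var(d) strictly above a floor; phenotype association uses Pearson
correlation of d with the per-individual phenotype, passing when |r| > r_min
and p < α. The extreme-group comparison ranks individuals by d (ties broken
by individual-ID order) and compares the phenotype of the top-k vs bottom-k
with an equal-variance t-test (Welch optional).

### Fisher-homogeneity differential coexpression

Per condition c, all-pairs Pearson correlations are stored as a condensed
upper-triangle vector (row-major, `scipy.spatial.distance.squareform`
order); constant genes are dropped with a warning. For each pair, z_c =
atanh(r_c) with weight w_c = n_c − 3; the statistic Σ w_c (z_c − z̄)² is
chi-square with k − 1 df under homogeneity, and Bonferroni runs over the
number of pairs tested. The k-sample form covers both the two-treatment and
the multi-timepoint design. Two caveats are deliberate: |r| = 1 is rejected
(infinite z), and the dependence between conditions induced by the paired
design is ignored by the test. The latter matches how the statistic is
ordinarily used; positive dependence between condition-specific correlation
estimates makes the test conservative, and the family-wise error of the
Bonferroni-corrected screen measured on synthetic null studies is at or
below the nominal 5%. Note that Bonferroni at α = 0.05 controls FWE at 5%,
so roughly one null study in twenty will contain a significant pair — zero
calls in ~99% of null studies is not what this procedure promises.

### Network topology

Edges require |r| strictly above τ; isolated genes remain nodes. The mean
local clustering coefficient follows the common convention that nodes of
degree < 2 contribute 0 and stay in the denominator (configurable). The
scale-free fit bins nonzero degrees into n_bins (default 10) equal-width
bins, regresses log10 frequency on log10 mean-degree per nonempty bin, and
reports γ = −slope with the regression R² as the fit index; fewer than 3
nonempty bins (e.g. a regular graph) is an error. Hub retention is the
overlap fraction of the k highest-degree nodes (ties broken by gene ID,
logged). Null networks are Maslov–Sneppen double-edge swaps (networkx
implementation) with a default of 10·|E| accepted swaps capped at 100×
proposals; the degree multiset is asserted unchanged on every call, and
graphs admitting no valid swap (a triangle) are returned unchanged. The
significance of clustering-coefficient differences between observed
networks is assessed against these rewired nulls — a design choice of this
package, since several reasonable nulls exist.

### SVR rewiring

Individuals present at baseline are split once (seeded) into train/test
halves, train size = round(f·n) with half-integers rounding up (131 → 66/65,
95 → 48/47). Training, baseline-test and stressed matrices are z-normalized
separately (per gene, ddof = 1; constant genes become zero rows). Each gene
is regressed on all others with `sklearn.svm.SVR(kernel="linear")`,
ε = 0.1, C = 1.0 — the exact dual solver, so fits are deterministic — and
the hyperplane is stored as explicit weights, which guarantees the test set
can never influence the model. R² is the squared Pearson correlation of
predicted vs actual values (so a sign-flipped perfect predictor scores 1 —
a documented consequence of the definition), 0 when either vector is
constant. Stressed evaluation uses *all* stressed samples, including those
of training individuals; the induced optimism applies equally to every gene
and cancels in the baseline-vs-stress contrast.

The permutation test pools the baseline-test and stressed samples and
reassigns them to groups of the original sizes; p = (1 + #{ΔR²_perm ≥
ΔR²_obs})/(1 + n_perm), so the smallest attainable p is 1/(n_perm+1) and
p = 0 is impossible. Each gene draws its permutation stream from a seed
keyed by the gene ID, making results independent of evaluation order and of
which other genes are analyzed. The FDR estimate at threshold t is the mean
permutation count of ΔR² ≥ t across genes divided by the observed count,
capped at 1 and monotonized q-value style (the estimate at a threshold is
the minimum over all stricter-or-equal raw estimates scanning from the
loosest threshold upward, so FDR never decreases as the threshold loosens).

### Overlap and comparison statistics

Set overlaps use the exact hypergeometric upper tail P(X ≥ obs) with the
run's filtered expressed-gene set as the universe. Annotation sharing
(fraction of pairs whose genes share ≥ 1 GMT term) is compared between
observed pairs and degree-preserving random pairs with a two-proportion
z-test, falling back to Fisher's exact test when any count is below 5.
Cross-stress comparison intersects each arm's significant genes over the
shared universe and is symmetric in its arguments.

## The synthetic generator

`generate_study` draws, for gene g, individual i, condition c,

    x_gic = μ_g + a_i + λ·F_{b(g),ic} + β_gc·P_{p(g),ic} + δ_g·1[c=stress] + ε_gic

with μ_g ~ N(8, 1) (typical log2 microarray range under the scaled-to-500
convention), a shared individual effect a_i ~ N(0, σ_a²) identical in both
conditions (the paired design), per-condition standard-normal block factors
F (background coexpression, block membership g mod n_blocks), pair factors P
shared by the two genes of a planted pair, an additive stress shift δ_g for
planted DE genes, and iid noise ε ~ N(0, σ_ε²). Pair genes are excluded
from blocks so the planted correlation is analytic: with V₀ = σ_a² + σ_ε²,
the loading solves β² = (rV₀ − σ_a²)/(1 − r) with a positive loading
product when r > σ_a²/V₀, else β² = (σ_a² − rV₀)/(1 + r) with one loading
negated — exact for every |r| ≤ 0.99 whenever V₀ > 0. Detection calls are
Bernoulli 'P' per cell at `present_fraction` (a configurable subset forced
low-presence), and the phenotype is Σ_g effect_g·Δx_g,i plus
N(0, phenotype_noise_sd²) noise per individual. All draws come from
dedicated seeded streams, so e.g. detection calls are reproducible
independently of the expression draw.

Defaults emulate the motivating design: ~100 paired individuals, modest
planted fold changes (1.2–2×, i.e. 0.26–1.0 log2 units), noise_sd 0.5,
individual effect 0.2. What the generator does *not* emulate: probe-level
effects, batch effects, missing values, heavy-tailed expression, and the
dense large-scale correlation structure of a real transcriptome (blocks are
disjoint and equally loaded). Passing tests therefore demonstrate
correctness and calibration of the statistics under a Gaussian latent-factor
model, not performance on any particular real dataset. The expression
distribution itself is this package's choice; the study design the generator
mirrors does not specify one.

`generate_module_switch_study` is the power/FDR companion: two modules of
`module_size` genes follow per-condition factors F1 and F2 at loading 1.0
over noise 0.5, and the planted targets follow F1 at baseline but F2 under
stress — a gene whose generating weights change. The redundancy of a module
mirrors real coexpression data, where well-modeled genes are predicted by
many correlated partners; with the defaults a target's model-attainable R²
is loading²/(loading² + noise_sd²) = 0.8, the regime reported for
well-predicted genes. Important bookkeeping subtlety: when a target
switches modules, the *module members'* correlations with it change too
(module 1 loses it, module 2 gains it), so the only genes whose
interactions are genuinely unchanged are the independent-noise genes; FDR
calibration counts false discoveries against that null set. The matched
null study (`switch=False`) keeps every relationship intact and, because
individuals carry no shared effect in this design, makes baseline-test and
stressed samples exchangeable — the clean setting for verifying the
permutation test's type-I error. (With a nonzero shared individual effect
the stressed samples of test individuals are dependent on their baseline
samples; the permutation test ignores this, as the analysis it implements
does.)

## Numerical and scale choices

* Trimmed-mean scaling uses 2% two-sided trimming (the conventional default
  for the scaled-to-500 normalization, whose exact trimming is not pinned
  down); values below 1 are clamped to 1 before log2.
* Marginal ('M') detection calls count as not-present; the ≥ threshold is
  inclusive and applies per condition with that condition's sample count
  ("present in at least 80% of samples in *either* condition").
* Probeset collapsing drops `*x_at` probesets first, then picks one probeset
  per gene uniformly at random from a dedicated seeded stream.
* All-pairs correlation at thousands of genes is one dense `corrcoef`; the
  condensed vector for the 6775-gene case is ~23M floats (≈180 MB), fine on
  a desktop.
* Simulation sizes in the test suite and acceptance script (100–200 genes,
  100–131 individuals, 200 permutations, 20–100 seeds per property) are the
  package's chosen verification scale; they keep every calibration check
  sharp (3·SE bounds) while remaining minutes-cheap.

## Known limitations

* The Fisher homogeneity test ignores paired-sample dependence between
  conditions (conservative under positive dependence).
* The correlation-based R² rewards anti-correlated predictions; it is kept
  because it is the definition this analysis uses.
* The permutation FDR estimator (pooled-null ratio, monotonized) is one of
  several reasonable choices; it is validated empirically (estimated FDR
  not exceeded by the realized false-discovery proportion beyond noise) on
  planted studies rather than derived.
* Bonferroni over ~2×10⁷ dependent pair tests is blunt; genuinely rewired
  pairs with small |Δr| will be missed at realistic sample sizes.
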