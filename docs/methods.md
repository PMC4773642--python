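# Methods

## The screen

The pipeline implements a pooled-phenotype transcriptomic screen for genes
associated with plant architecture in olive (*Olea europaea*). Material comes
from a breeding cross: among ~120 seedlings of a Picual × Arbequina progeny,
the individuals with the most extreme values of two architecture traits are
pooled — short vs long internode length (SILe/LILe) and small vs large trunk
diameter (SmaD/LarD) — and a fifth pool (ChiCa) collects Chiquitita × Arbosana
seedlings with the compact Chiquitita-like canopy. The pools and four named
varieties (Chiquitita, Picual, Arbequina, Arbosana) give 9 sample groups, each
hybridized in 3 biological replicates on a 37449-feature expression array.

Selection is a *three-way comparison* per trait:

1. **Primary contrast** between opposite-phenotype samples
   (SILe vs LILe; SmaD vs LarD; Chiquitita vs Arbosana for growth habit).
   A gene qualifies when, jointly,
   * the two-tailed equal-variance Student t-test gives p < α
     (df = n₁ + n₂ − 2, default α = 0.05), and
   * the fold change x̄/ȳ of the *linear* group means lies strictly outside
     [1/θ, θ] with θ = 2 ("more than 2-fold": a ratio of exactly 2 fails).
2. **Concordance contrast** between the reference variety (Chiquitita) and
   its like-phenotype pool (SILe, SmaD, or ChiCa). The gene is kept only when
   this contrast is *not* significant (p ≥ α), fold change ignored. This
   filters out genes that differ for pedigree reasons unrelated to the trait.

No gene-level multiple-testing correction is applied by default — the screen
deliberately operates at the raw per-gene α, with FDR control reserved for
the GO stage. A Benjamini–Hochberg switch exists for users who want it.

**Test scale.** The t-test runs on log2-transformed intensities by default
(`test_scale="log2"`), where microarray noise is closest to additive
Gaussian; the fold change is always a ratio of linear means. A `linear`
switch runs the t-test on raw intensities instead; neither scale is asserted
as canonical, since the selection rule itself only fixes the fold-change
scale.

The three trait-wise candidate sets are assembled into a Venn summary whose
union is the final candidate list; the three-set algebra is exact and the
inclusion–exclusion identity is asserted on every summary.

## Validation statistics

**Random-set Kruskal–Wallis.** To ask whether a candidate set separates the
9 sample groups more than chance, the per-gene per-group mean of log2
expression is treated as the observation (genes are observations, the 9
groups the factor) and a Kruskal–Wallis H test is run for the candidate set
and for R random gene sets of identical size drawn uniformly without
replacement from the array (default R = 1000, seeded). The phrase "median
expression of the set across the 9 samples" admits several readings; this
one makes the null concrete and testable. Two caveats follow directly from
the rank construction and are intentional:

* KW assumes observations are independent across groups. Per-gene baselines
  shared across groups violate this and make the test *conservative*: with
  realistic between-gene spread (baseline sd ~2 log2 units), random sets
  yield p ≈ 1 rather than uniform p. Calibration checks therefore zero the
  baseline spread so group samples are exchangeable, and under that null the
  fraction of random sets with p < α matches α to binomial accuracy.
* Mixed-direction signal cancels in ranks: a candidate set whose members are
  up- *and* down-regulated in the affected groups moves group medians little,
  so the KW validation only flags sets with a sign-consistent shift. The
  signal/noise check plants a one-group shift of +1 log2 unit, which drives
  the candidate p below 10⁻⁶ while random sets stay unremarkable.

**Overlap significance.** The chance overlap of two candidate sets of sizes
n_A and n_B on an array of N genes is modelled as Poisson with rate
λ = n_A·n_B/N, and P(X ≥ k) is computed by exact term summation of the
complementary lower tail (stable recurrence, no normal approximation). The
exact hypergeometric tail — the reference model for a random n_A-set against
a fixed n_B-set — is provided alongside; the two agree within ~10% whenever
both sets are small relative to the universe and the observed overlap is not
deep in the tail (the Poisson-vs-binomial error grows like k²/n_A). The
universe defaults to the number of genes on the array and is configurable.
This is the package's own clearly defined statistic: published overlap
p-values computed with unstated universes or tail conventions are not
reproduction targets.

## GO enrichment

Per term, a 2×2 table (candidate with/without term × background with/without
term) is tested by a two-sided Fisher exact test: the full hypergeometric
support for the fixed margins is enumerated and all point probabilities not
exceeding the observed one (relative tolerance 10⁻⁷) are summed — the
dominant two-sided convention. q-values are Benjamini–Hochberg over all
tested terms, with a q < 0.05 filter by default. The background defaults to
the annotated part of the array (configurable to the whole array). Only
directly assigned terms are tested unless a (child, parent) ontology edge
list is supplied, in which case annotations are propagated to all ancestors
(true-path rule) before testing.

## qPCR concordance

Relative expression uses the plain ΔCt method with assumed amplification
efficiency 2: rel = 2^−(C̄t_target − C̄t_reference) against a constitutive
actin reference. Technical triplicates are averaged at the Ct level;
biological replicates are summarized after the transform on the log2 scale,
preserving the geometric structure of ratios. Platform agreement pairs
per-gene log2 ratios (qPCR vs array) and compares Pearson r with the
analytic critical value r_c = t_{α,df}/√(t² + df), df = n − 2. The critical
value is single-tailed by default, which reproduces the conventional table
value 0.708 for n = 12 at α = 0.005 (the two-tailed value would be 0.750);
a two-tailed switch exists. Per-seedling comparisons use one-way ANOVA
followed, when significant at α, by Fisher's LSD at 95%:
LSD = t_{α/2, df_err}·√(MSE·(1/nᵢ + 1/nⱼ)), with compact letters assigned by
a descending-mean sweep so that groups sharing a letter are mutually
non-significant.

## Synthetic data

The generator emulates the study design so every stage is testable without
the original hybridizations: log2 value = baseline + group effect + noise,
with per-gene baselines N(10, 2²) drawn once and shared across groups
(preserving gene-wise pairing), i.i.d. Gaussian replicate noise (default
sd 0.2 log2 units, matching the high replicate correlations the QC stage
expects), and linear values 2^(·). Planted effects follow the three-way
logic: a *concordant* gene carries the same signed log2 shift (default
magnitude 1.5, random sign) in the trait's Chiquitita-like pool and in the
reference itself, so the primary contrast fires and the concordance contrast
stays null; a *discordant* gene carries the opposite shift in the reference,
and the filter should reject it. Planted sets are disjoint across traits.
Default scale is 5000 genes for routine work — large enough for stable
calibration estimates, small enough to run in seconds — with the full 37449
available by parameter. Pool phenotypes (120 seedlings, diameter ~N(75, 20²)
mm, internode latent ~N(1.8, 0.5²) mm with 0.3 mm branch scatter) bracket
the spreads of the published pool tables. Ct tables plant log2 ratios with
technical-triplicate structure; at zero Ct noise the ΔCt transform recovers
them exactly.

What the generator does *not* model: probe-level effects, dye bias,
normalization artifacts, correlated noise between replicates, and the
physical RNA mixing of pools (each pool is one group; mixing 4–6 seedlings
before hybridization may shrink biological variance in ways the i.i.d. noise
model ignores). Passing tests therefore demonstrate the correctness and
calibration of the *statistics*, not the biology of any particular array.

## Numerical and degenerate-case choices

* Zero pooled variance in a contrast: p = 1 when the group means are equal,
  p = 0 with a warning when they differ (constant fixtures stay defined).
* Strict inequalities throughout the DEG rule: p < α, fold change outside the
  *closed* interval [1/θ, θ].
* Trait values are rounded half-up to 2 decimals for display only; full
  precision propagates internally.
* Extreme-pool ties break by input row order (stable sort) — selection is
  deterministic on constant tables.
* Repeated seedling ids warn rather than fail: the published pool table
  itself reuses an id within one pool, so rows are identified positionally.
* The noise-free recovery oracle applies to the primary DEG call (100% of
  planted genes recovered as noise vanishes). It cannot apply to the
  three-way filter: the concordance t statistic is scale-invariant, so under
  the concordant null its p-value is uniform at *any* noise level and the
  filter excludes ≈ α of true concordant genes by construction. Expected
  three-way recall is therefore ≈ (1 − α) · power, and the recovery checks
  assert ≥ 90% under the reference conditions.
* All randomness flows from one top-level seed; per-stage child seeds derive
  via `numpy.random.SeedSequence([seed, stage_index])` and are recorded in
  the run manifest.

## Known limitations

* The KW validation's power depends strongly on sign-consistency of the
  candidate set's effects (see above); a mixed up/down candidate set can be
  real and still validate at p ≈ 1.
* The Poisson overlap model treats the two sets as independent uniform
  draws; sets produced by overlapping contrasts on the same data violate
  independence, which is why the hypergeometric reference is reported
  alongside.
* Enrichment results depend on the annotation's term granularity and on the
  background choice; with propagation off, parent terms are only tested if
  directly assigned.
* ΔCt assumes perfect amplification efficiency; no efficiency correction or
  multi-reference normalization is implemented.
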