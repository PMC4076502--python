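# Methods

## Problem and model

A di-allelic SNP in a case-control study is summarized by a 2×3 table of
genotype counts: cases (X₁, X₂, X₃) and controls (Y₁, Y₂, Y₃) for
genotypes (AA, Aa, aa), with `a` the minor (risk) allele, arm totals
R_X and R_Y, column totals C₁..C₃, and N = R_X + R_Y. The
Cochran-Armitage (CA) trend statistic with genotype weights
t = (t₁, t₂, t₃) is

    W = Σᵢ tᵢ (R_Y Xᵢ − R_X Yᵢ),

with weights (0,1,2), (0,1,1), (0,0,1) for the additive, dominant, and
recessive genetic models (statistics T₁, T₂, T₃). Analysts routinely run
all three because the true inheritance model is unknown; the three
statistics are functionally dependent (T₃ = T₁ − T₂), so reporting their
minimum p-value is anti-conservative and Bonferroni over-corrects.

### Asymptotic tests

Each W is standardized by its null variance

    Var(W) = (R_X R_Y / N) (N Σ tᵢ² Cᵢ − (Σ tᵢ Cᵢ)²),

and z = W/√Var(W) is referred to the standard normal, two-sided. z²
equals the usual χ²₁ trend statistic, so the two-sided normal and the
χ²₁ tails agree. A weighting with all its mass in one occupied column
has Var(W) = 0; such degenerate tables report p = 1 with a flag rather
than raising. min-p is the uncorrected minimum of the three p-values
(kept only as an invalid comparator); Bonferroni is min(1, 3·min-p).

### Exact joint distribution

Conditional on the arm sizes, (X₁,X₂,X₃) and (Y₁,Y₂,Y₃) are modeled as
independent trinomials with probability triples p and q. Because
T₃ = T₁ − T₂, the joint law of the three statistics is carried by the
two symmetrized integer coordinates

    Z₁ = R_Y X₃ − R_X Y₃,    Z₂ = R_Y X₂ − R_X Y₂

(inverse: T₁ = 2Z₁ + Z₂, T₂ = Z₁ + Z₂). The support is the solution set
of these two linear Diophantine equations under the trinomial
constraints: for each of the (R_Y+1)(R_Y+2)/2 pairs (Y₂, Y₃) the
attainable points form a translated triangle of (R_X+1)(R_X+2)/2 lattice
points, and triangles overlap only at multiples of gcd(R_X, R_Y).

The exact p-value orders outcomes by probability:

    p(z₁, z₂) = Σ { f(Z₁, Z₂) : f(Z₁, Z₂) ≤ f(z₁, z₂) },

the total mass of all support cells no more probable than the observed
one (a two-sided exact test on a discrete lattice, analogous in spirit
to Fisher's exact test but conditioning only on the arm sizes, not the
genotype margins).

### Null probability triples

A null reference distribution requires a common triple p = q. The
default is the pooled maximum-likelihood estimate under the null,
pᵢ = qᵢ = Cᵢ/N. Separate per-arm estimates (pᵢ = Xᵢ/R_X, qᵢ = Yᵢ/R_Y)
are exposed for completeness but are degenerate for probability
ordering: they make the observed cell modal, so every cell satisfies
f ≤ f_obs and the p-value is 1. Fixed user-supplied triples are also
accepted (validated to be non-negative and sum to 1 within 1e-9).

## Algorithms

Dispatch is on the gcd regime of (R_X, R_Y):

* **coprime** (gcd = 1, R_X ≠ R_Y). Triangles share no lattice point
  except the origin, where exactly three meet (the all-AA, all-Aa and
  all-aa diagonal outcomes). Every other cell's mass is a single product
  f_X·f_Y of trinomial masses, so the p-value is
  P(f_X(X) f_Y(Y) ≤ f_obs) over independent trinomials: sort the case-arm
  log-masses once, binary-search per control cell against prefix sums,
  and correct the three origin terms for pooling. O(R² log R) time,
  O(R²) memory, never materializing the support. The worked example
  (421/423, coprime) runs in well under a second.
* **equal** (R_X = R_Y = R). Z₁ and Z₂ are multiples of R, so the
  support condenses to the (2R+1)×(2R+1) matrix indexed by
  (X₃−Y₃, X₂−Y₂) — the 2-D cross-correlation of the case and control
  trinomial triangle arrays. It is accumulated by exact direct summation
  (scatter-add over triangle-cell pairs, chunked over control cells to
  bound memory at a few million floats); only the condensed matrix is
  ever stored. O(R⁴) time; R = 200 takes well under a second, R = 1000
  is feasible but slow (~10¹² elementary products) and sits above the
  default term budget.
* **general** (gcd > 1, unequal). The per-cell sums over contributing
  triangles are accumulated in one deterministic row-major pass into a
  sparse map keyed by (Z₁, Z₂) (vectorized per triangle, aggregated with
  a stable key sort). Memory scales with the support size, so this path
  has its own storage ceiling (5·10⁷ terms) in addition to the global
  term budget.

A brute-force enumerator over all (X₂, X₃, Y₂, Y₃) combinations, guarded
to (R_X+1)²(R_Y+1)²/4 ≤ 10⁷, is the independent oracle; the test suite
checks every optimized path against it to 1e-10 across all three
regimes.

### Numerical choices

* Trinomial masses are computed in log space from `scipy.special.gammaln`
  log-factorials; 0·log 0 is treated as 0 so zero-probability categories
  simply drop their cells from the support. Masses underflow double
  precision near N ≈ 2000 only at extreme cells whose true contribution
  to any p-value is far below 1e-300, so p-value accumulation is done in
  linear space.
* Tie rule: "equally or less probable" includes cells with
  f ≤ f_obs·(1 + tie_tol), tie_tol = 1e-12 relative. Mathematically tied
  cells (e.g. the point-symmetric mirror of the observed cell when
  p = q) are computed through different floating orderings and can
  differ in the last few ulps; 1e-12 absorbs that while being far below
  any scientifically meaningful probability difference.
* An observed outcome with zero null probability (possible only with
  user-fixed triples) raises a validation error rather than reporting
  p = 0.
* The dispatcher estimates the elementary term count
  (R_X+1)(R_X+2)(R_Y+1)(R_Y+2)/4 and refuses above a configurable budget
  (default 10¹¹) with the estimate in the message.
* Iteration orders are fixed (row-major over triangles), so repeated
  runs are bit-identical.

## Simulation harness

The generator emulates a retrospective case-control study of a single
SNP: genotypes are drawn under Hardy-Weinberg equilibrium (HWE) from the
minor allele frequency m — probabilities ((1−m)², 2m(1−m), m²) — and
disease status from the logistic model logit P(Z=1) = β₀ + β₁X, where X
codes genotype under the generating model (additive 0/1/2, dominant 0/1,
recessive 0/1) and β₁ is the log odds ratio. Individuals accrue into the
case and control arms in draw order until both quotas are met; excess
individuals of a filled arm are discarded. The batched implementation is
exactly equivalent to one-at-a-time accrual because the accrued arms are
the first n_cases cases and first n_controls controls in draw order.

Default study conditions: MAF 0.40, β₀ = −2.5, β₁ = log(1) (null),
1000 cases / 1000 controls, 1000 replicates, α = 0.05. Power scenarios
use odds ratios 1.2 (additive) and 1.3 (dominant, recessive) at MAFs
0.40 and 0.20, keeping β₀ = −2.5 (β₀ is exposed in the config; the
prevalence it implies, ≈7.6%, only shifts the accrual rejection rate,
not the genotype-given-status laws).

One root seed spawns an independent child stream per replicate
(`SeedSequence.spawn`), so any prefix or subset of replicates is
reproducible in isolation and experiment runs are bit-reproducible.

What the generator does *not* emulate: linkage disequilibrium between
SNPs, covariates or population stratification, genotyping error, missing
data, or deviation from HWE. Passing simulation tests therefore
establish the operating characteristics of the tests under a clean
single-SNP retrospective design, not robustness to those complications.

Test and acceptance runs keep full scale (1000/1000, 1000 replicates)
for the asymptotic methods, whose per-replicate cost is microseconds.
Experiments that evaluate the exact joint test per replicate use smaller
coprime arm sizes (e.g. 201/200 or 151/150, 300–600 replicates), where
the coprime path makes the exact test cheap; coprime sizes were chosen
deliberately since the equal-arms path is the costliest per replicate.

## Design decisions that were genuinely open

* **Pooled vs separate null triples.** The per-arm estimators do not
  enforce the null hypothesis and are degenerate for probability
  ordering (see above), so the pooled MLE is the default; both are
  exposed.
* **Two-sidedness.** The two-sided normal tail reproduces the published
  per-model p-values of the worked example exactly at printed precision;
  one-sided tails do not.
* **Variance formula.** The unconditional CA null variance above was
  validated the same way (all three worked-example p-values match at 4
  decimals).
* **Bonferroni as p-value scaling.** min(1, 3·min-p) is equivalent to
  the α/3 threshold rule used in the simulation comparisons.

## Known limitations

* The probability-ordering exact test on this unconditional joint pmf is
  markedly conservative: the pmf is highly multimodal with a very large,
  thin-mass support, so the ordering admits a substantial total mass of
  far-away low-probability cells into the rejection sum. The test
  controls its level (empirically well below α in the included
  simulations) but is less powerful than Bonferroni at the simulated
  effect sizes. For the worked breast-cancer example it reports
  p = 0.0864 where the per-model asymptotic p-values are
  0.0045/0.0148/0.0313 — the joint exact procedure as printed is more
  conservative than any single-model test on these data.
* The equal-arms path at R = 1000 requires ~10¹² elementary products
  (minutes to hours depending on hardware); the coprime path at the same
  N is near-instant. Users with equal arms and large N can drop one
  control to land on a coprime pair at negligible inferential cost.
* Multi-allelic loci, X-linked/sex-stratified analyses, covariate
  adjustment, and margin-conditioned (Fisher-style) exact variants are
  out of scope.
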