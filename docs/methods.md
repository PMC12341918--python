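# Methods

## The 2x–4x genetic model

A triploid hybrid receives one genome from its diploid (2x) parent and two
from its tetraploid (4x) parent, itself a colchicine-doubled diploid.  The
phenotype of plant *h* from cross (u, v), measured in block *b* at crop
cycle *c* (replicate *r* exists only for the repeated check variety), is

    y = μ + α_b + β_c + D_u + T_v + (D×T)_uv + H_th + e

All genetic terms are random; block and cycle are fixed with corner-point
(first-level-reference) constraints.  Errors of the same plant across its
crop cycles follow an unstructured positive-definite 3×3 covariance R
(`e ~ N(0, R ⊗ I)` over plants); plants missing a cycle contribute the
corresponding principal submatrix.  All random terms are independent of
each other.

Model variants differ in the covariances of the genetic terms:

| variant            | D, T            | SCA term(s)                          |
|--------------------|-----------------|--------------------------------------|
| `PHENO`            | identity        | identity                             |
| `GCA_A`            | A_D, A_T        | identity                             |
| `GCA_A_SCA_D`      | A_D, A_T        | dominance: mean −F·b, covariance D   |
| `GCA_A_SCA_AA`     | A_D, A_T        | epistasis: A_D ⊗ A_T submatrix       |
| `GCA_A_SCA_D_AA`   | A_D, A_T        | both                                 |

The dominance mean −F·b is carried as a fixed covariate (the column holds
F_uv, its coefficient estimates −b), so a Wald test of b is read off the
fixed-effects solution.

## Genomic covariance structures

Parents of both ploidies are stored as diploid base genotypes (dosage
0/1/2); tetraploid dosages are twice the base, because every 4x parent is a
doubled diploid.  Allele frequencies f_m default to the unweighted panel
mean (each parent counted once regardless of usage); a reference subset
can be supplied.  This keeps A_T = 2 A_D exact.

* Additive GRM at ploidy P: `(A_P)ij = Σ_m (X_im − P f_m)(X_jm − P f_m) /
  (P Σ_m f_m (1−f_m))`.
* Dominance regressor at ploidy P: `Q = τ_P − (X − ξ_P)²` with
  `τ_P = (P−1) f (1−f) + ¼`, `ξ_P = (P−1) f + ½`; its expectation over
  Hardy–Weinberg genotypes is zero.
* Expected hybrid regressor of a cross: the hybrid dosage is one Bernoulli
  2x gamete plus one hypergeometric 4x gamete (random bivalent pairing,
  no double reduction), giving `E(X) = (x2 + x4)/2` and
  `E(X²) = x2/2 + (2x4 + x4²)/6 + x2·x4/2`, hence
  `Q_uv = τ₃ − ξ₃² − E(X²) + E(X)(4f + 1)`.  All cross-level quantities
  use the hybrid ploidy P = 3 in τ, ξ and C(P,2); parental ploidies enter
  only through dosages.
* Expected inbreeding: `F_uv = −Σ_m Q_uvm / (C(3,2) · 2 · Σ_m f(1−f))`.
* Expected dominance GRM: `D_{uv,u'v'} = Σ_m Q_uvm Q_u'v'm /
  (C(3,2)² · 4 · Σ_m f²(1−f)²)`.
* Across-population epistasis: `(A_D)_{uu'} (A_T)_{vv'}` over crosses — a
  principal submatrix of a Kronecker product of PSD matrices, hence PSD.

Denominator conventions: the normalisations above reduce at P = 2 to the
standard diploid dominance normalisations (2Σf(1−f) and Σ(2f(1−f))²), make
F = 1 for a cross fixed for one allele and F = 0 when progeny genotype
frequencies match Hardy–Weinberg.  Note that doubled-diploid 4x parents
*never* produce Hardy–Weinberg progeny: the two chromosomes of a 4x gamete
are IBD with probability 1/3, so random crosses of unrelated parents have
expected F near 1/9 — a real feature of this breeding system, verified in
the tests.

PSD is checked with tolerance 1e−8 and never enforced by projection; an
optional diagonal jitter (default off) is available for near-singular
structures.  A parent used both as 2x and as 4x appears as two levels
backed by the same base genotype.

## REML engine

`lmm.MixedModel` supports any number of random terms with supplied
covariance structures, variance parameters shared by name, an unstructured
cycle covariance applied blockwise per plant, and a fixed mean covariate
for the dominance term.  Two implementation choices matter:

* **Scaled eigen-factor representation.**  Each structure G_k is factored
  once as L_k L_kᵀ (null eigendirections dropped), and the working design
  is Z_k L_k with iid scaled effects.  Singular GRMs are handled without
  ridges, and levels with no observations (held-out crosses, unobserved
  parents) receive BLUPs through their covariance with observed levels —
  the one-step prediction used in cross-validation.
* **Absorption of plant-exclusive terms.**  The within-cross hybrid effect
  of a once-planted hybrid only appears in that plant's records, so its
  contribution is folded into the per-plant residual block (R + σ²_H J).
  This removes thousands of mixed-model-equation rows at identical
  likelihood.  The repeated control varieties span plants and stay an
  explicit term sharing the same σ²_H.  Cross-specific within-cross
  variances (one parameter per cross with >15 progeny, one pooled
  parameter for the rest and the controls) are absorbed the same way.

The REML criterion is evaluated through the Woodbury identity on the
factored design and maximised with projected quasi-Newton steps (L-BFGS-B)
on analytic gradients; variances are bounded below at 1e−10·var(y) and
flagged when pinned there, and R is parameterised by its Cholesky factor.
Monotone EM-REML updates serve as warm start and as fallback when the
quasi-Newton path fails; the EM update of R requires complete cycle
patterns and is skipped otherwise.  Convergence: relative criterion change
below 1e−12 per L-BFGS-B step with projected-gradient tolerance 1e−7
(restarting from a solution moves the log-likelihood by <1e−6, verified in
tests); at most 200 iterations.

Likelihood-ratio tests of nested fits use χ² references; when a single
variance sits on the boundary under the null the 50:50 mixture
½χ²₀ + ½χ²₁ is used.

**Identifiability.**  For once-planted hybrids σ²_H J₃ lies inside the
span of an unstructured R, so σ²_H is separated from R only through the
replicated checks (and the control-variety variance).  Designs with few
blocks therefore estimate σ²_H noisily — visible in null-calibration
simulations, which need the full benchmark design (~50 blocks, ~430
control plants) to keep spurious H² below 0.05 in ≥95% of runs.  The same
confounding is intrinsic to the real experimental design, not an artefact
of the engine.

## Heritability

`H² = E(V_G) / (E(V_G) + E(V_Ē))` over the N evaluated breeding hybrids
(controls excluded — heritability describes the breeding population).
`E(V_G) = (1/(N−1)) Σ_k [Tr(Z_kᵀ C Z_k G_k) + μ_kᵀ Z_kᵀ C Z_k μ_k]` with C
the centering projector, G_k and μ_k the REML plug-in covariance and mean
of component k (μ_k = −F·b̂ for the dominance term, zero otherwise), and
Z_k mapping hybrids (one row each) to levels.
`E(V_Ē) = Σ_cc' R̂_cc' / 9` is the variance of the cycle-averaged error.
Per-component contributions divide by the same denominator and sum to H².

## Cross evaluation and progeny sizing

Two clonal-value scales: `yhat = m̂ + D̂_u + T̂_v + (D×T̂)_uv + Ĥ_th` with
`m̂ = μ̂ + mean(α̂) + mean(β̂)`, and the shrinkage-free corrected mean
`ytilde = mean(y − α̂_b − β̂_c)` over a genotype's records.  The correction
uses *centred* effect estimates, making ytilde invariant to the
identifiability constraint and directly comparable to m̂.  Controls,
observed in every block, are averaged over all replicates — this is the
scale on which crosses are compared to the Cavendish check.

Cross means for progeny sizing use ytilde; observed cross means for
predictive ability use yhat (both are exposed).  The minimum progeny size
against a reference y_ref at probability p is
`N_min = ⌈log(1−p) / log q⌉` with q the per-offspring probability of
failing to beat y_ref under N(μ̂_uv, σ̂²_uv); q = 0 gives 1, q = 1 is
"not attainable" (∞), and σ = 0 resolves through those limits.  The
ceiling is used because a progeny count is an integer; p defaults to 0.9.
Trait directions (lower-is-better for pseudostem height, robustness index,
peduncle index and days to fruit maturity; the three leaf-blade traits are
descriptive and have none) live in the trait catalog.

Genotypic correlations are Pearson correlations of yhat across breeding
hybrids, tested with the t approximation (n−2 df) and filtered by Holm's
sequential Bonferroni at family level 5%.  The PCA of cross-mean
performance standardises traits to unit variance (a sensitivity toggle is
provided) and reports scores, loadings, variance shares and trait–axis
correlations.

## Cross-validation

Folds per scenario: 2x–4x holds out one cross (both parents must appear in
other crosses); 0–4x also removes every cross of the 2x parent (the 4x
parent must remain observed); 2x–0 is the mirror image; 0–0 removes every
cross of either parent.  The pedigree-only variant cannot predict in 0–0
and raises.  Training fits re-estimate all variance parameters per fold by
default; a fast mode reuses the full-data REML estimates and only
re-solves the mixed-model equations on the training records (used by the
test benchmarks).  Folds where REML fails fall back to EM; persistent
failures drop the fold with a reason.  Fold hygiene is auditable through a
checksum of the training records in each report row.

## Synthetic data

The generator emulates: diploid panels with Binomial(2, f) dosages and
frequencies uniform on (0.05, 0.95); tetraploids by dosage doubling;
triploid progeny as Bernoulli 2x gamete + hypergeometric 4x gamete
(polysomic, zero double reduction); unbalanced family sizes (lognormal,
clipped to 1–188, matching the reported range); blocks of 56 hybrids and 8
controls (5 Cavendish-type checks plus 3 single controls), blocks grouped
into trials; three cycles with errors from an unstructured R.  Default
variance components (σ²_D = 0.3, σ²_T = 0.9, σ²_DT = 0.1, σ²_H = 0.5, R
with positive cross-cycle covariances) encode the study's qualitative
findings: tetraploid GCA ≈ 3× diploid GCA, small SCA, large within-cross
share, moderate-to-high heritability.

Genetic values come either from Gaussian draws of the components
(`engine="gaussian"`, used for recovery benchmarks, where "realized
truth" is the empirical variance of the drawn effects) or from QTL
effects on simulated triploid dosages (`engine="genomic"`), decomposed
exactly into GCA/SCA/within parts via the closed-form conditional
expectations over the virtual complete factorial of the parents — no
Monte Carlo in the truth.

What it does **not** emulate: linkage (markers segregate independently —
the model's quantities are single-marker expectations, but real LD would
change GRM sampling noise), preferential pairing or double reduction in 4x
meiosis, selection during seed production, spatial field trends beyond
block effects, interspecific introgression, and genetic correlations
between traits (multi-trait datasets draw traits independently).  Passing
tests therefore validate the estimators under the model's own assumptions,
not robustness to these departures.

## Problem sizes used by the test benchmarks

Desk-scale suites: parameter recovery uses 50 replicates of 40 parents /
100 crosses / 30 progeny (each REML fit ≈ 10,300 records, ~5 s); the null
heritability calibration uses 20 replicates at the same scale; the
cross-validation benchmarks use 20 replicates each of 40-cross and
60-cross designs in fast mode.  Smaller unit-test simulations (8–24
parents, 12–60 crosses) keep individual checks under a minute; replicate
counts for calibration/power checks (30–200) were chosen for runtime with
margins re-measured at those sizes.

## Known limitations

* σ²_H / R confounding in designs with few replicated checks (above).
* Dominance and epistasis SCA structures overlap strongly over a finite
  cross set; variance can transfer between them, so their split should be
  read cautiously (their sum is stable).
* Leave-one-out predictive abilities can go slightly negative for
  low-heritability traits — a known artefact of LOO correlation.
* Nmin treats one trait at a time; a multi-trait version would need the
  genetic correlations between traits.
* No spatial row–column residual modelling; block effects only.
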