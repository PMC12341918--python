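# triploidcross

Quantitative-genetic analysis and genomic prediction for triploid hybrids
obtained from diploid × tetraploid (2x–4x) crosses, as practised in banana
breeding: a diploid parent is crossed with a colchicine-doubled tetraploid
to produce seedless triploid progeny, and the breeder must decide which
parents to combine and how many seeds each cross should yield.

## What it computes

For a breeding population of triploid full-sib families evaluated in an
augmented block design over three crop cycles, the package fits the mixed
model

```
y_bcuvthr = μ + α_b + β_c + D_u + T_v + (D×T)_uv + H_th + e_bcuvthr
```

with fixed block (α) and crop-cycle (β) effects, random general combining
abilities of the diploid (D_u) and tetraploid (T_v) parent, a random
specific combining ability of the pair (D×T), a within-cross hybrid effect
H, and errors of the same plant correlated across cycles through an
unstructured 3×3 covariance R (e ~ N(0, R ⊗ I)).  Estimation is REML with
all components free to sit on the zero boundary.

On top of this model the package provides:

* **Ploidy-aware genomic covariances** from a parental SNP panel: the
  ploidy-general additive GRM `(A_P)ij = Σ_m (X_im − P f_m)(X_jm − P f_m) /
  (P Σ_m f_m(1−f_m))` (so A_T = 2 A_D for doubled diploids), the dominance
  regressor `Q = τ_P − (X − ξ_P)²`, its exact expectation over a cross's
  progeny under polysomic 4x inheritance, the expected inbreeding F per
  cross, the expected dominance GRM between crosses, and the
  across-population additive×additive epistasis matrix (principal submatrix
  of A_D ⊗ A_T).  The SCA term can thus be split into dominance (with mean
  −F·b) and epistasis components.
* **Broad-sense heritability** `H² = E(V_G) / (E(V_G) + E(V_Ē))` among the
  evaluated hybrids, with E(V_G) from the quadratic-form expectation per
  genetic component and `E(V_Ē) = Σ_cc' R_cc' / 9`, partitioned into 2x
  GCA, 4x GCA, SCA and within-cross shares.
* **Cross evaluation**: BLUE+BLUP clonal values and shrinkage-free
  block/cycle-corrected means, cross-specific within-cross variances
  (crosses with >15 progeny get their own parameter), Pearson genotypic
  correlations with Holm (sequential Bonferroni) correction, PCA of
  cross-mean performance, and the minimum progeny size
  `N_min = ⌈log(1−p) / log P(Y < y_ref)⌉` needed to beat a reference
  (e.g. the Cavendish check) with probability p.
* **Cross-mean prediction** for untested crosses under four leave-one-out
  schemes (2x–4x, 0–4x, 2x–0, 0–0) for the pedigree-only and four genomic
  model variants.
* **A synthetic-data generator** reproducing the whole study structure
  (doubled tetraploids, hypergeometric 4x gametes, unbalanced families,
  56-hybrid blocks with 8 controls, longitudinal errors), so every analysis
  is testable without any download.

## Worked example

`python examples/03_variance_partition.py` simulates a 30-cross study with
a 3:1 tetraploid:diploid GCA variance ratio and fits the pedigree-only
model:

```
REML variance components (truth in parentheses):
  sigma2_D   = 0.088  (0.167)
  sigma2_T   = 2.087  (1.469)
  sigma2_DT  = 0.115  (0.143)
  sigma2_H   = 0.471  (0.504)
broad-sense H2 = 0.804
contributions to H2 (sum to H2):
  gca2     0.025
  gca4     0.595
  sca      0.035
  hybrid   0.149
```

The tetraploid parent dominates the heritability, as expected when it
transmits two of the hybrid's three genomes.  Prediction of untested
crosses (`python examples/05_cross_prediction.py`) shows the matching
asymmetry between the cross-validation schemes:

```
GCA(A) scenario 2x-4x: r = 0.944 over 28 folds (2 ineligible)
GCA(A) scenario 0-4x : r = 0.871 over 29 folds (1 ineligible)
GCA(A) scenario 2x-0 : r = 0.274 over 29 folds (1 ineligible)
```

`r` is the Pearson correlation between predicted and observed cross means
over the held-out crosses: losing the 4x parent (2x–0) hurts far more than
losing the 2x parent (0–4x).

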