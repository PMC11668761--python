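# Methods

## The model

`locmorph` treats a cohort of non-linear registration outputs — per-voxel
3-D displacement fields on a common atlas grid — as a single data matrix
`X` (n subjects × p features, p = 3 × masked voxels, displacements in mm)
and builds multivariate imaging-derived phenotypes from it by *spatially
localized* principal component analysis.

Standard PCA diagonalizes the sample covariance `C = X̃ᵀX̃/(n−1)` of the
centred training data.  Its leading eigenvectors are spatially global:
distant, anatomically unrelated regions co-vary inside one component, which
makes it hard to say *which* structure an associated component describes.
The localized variant instead diagonalizes the Hadamard product

    C_loc = C ∘ K,      K_ij = exp(−‖x_i − x_j‖² / 2σ²),

where `x_i` is the mm-space location of feature i and the kernel width σ is
expressed as a **locality fraction** of the diagonal of the bounding box
around the brain mask.  The fraction sweep shipped as the default —
global, 3/4, 1/2, 1/8, 1/16, 1/64, 1/128 — spans the spectrum from
standard PCA (`GLOBAL`, fraction = ∞, K ≡ 1) to a pseudo voxel-wise
analysis.  Two properties make the manipulation well behaved:

* `K` is a Gaussian kernel matrix, hence positive semidefinite with unit
  diagonal; by the Schur product theorem `C ∘ K` is PSD, and
  `trace(C ∘ K) = trace(C)`, so "fraction of variance retained" means the
  same thing at every locality.
* The three displacement components of one voxel are co-located, so their
  pairwise weight is exactly 1 and the kernel acts at voxel resolution.

Component scores of all subjects on the training-fit model are the traits
of a per-SNP multivariate association: with a single dosage variable on one
side, canonical correlation analysis reduces to the multiple correlation of
the dosage with the trait block — `r²` is the R² of regressing centred
dosage on centred traits, Wilks' Λ = 1 − r², and
`F = ((n−k−1)/k) · r²/(1−r²)` with (k, n−k−1) degrees of freedom gives the
p-value.  Traits are first residualized against an intercept, sex, age and
the leading 10 genetic principal components.  Per-SNP **loadings** are
structure correlations (each trait against the fitted canonical variate);
components with |loading| > 0.2 (fallback 0.15 when none pass) are selected
for interpretation, sampled generatively along their axes
(`mean ± α·√λ·v`), and attributed to regions of a label atlas by ranking
per-region mean displacement magnitude.

### Assumptions

* Registration quality is uniform across the cohort; fields are finite
  displacements in mm on one grid with one mask.
* The trait block is approximately Gaussian after covariate adjustment
  (the F transform of Wilks' Λ is exact for one canonical pair under
  normality).
* Genotypes are biallelic; dosage counts the A2 allele; missingness is
  handled per SNP by complete-case analysis.
* `k` (retained components) stays well below n, otherwise the per-SNP
  F-test loses its degrees of freedom (`df2 = n − k − 1`).  This is a
  validity precondition the model reports but does not enforce.

## Numerical scheme

The p × p matrix `C ∘ K` is never formed.  Its matrix-vector product is
assembled from the training rows:

    (C ∘ K) v = (1/(n−1)) Σ_r x̃_r ∘ K(x̃_r ∘ v),

and `K` is applied at voxel resolution.  On the regular grid the Gaussian
kernel is separable (`K = Kx ⊗ Ky ⊗ Kz`), so one kernel application is
three 1-D correlations over the grid volume with explicit (unnormalized,
peak-1) Gaussian taps — O(n · N · w) per matvec instead of a sparse p × p
product.  Leading eigenpairs come from ARPACK (`eigsh`) on this operator,
requested in doubling blocks (32, 64, …) until the retained eigenvalue sum
reaches the variance target (default 90 %) of `trace(C)` or the spectrum is
exhausted; a fixed-seed start vector makes runs reproducible.

Numerical conventions:

* **Truncation.**  Kernel support is cut at 3σ per axis (configurable);
  weights beyond it are exactly 0.  The generic point-set kernel
  (`build_locality_kernel`, used for irregular feature sets and small-p
  verification) truncates radially at 3σ instead; both keep the diagonal
  exactly 1 and so preserve the trace identity.
* **Eigenvalue floor.**  Eigenvalues below 1e−12 × trace are treated as
  zero and excluded; remaining eigenvalues are clipped at 0 (the exact
  spectrum is PSD; tiny negatives can only come from truncation and
  round-off).
* **Zero-variance convention.**  If the training variance is at
  rounding-noise level relative to the data scale (≤ 1e−18 × mean square),
  the model has k = 0 components and `retained_fraction` is defined as 1.
* **Sign rule.**  Each component's largest-|entry| is made positive, ties
  broken by lowest feature index, so solver-dependent sign flips cannot
  change downstream output.
* **Feature order.**  Masked voxels are enumerated x-fastest with the three
  axis components contiguous per voxel; this order is fixed, stored in the
  model archive, and shared by cohort, kernel and reconstruction code.
* **p-value floor** 1e−300; untestable SNPs (monomorphic after
  complete-case removal, or `n_used ≤ k+1`) carry NaN p and are excluded
  from Manhattan plots but kept in the table.
* **QC order** is fixed: snps-only → mind → geno → maf → hwe, with the
  SNP-level statistics recomputed on the post-`mind` sample set, so removal
  counts are reproducible.  The HWE test is the plain (not mid-p) exact
  test, computed in log space via `gammaln`.
* **Genetic PCs** use per-SNP mean imputation, standardization by
  `2f, √(2f(1−f))` with monomorphic SNPs dropped, and a sample-space
  eigendecomposition (n × n), with the same sign rule.

## Design choices that were genuinely open

* **Traits for the scan** are the scores of *all* subjects projected onto
  the training-fit model; the held-out 20 % is used only to report
  generalization (reconstruction RMSE in the per-fraction summary).  The
  alternative — scanning training scores only — discards a fifth of the
  association sample for no variance benefit.
* **Loadings are structure correlations**, not raw canonical weights: they
  are thresholded like correlations (0.2 / 0.15) and are invariant to the
  arbitrary scaling of the score columns.
* **Recovery footprint.**  For scoring recovery of a planted effect, the
  association's spatial footprint is the canonical direction mapped back to
  feature space over the selected components, `w = Σ_sel loading_j · v_j`.
  The dose-aligned content of the selected components adds coherently in
  `w`, while each component's incidental distant lobes are mutually
  incoherent and cancel; energy fractions and region attribution computed
  on single components are noticeably noisier.
* **GLOBAL as a limit, not a branch**: fraction = ∞ gives σ = ∞ and kernel
  weight exactly 1 through the same code path, which is why the
  global-equivalence check can demand 1e−8 agreement with dense PCA.

## The synthetic cohort

The generator supplies the study conditions under which the pipeline is
validated.  A subject's field is

    field_s = Σ_m c_{s,m}·M_m  +  β·dose_s·B  +  (optional covariate terms)  +  ε_s

on an elongated ellipsoidal "brain" (28×10×10 grid, 5 mm spacing, ≈ 900
mask voxels, p ≈ 2700), with n = 300 subjects and m = 200 SNPs on 4
chromosomes by default.

* **Background modes** `M_m` (4 by default, 1 mm RMS each) are
  Gaussian-smoothed white vector fields (30 mm FWHM) modulated by a
  log-normal spatial amplitude envelope (`amplitude_heterogeneity = 1.5`,
  clipped at ±4 SD).  The envelope matters: anatomical variability is
  spatially heterogeneous, and that non-stationarity is what allows a
  distance-localized covariance to concentrate its eigenvectors — the
  localized spectrum of a *stationary* smooth field has extended,
  Fourier-like eigenvectors and a nearly flat tail, which both inflates the
  component count at 90 % retention beyond n (invalidating the CCA
  F-test) and removes any spatial contrast for localization to exploit.
* **The planted effect** `B` is a compactly supported flat-top radial
  profile (weight 1 inside half the radius, cosine-taper to 0 at the
  radius; 18 mm default radius) oriented along +x, scaled by β = 1 mm per
  A2 allele of the causal SNP (MAF 0.3, exempt from missingness so the
  effect is a deterministic function of the stored dosage).  β is twice
  the smooth-noise scale.  The flat top is deliberate: a regional effect
  displaces a subregion roughly uniformly, and it gives the effect enough
  total variance (β²·2f(1−f)·‖B‖²) to be representable by the retained
  localized components without dominating any single global component.
* **Placement** is automatic: among x-axis offsets whose support stays
  inside the mask, the bump is planted where the background modes are
  quietest.  A genotype effect inside a high-variance region is masked by
  background variability for localized and global models alike; the
  low-variability regime is precisely where localization helps, which is
  the contrast the validation is designed to exhibit.
* **Noise** ε_s is per-subject smoothed white noise (0.5 mm RMS, same FWHM
  and heterogeneity).  **Covariates**: age uniform on 108–173 months, sex
  Bernoulli(1/2); optional age/sex displacement effects for confounding
  experiments.  **Genotypes**: per-SNP frequencies uniform on the MAF
  range, Binomial(2, f) dosages, 2 % missingness, optional two-group
  Balding–Nichols structure (group labels kept in the sample table).

What the generator does **not** emulate: registration error, MRI intensity
content, scanner/site effects, LD between SNPs, relatedness, non-ellipsoid
anatomy.  Passing the validation therefore shows the pipeline recovers a
localized genetic effect under smooth, heterogeneous background variation
at desk scale — not that it would survive registration artefacts or
population LD structure on real data.

## Problem sizes

The shipped verification runs use: a 6³-grid cohort (n = 20, p ≈ 100) for
every dense-oracle check (global equivalence, trace/PSD conservation,
retention); the default 28×10×10 cohort (n = 300, m = 200) for null
calibration (k = 10 traits) and for planted-effect recovery (5 seeds ×
{global, 1/16}).  These sizes keep the full suite around two minutes on one
CPU while leaving every claimed property exercised end to end.

## Known limitations

* At very small locality fractions (1/64, 1/128) on fine grids, the 90 %
  spectrum approaches rank n and the model sets `rank_limited`; the
  per-SNP F-test then needs larger cohorts than the default synthetic one.
* The per-SNP CCA assumes the trait block is fixed across SNPs; per-SNP
  complete-case removal re-uses globally residualized traits rather than
  re-residualizing per SNP (standard practice; exact only when missingness
  is independent of covariates).
* Exact numerical parity with external multivariate-PLINK tooling is not
  claimed; the statistic is implemented natively with documented
  conventions.
* `hwe_exact` on tiny samples cannot reach small p-values (the most
  extreme configuration at n = 9 has p ≈ 0.0029), so toy examples that
  must trigger the HWE filter use a correspondingly raised threshold.
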