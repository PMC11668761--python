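# locmorph

Spatially localized morphometrics for imaging genetics: localized PCA of
deformation-field cohorts as multivariate imaging-derived phenotypes, and a
per-SNP canonical-correlation GWAS on top of them.

## The problem

Genotype–phenotype studies that use whole brain images as the phenotype
face a dilemma.  Voxel-wise testing preserves spatial detail but drowns in
multiple testing; global PCA reduces a T1-derived deformation field to a
few hundred components but mixes distant, anatomically unrelated regions
into each component, so an associated component cannot be pinned to a
structure.  `locmorph` implements the middle ground: PCA of the vectorized
displacement fields after the sample covariance `C` has been manipulated
element-wise with a distance-based Gaussian kernel,

    C_loc = C ∘ K,      K_ij = exp(−‖x_i − x_j‖² / 2σ²),

which damps correlations between spatially distant voxels and makes the
leading eigenvectors spatially compact.  The kernel width σ is a
*locality fraction* of the brain bounding-box diagonal; the default sweep
{global, 3/4, 1/2, 1/8, 1/16, 1/64, 1/128} interpolates from standard PCA
(kernel ≡ 1, recovered exactly) down to a pseudo voxel-wise analysis.
Because `K` is PSD with unit diagonal, `C ∘ K` stays PSD and keeps the
trace of `C`, so 90 %-variance retention is comparable across fractions.
`C ∘ K` is never formed: eigenpairs come from a matrix-free Lanczos solver
whose kernel application is a separable Gaussian correlation on the grid.

Component scores, residualized for sex, age and 10 genetic principal
components, are then tested per SNP by canonical correlation: with one
dosage variable, the canonical `r²` is the R² of regressing dosage on the
trait block, Wilks' Λ = 1 − r², and `F = ((n−k−1)/k)·r²/(1−r²)` gives the
p-value.  Components most correlated with a hit (|structure correlation| >
0.2, fallback 0.15) are sampled generatively (`mean ± α√λ·v`) and
attributed to atlas regions by ranked displacement magnitude.

The package is aimed at methods developers and imaging-genetics analysts:
it ships PLINK 1 binary I/O with standard QC (MAF, missingness, exact HWE),
NIfTI vector-field I/O, a synthetic-cohort generator with a planted,
dose-dependent localized effect, and a CLI chaining the stages.

## Worked example

Simulate the default synthetic cohort (n = 300 subjects on a 28×10×10
5 mm grid, m = 200 SNPs, a planted 18 mm effect at the causal SNP), run QC,
fit the 1/16-locality model and scan:

```python
from locmorph import *
from locmorph.genetics import genetic_pcs, qc_filter
from locmorph.synthdata import SimConfig, recovery_report, simulate_fields, simulate_genotypes

cfg = SimConfig(seed=2)
g = simulate_genotypes(cfg)
fields, mask, covars, truth = simulate_fields(cfg, g)
cohort = assemble_cohort(fields, mask, list(g.samples["iid"]))

g_qc, report = qc_filter(g)
res = localized_pca(cohort, mask, fraction=1 / 16, seed=2)
print(res.summary())

pcs = genetic_pcs(g_qc, n_pcs=10)
rows = [list(g.samples["iid"]).index(i) for i in g_qc.samples["iid"]]
cov = covars.iloc[rows][["sex", "age"]].astype(float)
for i in range(10):
    cov[f"gpc{i + 1}"] = pcs[:, i]
gwas = MultivariateGWAS(g_qc, res.project(cohort.X[rows]), covariates=cov).fit()
print(gwas.summary())
print(recovery_report(gwas, res, truth)["top_region"])
```

prints

```
Localized PCA results
============================================
locality fraction           0.0625
kernel sigma (mm)           8.403
subjects (train/test)       240/60
features p                  2688
components k                100
total variance              11573.7
retained fraction           0.9009
rank limited                False

Multivariate GWAS (single-SNP CCA) results
============================================
SNPs scanned                199
SNPs testable               199
traits k                    100
top SNP                     snp00000 (chr1:10000)
top SNP p                   4.493e-33
top SNP r                   0.8878

planted_effect_region
```

Reading it: one SNP failed the MAF filter during QC (199 of 200 scanned);
the 1/16-fraction model needed 100 components for 90 % of the variance
(σ = 8.4 mm — about a tenth of the 84 mm kernel scale a global model
implicitly uses); the planted causal SNP `snp00000` tops the scan at
p ≈ 4×10⁻³³ with canonical correlation 0.89; and region attribution of the
selected components' canonical direction lands on the planted effect
region.  The same cohort scanned with the `GLOBAL` model leaves the causal
SNP far from the top — the association only becomes visible once the
components are local.

The same pipeline is available from the shell:

```bash
locmorph simulate --out run/data
locmorph fit     --data run/data --out run/models
locmorph gwas    --data run/data --models run/models --out run/scan
locmorph interpret --data run/data --models run/models --scans run/scan \
                   --snp snp00000 --fraction 0p0625 --out run/interp
```

with all scientific settings (fractions, variance target, QC thresholds,
loading thresholds, significance line) in a validated YAML config; see
`locmorph.config.default_config()` for the shipped defaults.

## Layout

| Module | Contents |
| --- | --- |
| `locmorph.fieldio` | NIfTI vector fields, masks, label volumes; cohort assembly; warping; region attribution |
| `locmorph.locpca` | `LocalizedPCA` model / `LocalizedPCAResults`; locality kernels; generative sampling |
| `locmorph.genetics` | PLINK 1 binary codec, allele statistics, exact HWE test, QC, genetic PCs |
| `locmorph.mvgwas` | `MultivariateGWAS` model / `GWASResults`; residualization, per-SNP CCA, Manhattan plots |
| `locmorph.synthdata` | synthetic cohorts with planted effects; ground truth; recovery scoring |
| `locmorph.cli` | `locmorph` command: simulate / fit / gwas / interpret / recovery |
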