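"""Synthetic genotype + deformation-field cohorts with a planted effect.

The generator emulates the structure the pipeline assumes upstream of it:
smooth per-subject displacement fields on a common atlas grid with an
ellipsoidal "brain" mask, biallelic SNP genotypes, and age/sex covariates.
One SNP is causal: each copy of its A2 allele adds a fixed, compactly
supported displacement bump (a flat-top radial profile with a cosine taper,
oriented along +x) at a chosen location, so the planted genotype-phenotype
association has a known effect region, direction and size against which
recovery can be scored.

A subject's field is

    field_s = sum_m  c_{s,m} * M_m                (shared smooth background modes)
            + beta * dose_s(causal) * B           (planted localized effect)
            + covariate terms (optional)
            + noise_s                             (smooth per-subject noise)

where the background modes M_m and the noise are Gaussian-smoothed white
vector noise with a configurable FWHM, scaled to a root-mean-square
displacement over the mask.  Everything is a deterministic function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ValidationError
from .fieldio import BrainMask, Cohort, LabelVolume, VectorField, magnitude_map, region_attribution, vector_to_field
from .genetics import MISSING, GenotypeMatrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_fields",
    "effect_label_volume",
    "recovery_report",
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Geometry defaults describe a desk-scale analogue of an atlas brain: an
    elongated ellipsoidal mask in a 28x10x10 grid at 5 mm spacing (~900
    voxels, p ~ 2700 features), with four smooth shared background modes
    (1 mm RMS each, 30 mm FWHM, spatially heterogeneous amplitude) plus
    smooth per-subject noise.  The causal effect is an 18 mm-radius
    flat-top bump along +x, placed in a low-background-variability site,
    with beta = 1 mm/allele -- twice the smooth-noise scale (0.5 mm RMS) --
    at a causal minor-allele frequency of 0.3.
    """

    n: int = 300
    m: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    grid: tuple[int, int, int] = (28, 10, 10)
    spacing: tuple[float, float, float] = (5.0, 5.0, 5.0)
    causal_snp_index: int | None = 0
    causal_maf: float = 0.3
    effect_center: tuple[int, int, int] | None = None   # voxel triple; None = auto
    effect_radius_mm: float | None = None               # None = 0.9 * min mask semi-extent
    effect_beta: float = 1.0                            # mm displacement per A2 allele
    smooth_noise_scale_mm: float = 0.5                  # RMS over mask
    smoothness_fwhm_mm: float = 30.0
    n_background_modes: int = 4
    background_scale_mm: float = 1.0                    # RMS per mode over mask
    amplitude_heterogeneity: float = 1.5                # log-normal spatial variance contrast
    population_structure: float | None = None           # Fst-like divergence
    covariate_effects: dict[str, float] | None = None   # {"age": mm/SD, "sex": mm}
    n_chromosomes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.causal_snp_index is not None and not 0 <= self.causal_snp_index < self.m:
            raise ValidationError(
                f"causal_snp_index {self.causal_snp_index} out of range for m={self.m}"
            )
        for name in ("missing_rate",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError(f"maf_range must be within (0, 0.5], got {self.maf_range}")
        if self.effect_radius_mm is not None and self.effect_radius_mm <= 0:
            raise ValidationError("effect_radius_mm must be > 0")


@dataclass
class GroundTruth:
    """Ledger of the planted effect for recovery scoring."""

    causal_id: str | None
    region_mask: np.ndarray            # boolean volume: bump support
    beta: float
    effect_center_vox: tuple[int, int, int] | None
    effect_radius_mm: float
    direction: tuple[float, float, float]
    per_subject_effect: np.ndarray     # beta * causal dosage, length n
    groups: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject": np.arange(self.per_subject_effect.size),
            "effect_mm": self.per_subject_effect,
            "group": self.groups if self.groups is not None else 0,
        })


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Binomial dosages with per-SNP frequencies drawn from ``maf_range``.

    Optional two-group structure perturbs per-group frequencies with a
    Balding-Nichols model at divergence ``cfg.population_structure``; group
    labels are stored in the ``group`` column of the sample frame.  The
    causal SNP's frequency is pinned at ``cfg.causal_maf`` and it is exempt
    from missingness (its dosage drives the planted field effect).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA]))
    f = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.m)
    if cfg.causal_snp_index is not None:
        f[cfg.causal_snp_index] = cfg.causal_maf
    groups = None
    if cfg.population_structure:
        fst = float(cfg.population_structure)
        groups = (np.arange(cfg.n) % 2).astype(int)
        rng.shuffle(groups)
        a = f * (1.0 - fst) / fst
        b = (1.0 - f) * (1.0 - fst) / fst
        fg = np.stack([np.clip(rng.beta(a, b), 0.01, 0.99) for _ in range(2)])
        freq = fg[groups]                      # (n, m)
        dosage = rng.binomial(2, freq).astype(np.int8)
    else:
        dosage = rng.binomial(2, f[None, :].repeat(cfg.n, axis=0)).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random((cfg.n, cfg.m)) < cfg.missing_rate
        if cfg.causal_snp_index is not None:
            miss[:, cfg.causal_snp_index] = False
        dosage[miss] = MISSING
    chrom = 1 + (np.arange(cfg.m) * cfg.n_chromosomes) // max(cfg.m, 1)
    snps = pd.DataFrame({
        "chrom": chrom.astype(str),
        "id": [f"snp{j:05d}" for j in range(cfg.m)],
        "cm": 0.0,
        "pos": 10_000 + 1_000 * np.arange(cfg.m),
        "a1": "A",
        "a2": "G",
    })
    samples = pd.DataFrame({
        "fid": [f"F{i:05d}" for i in range(cfg.n)],
        "iid": [f"S{i:05d}" for i in range(cfg.n)],
        "father": "0",
        "mother": "0",
        "sex": 0,
        "phenotype": -9,
    })
    if groups is not None:
        samples["group"] = groups
    return GenotypeMatrix(dosage=dosage, snps=snps, samples=samples)


# ---------------------------------------------------------------------------
# Fields
# ---------------------------------------------------------------------------

def _ellipsoid_mask(grid: Sequence[int], spacing: Sequence[float]) -> BrainMask:
    dims = tuple(int(d) for d in grid)
    center = (np.asarray(dims) - 1) / 2.0
    semi = np.maximum((np.asarray(dims) - 1) / 2.0 - 0.5, 0.75)
    idx = np.indices(dims)
    r2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return BrainMask(voxels=r2 <= 1.0, spacing=tuple(float(s) for s in spacing))


def _wendland_bump(grid, spacing, center_vox, radius_mm) -> np.ndarray:
    """Unit-height flat-top radial profile with a smooth cosine taper.

    Weight 1 inside half the radius, falling as cos^2 to exactly 0 at the
    radius (compact support).  A plateau rather than a peak: the planted
    effect displaces a whole subregion roughly uniformly, as a regional
    volume change would, instead of a single-voxel spike.
    """
    idx = np.indices(grid).astype(float)
    mm = [idx[a] * spacing[a] for a in range(3)]
    c = [center_vox[a] * spacing[a] for a in range(3)]
    rho = np.sqrt(sum((mm[a] - c[a]) ** 2 for a in range(3))) / radius_mm
    w = np.where(rho <= 0.5, 1.0,
                 np.where(rho < 1.0, np.cos(np.pi * (rho - 0.5)) ** 2, 0.0))
    return w


def _smooth_unit_field(rng, grid, spacing, fwhm_mm, mask_vox,
                       heterogeneity: float = 0.0) -> np.ndarray:
    """Gaussian-smoothed white vector noise, RMS-normalized over the mask.

    ``heterogeneity > 0`` modulates the field with a log-normal smooth
    amplitude envelope, exp(h * g) with g a unit-variance smooth scalar
    field, so variance differs across space the way anatomical variability
    does (some structures vary much more than others).  This spatial
    non-stationarity is what lets a distance-localized model concentrate
    components; a stationary field has extended, Fourier-like eigenvectors.
    """
    sigma_vox = [fwhm_mm / 2.354820045 / s for s in spacing]
    field = rng.standard_normal(tuple(grid) + (3,))
    for a in range(3):
        field[..., a] = ndimage.gaussian_filter(field[..., a], sigma=sigma_vox)
    if heterogeneity > 0:
        env = ndimage.gaussian_filter(rng.standard_normal(tuple(grid)), sigma=sigma_vox)
        sd = env[mask_vox].std()
        # clip keeps the amplitude contrast bounded (and guards tiny grids,
        # where heavy smoothing leaves an almost-constant envelope)
        env = np.clip(env / sd, -4.0, 4.0) if sd > 1e-12 else np.zeros_like(env)
        field *= np.exp(heterogeneity * env)[..., None]
    rms = np.sqrt((field[mask_vox] ** 2).mean())
    return field / rms if rms > 0 else field


def simulate_fields(
    cfg: SimConfig,
    g: GenotypeMatrix,
) -> tuple[list[VectorField], BrainMask, pd.DataFrame, GroundTruth]:
    """Generate the deformation-field cohort matching a genotype matrix.

    Returns per-subject fields, the brain mask, the covariate table (age in
    months, sex coded 0/1) and the ground-truth ledger.
    """
    if g.n != cfg.n:
        raise ValidationError(f"genotypes have n={g.n} but config n={cfg.n}")
    grid, spacing = cfg.grid, cfg.spacing
    mask = _ellipsoid_mask(grid, spacing)
    center = (np.asarray(grid) - 1) / 2.0
    semi_mm = np.maximum((np.asarray(grid) - 1) / 2.0 - 0.5, 0.75) * np.asarray(spacing)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xB]))
    background_modes = [
        _smooth_unit_field(rng, grid, spacing, cfg.smoothness_fwhm_mm, mask.voxels,
                           heterogeneity=cfg.amplitude_heterogeneity)
        for _ in range(cfg.n_background_modes)
    ]

    radius = cfg.effect_radius_mm if cfg.effect_radius_mm is not None else 0.9 * semi_mm.min()
    if cfg.effect_center is not None:
        center_vox = tuple(int(c) for c in cfg.effect_center)
        bump_w = _wendland_bump(grid, spacing, center_vox, radius)
        region = bump_w > 0.0
    else:
        # Auto placement along the x axis: among offsets whose support stays
        # inside the mask, pick the site where the shared background modes
        # are quietest -- a genotype effect in a low-variability region is
        # the regime in which spatial localization helps most, while an
        # effect inside a high-variance region is masked by background
        # variability for localized and global models alike.  If no offset
        # fits (tiny grids), the radius shrinks until one does.
        candidates: list[tuple[float, tuple[int, int, int], np.ndarray, np.ndarray]] = []
        while not candidates and radius >= spacing[0] / 2:
            x_lo = -int(semi_mm[0] / spacing[0]) - 1
            x_hi = int(semi_mm[0] / spacing[0]) + 1
            for shift_vox in range(x_lo, x_hi + 1):
                cand = (int(round(center[0])) + shift_vox,
                        int(round(center[1])), int(round(center[2])))
                if not 0 <= cand[0] < grid[0]:
                    continue
                bump_cand = _wendland_bump(grid, spacing, cand, radius)
                region_cand = bump_cand > 0.0
                if mask.voxels[cand] and not (region_cand & ~mask.voxels).any():
                    mode_energy = sum(
                        float((m[region_cand] ** 2).sum()) for m in background_modes
                    )
                    candidates.append((mode_energy, cand, bump_cand, region_cand))
            if not candidates:
                radius *= 0.8
        if not candidates:
            raise ValidationError(
                "could not place the effect bump inside the mask; grid too small"
            )
        _, center_vox, bump_w, region = min(candidates, key=lambda t: (t[0], t[1]))
    if not mask.voxels[tuple(center_vox)]:
        raise ValidationError(f"effect centre {center_vox} lies outside the brain mask")
    if (region & ~mask.voxels).any():
        raise ValidationError(
            "effect region extends outside the brain mask; shrink effect_radius_mm "
            "or move effect_center"
        )
    bump = np.zeros(tuple(grid) + (3,))
    bump[..., 0] = bump_w                      # displacement along +x

    modes = background_modes
    coeffs = rng.standard_normal((cfg.n, cfg.n_background_modes))

    age = rng.uniform(108.0, 173.0, size=cfg.n)      # months
    sex = rng.integers(0, 2, size=cfg.n)             # 0 female, 1 male
    cov_fields = {}
    if cfg.covariate_effects:
        for name in cfg.covariate_effects:
            if name not in ("age", "sex"):
                raise ValidationError(f"unknown covariate effect {name!r}")
            cov_fields[name] = _smooth_unit_field(
                rng, grid, spacing, cfg.smoothness_fwhm_mm, mask.voxels
            )

    if cfg.causal_snp_index is not None:
        dose = g.dosage[:, cfg.causal_snp_index].astype(float)
        dose = np.where(dose == MISSING, np.nan, dose)
        if np.isnan(dose).any():
            raise ValidationError("causal SNP has missing dosages; cannot plant effect")
        causal_id = str(g.snps["id"].iloc[cfg.causal_snp_index])
    else:
        dose = np.zeros(cfg.n)
        causal_id = None

    age_z = (age - age.mean()) / age.std() if cfg.n > 1 and age.std() > 0 else np.zeros(cfg.n)
    fields = []
    for s in range(cfg.n):
        data = np.zeros(tuple(grid) + (3,))
        for m_i, mode in enumerate(modes):
            data += cfg.background_scale_mm * coeffs[s, m_i] * mode
        data += cfg.effect_beta * dose[s] * bump
        if cfg.covariate_effects:
            if "age" in cov_fields:
                data += cfg.covariate_effects["age"] * age_z[s] * cov_fields["age"]
            if "sex" in cov_fields:
                data += cfg.covariate_effects["sex"] * float(sex[s]) * cov_fields["sex"]
        if cfg.smooth_noise_scale_mm > 0:
            data += cfg.smooth_noise_scale_mm * _smooth_unit_field(
                rng, grid, spacing, cfg.smoothness_fwhm_mm, mask.voxels,
                heterogeneity=cfg.amplitude_heterogeneity,
            )
        data[~mask.voxels] = 0.0
        fields.append(VectorField(data=data, spacing=mask.spacing))

    covars = pd.DataFrame({"age": age, "sex": sex.astype(int)},
                          index=[str(i) for i in g.samples["iid"]])
    truth = GroundTruth(
        causal_id=causal_id,
        region_mask=region,
        beta=float(cfg.effect_beta),
        effect_center_vox=center_vox,
        effect_radius_mm=float(radius),
        direction=(1.0, 0.0, 0.0),
        per_subject_effect=cfg.effect_beta * dose,
        groups=g.samples["group"].to_numpy() if "group" in g.samples else None,
    )
    return fields, mask, covars, truth


def effect_label_volume(mask: BrainMask, truth: GroundTruth) -> LabelVolume:
    """Label atlas for attribution: effect region = label 1, octants 2..9 elsewhere."""
    labels = np.zeros(mask.dims, dtype=np.int32)
    center = (np.asarray(mask.dims) - 1) / 2.0
    idx = np.indices(mask.dims)
    octant = (
        (idx[0] > center[0]).astype(int)
        + 2 * (idx[1] > center[1]).astype(int)
        + 4 * (idx[2] > center[2]).astype(int)
    )
    labels[mask.voxels] = 2 + octant[mask.voxels]
    labels[truth.region_mask] = 1
    names = {1: "planted_effect_region"}
    names.update({i: f"octant_{i - 2}" for i in range(2, 10)})
    return LabelVolume(labels=labels, spacing=mask.spacing, names=names)


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def component_energy_in_region(
    component: np.ndarray,
    cohort: Cohort,
    region_mask: np.ndarray,
) -> float:
    """Fraction of a component vector's squared energy inside a voxel region."""
    component = np.asarray(component, dtype=float).ravel()
    vox = cohort.voxel_index
    inside = region_mask[vox[:, 0], vox[:, 1], vox[:, 2]]
    per_feature = np.repeat(inside, 3)
    total = float(component @ component)
    if total == 0:
        return 0.0
    return float(component[per_feature] @ component[per_feature]) / total


def recovery_report(
    gwas_results,
    pca_results,
    truth: GroundTruth,
    atlas: LabelVolume | None = None,
) -> dict:
    """Score pipeline output against the planted ground truth.

    Reports the causal SNP's rank and p-value in the scan, the selected
    component's squared-energy fraction inside the true effect region, and
    whether region attribution of that component's magnitude map ranks the
    planted region first.
    """
    if truth.causal_id is None:
        raise ValidationError("ground truth has no causal SNP")
    cohort = pca_results.model.cohort
    if atlas is None:
        atlas = effect_label_volume(pca_results.model.mask, truth)
    rank = gwas_results.rank_of(truth.causal_id)
    row = gwas_results.table[gwas_results.table["id"] == truth.causal_id].iloc[0]
    loadings = gwas_results.loadings_for(truth.causal_id)
    selected = select_components_or_top(loadings)
    top_comp = max(selected, key=lambda i: abs(loadings[i]))
    # The association's spatial footprint is the canonical direction mapped
    # back to feature space over the selected components.  Their shared
    # (dose-aligned) content adds coherently there, while each component's
    # incidental distant lobes are mutually incoherent and average out.
    sel = sorted(selected)
    direction = pca_results.components[:, sel] @ loadings[sel]
    energy = component_energy_in_region(direction, cohort, truth.region_mask)
    mag = magnitude_map(vector_to_field(direction, cohort))
    ranking = region_attribution(mag, atlas, stat="mean")
    return {
        "causal_id": truth.causal_id,
        "causal_rank": rank,
        "causal_p": float(row["p"]),
        "selected_components": sel,
        "top_component": int(top_comp),
        "energy_in_region": energy,
        "top_region": ranking[0][0],
        "top_region_is_planted": ranking[0][0] == "planted_effect_region",
        "region_ranking": ranking[:3],
    }


def select_components_or_top(loadings: np.ndarray) -> set[int]:
    """Thresholded component selection, falling back to the argmax |loading|."""
    from .mvgwas import select_components

    sel = select_components(loadings)
    if not sel:
        sel = {int(np.argmax(np.abs(loadings)))}
    return sel
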