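"""PLINK 1 binary genotypes, per-SNP statistics, QC, and genetic PCs.

Genotypes are held as an ``n x m`` dosage matrix counting copies of the A2
allele (the second allele column of the .bim file), with missing calls
encoded by the sentinel :data:`MISSING` (-1).  The .bed codec follows the
PLINK 1 binary layout: magic bytes 0x6C 0x1B, mode byte 0x01 (SNP-major),
then ceil(n/4) bytes per variant, two bits per sample from the least
significant pair upward (00 = hom A1, 01 = missing, 10 = het, 11 = hom A2),
with zero padding bits in the last byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .exceptions import FormatError, ValidationError

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "QCThresholds",
    "QCReport",
    "AlleleStats",
    "read_plink",
    "write_plink",
    "allele_stats",
    "hwe_exact",
    "qc_filter",
    "genetic_pcs",
]

MISSING: int = -1

_BIM_COLS = ["chrom", "id", "cm", "pos", "a1", "a2"]
_FAM_COLS = ["fid", "iid", "father", "mother", "sex", "phenotype"]

# 2-bit code -> A2 dosage (code 1 is missing)
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 0, MISSING: 1, 1: 2, 2: 3}

# byte -> 4 dosages, least significant bit pair first
_BYTE_TABLE = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _s in range(4):
        _BYTE_TABLE[_b, _s] = _CODE_TO_DOSAGE[(_b >> (2 * _s)) & 0b11]


@dataclass
class GenotypeMatrix:
    """Biallelic dosages (A2-allele counts) plus SNP and sample metadata."""

    dosage: np.ndarray          # (n, m) int8 with values {0, 1, 2, MISSING}
    snps: pd.DataFrame          # columns chrom, id, cm, pos, a1, a2
    samples: pd.DataFrame       # columns fid, iid, father, mother, sex, phenotype

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValidationError(f"dosage must be 2-D, got shape {self.dosage.shape}")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValidationError("dosage contains symbols outside {0, 1, 2, MISSING}")
        if len(self.snps) != self.m:
            raise ValidationError(
                f"{self.m} dosage columns but {len(self.snps)} SNP metadata rows"
            )
        if len(self.samples) != self.n:
            raise ValidationError(
                f"{self.n} dosage rows but {len(self.samples)} sample metadata rows"
            )

    @property
    def n(self) -> int:
        return self.dosage.shape[0]

    @property
    def m(self) -> int:
        return self.dosage.shape[1]

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage[idx],
            snps=self.snps,
            samples=self.samples.iloc[idx].reset_index(drop=True),
        )

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage[:, idx],
            snps=self.snps.iloc[idx].reset_index(drop=True),
            samples=self.samples,
        )


@dataclass
class QCThresholds:
    """Quality-control cut-offs (PLINK-style flags)."""

    maf_min: float = 0.05
    geno_max: float = 0.1
    mind_max: float = 0.1
    hwe_p_min: float = 0.001
    snps_only: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_min", "geno_max", "mind_max", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    """Per-step removal counts, in application order."""

    steps: list[tuple[str, str, int]] = dc_field(default_factory=list)
    n_in: int = 0
    m_in: int = 0
    n_out: int = 0
    m_out: int = 0
    empty: bool = False

    def removed(self, step: str) -> int:
        for name, _axis, count in self.steps:
            if name == step:
                return count
        raise KeyError(step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "axis", "removed"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class AlleleStats(NamedTuple):
    maf: float
    call_rate: float
    n0: int
    n1: int
    n2: int
    a2_freq: float


# ---------------------------------------------------------------------------
# PLINK binary I/O
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a .bed/.bim/.fam triplet (SNP-major PLINK 1 binary)."""
    prefix = Path(prefix)
    bed, bim, fam = (Path(f"{prefix}{s}") for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FormatError(f"missing PLINK file: {f}")
    snps = pd.read_csv(bim, sep=r"\s+", header=None, names=_BIM_COLS,
                       dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    samples = pd.read_csv(fam, sep=r"\s+", header=None, names=_FAM_COLS,
                          dtype={"fid": str, "iid": str})
    n, m = len(samples), len(snps)
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw.size < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise FormatError(f"{bed}: bad magic bytes (expected 0x6C 0x1B)")
    if raw[2] != 0x01:
        raise FormatError(f"{bed}: mode byte {raw[2]:#x} is not SNP-major (0x01)")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != m * bytes_per_snp:
        raise FormatError(
            f"{bed}: {body.size} data bytes, expected {m} variants x "
            f"{bytes_per_snp} bytes for {n} samples"
        )
    if m == 0:
        dosage = np.empty((n, 0), dtype=np.int8)
    else:
        decoded = _BYTE_TABLE[body.reshape(m, bytes_per_snp)]
        dosage = decoded.reshape(m, 4 * bytes_per_snp)[:, :n].T.copy()
    return GenotypeMatrix(dosage=dosage, snps=snps, samples=samples)


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a .bed/.bim/.fam triplet; exact inverse of :func:`read_plink`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = g.n, g.m
    bytes_per_snp = (n + 3) // 4
    codes = np.zeros((m, 4 * bytes_per_snp), dtype=np.uint8)
    dos = g.dosage.T  # (m, n)
    for sym, code in _DOSAGE_TO_CODE.items():
        codes[:, :n][dos == sym] = code
    packed = (
        codes[:, 0::4]
        | (codes[:, 1::4] << 2)
        | (codes[:, 2::4] << 4)
        | (codes[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))
        fh.write(packed.tobytes())
    g.snps[_BIM_COLS].to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    g.samples[_FAM_COLS].to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Per-SNP statistics
# ---------------------------------------------------------------------------

def allele_stats(g: GenotypeMatrix, j: int) -> AlleleStats:
    """MAF, call rate and genotype counts for SNP ``j`` (complete-case)."""
    if not 0 <= j < g.m:
        raise ValidationError(f"SNP index {j} out of range for m={g.m}")
    col = g.dosage[:, j]
    obs = col[col != MISSING]
    n0 = int((obs == 0).sum())
    n1 = int((obs == 1).sum())
    n2 = int((obs == 2).sum())
    call_rate = obs.size / col.size if col.size else 0.0
    if obs.size == 0:
        return AlleleStats(maf=np.nan, call_rate=0.0, n0=0, n1=0, n2=0, a2_freq=np.nan)
    freq = (n1 + 2 * n2) / (2 * obs.size)
    return AlleleStats(
        maf=float(min(freq, 1.0 - freq)),
        call_rate=float(call_rate),
        n0=n0, n1=n1, n2=n2,
        a2_freq=float(freq),
    )


def hwe_exact(n0: int, n1: int, n2: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value from genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    every attainable heterozygote count whose conditional probability does
    not exceed that of the observed count.  Computed in log space.
    """
    if min(n0, n1, n2) < 0:
        raise ValidationError(f"genotype counts must be >= 0, got ({n0}, {n1}, {n2})")
    n = n0 + n1 + n2
    if n < 1:
        raise ValidationError("total genotype count must be >= 1")
    na = n1 + 2 * min(n0, n2)          # rare-allele count (conditioning statistic)
    nb = 2 * n - na
    # attainable heterozygote counts share the parity of na and satisfy h <= na
    hs = np.arange(na % 2, na + 1, 2)
    # log P(h) = log n! - log naa! - log h! - log nbb! + log na! + log nb! - log (2n)! + h log 2
    naa = (na - hs) // 2
    nbb = (nb - hs) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(naa + 1) - gammaln(hs + 1) - gammaln(nbb + 1)
        + gammaln(na + 1) + gammaln(nb + 1) - gammaln(2 * n + 1)
        + hs * np.log(2.0)
    )
    logp_obs = logp[hs == n1][0]
    p = float(np.exp(logp[logp <= logp_obs + 1e-9]).sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_filter(g: GenotypeMatrix, t: QCThresholds | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the fixed QC sequence: snps-only, mind, geno, maf, hwe.

    Missingness, frequency and HWE statistics for the SNP-level filters are
    recomputed on the post-``mind`` sample set.  SNPs with an undefined MAF
    (all calls missing) fail the MAF filter.
    """
    if t is None:
        t = QCThresholds()
    report = QCReport(n_in=g.n, m_in=g.m)

    # 1. snps-only: drop variants with any multi-character allele code
    if t.snps_only:
        keep = np.array([
            len(str(a1)) == 1 and len(str(a2)) == 1
            for a1, a2 in zip(g.snps["a1"], g.snps["a2"])
        ])
    else:
        keep = np.ones(g.m, dtype=bool)
    report.steps.append(("snps_only", "snp", int((~keep).sum())))
    g = g.take_snps(np.flatnonzero(keep))

    # 2. mind: drop samples with too much missingness
    if g.m > 0:
        miss_frac = (g.dosage == MISSING).mean(axis=1)
    else:
        miss_frac = np.zeros(g.n)
    keep_s = miss_frac <= t.mind_max
    report.steps.append(("mind", "sample", int((~keep_s).sum())))
    g = g.take_samples(np.flatnonzero(keep_s))

    # 3. geno: per-SNP missingness on the surviving samples
    if g.n > 0:
        miss_frac = (g.dosage == MISSING).mean(axis=0)
    else:
        miss_frac = np.ones(g.m)
    keep = miss_frac <= t.geno_max
    report.steps.append(("geno", "snp", int((~keep).sum())))
    g = g.take_snps(np.flatnonzero(keep))

    # 4. maf
    stats = [allele_stats(g, j) for j in range(g.m)]
    keep = np.array([
        (not np.isnan(s.maf)) and s.maf >= t.maf_min for s in stats
    ]) if g.m else np.zeros(0, dtype=bool)
    report.steps.append(("maf", "snp", int((~keep).sum()) if g.m else 0))
    kept_stats = [s for s, k in zip(stats, keep) if k]
    g = g.take_snps(np.flatnonzero(keep))

    # 5. hwe exact test
    keep = np.array([
        hwe_exact(s.n0, s.n1, s.n2) >= t.hwe_p_min for s in kept_stats
    ]) if g.m else np.zeros(0, dtype=bool)
    report.steps.append(("hwe", "snp", int((~keep).sum()) if g.m else 0))
    g = g.take_snps(np.flatnonzero(keep))

    report.n_out, report.m_out = g.n, g.m
    report.empty = g.n == 0 or g.m == 0
    return g, report


# ---------------------------------------------------------------------------
# Genetic principal components
# ---------------------------------------------------------------------------

def _sign_fix(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (ties: lowest index)."""
    out = vectors.copy()
    for c in range(out.shape[1]):
        col = out[:, c]
        idx = int(np.argmax(np.abs(col)))  # argmax returns the first maximum
        if col[idx] < 0:
            out[:, c] = -col
    return out


def genetic_pcs(g: GenotypeMatrix, n_pcs: int = 10) -> np.ndarray:
    """Leading sample-space principal components of standardized genotypes.

    Missing dosages are mean-imputed per SNP; columns are centred at ``2f``
    and scaled by ``sqrt(2 f (1 - f))`` with monomorphic SNPs dropped.
    Returns an ``(n, n_pcs)`` matrix of orthonormal score vectors used as
    population-stratification covariates.
    """
    if n_pcs >= min(g.n, g.m):
        raise ValidationError(
            f"n_pcs={n_pcs} must be < min(n, m) = {min(g.n, g.m)}"
        )
    D = g.dosage.astype(float)
    D[D == MISSING] = np.nan
    f = np.nanmean(D, axis=0) / 2.0
    poly = np.isfinite(f) & (f > 0.0) & (f < 1.0)
    if poly.sum() < n_pcs + 1:
        raise ValidationError(
            f"only {int(poly.sum())} polymorphic SNPs; cannot compute {n_pcs} PCs"
        )
    D = D[:, poly]
    f = f[poly]
    mean = 2.0 * f
    scale = np.sqrt(2.0 * f * (1.0 - f))
    inds = np.where(np.isnan(D))
    D[inds] = mean[inds[1]]
    Z = (D - mean) / scale
    gram = Z @ Z.T
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1][:n_pcs]
    scores = vecs[:, order]
    return _sign_fix(scores)
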