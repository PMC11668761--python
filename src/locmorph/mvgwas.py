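"""Multivariate genome-wide association of component scores via CCA.

Each SNP's dosage (one predictor) is tested against the block of localized
PCA component scores (the multivariate imaging-derived phenotype).  With a
single variable on one side, canonical correlation analysis reduces to the
multiple correlation of the dosage with the trait block: ``r^2`` is the R²
of the least-squares regression of centred dosage on centred traits,
Wilks' lambda is ``1 - r^2``, and

    F = ((n - k - 1) / k) * r^2 / (1 - r^2),   df1 = k,  df2 = n - k - 1,

gives the exact test under normality.  Component *loadings* are structure
correlations: the Pearson correlation of each trait with the fitted
canonical variate, thresholded (|loading| > 0.2, falling back to 0.15) to
select the components driving an association.

Scores are adjusted for covariates (sex, age, leading genetic PCs) by
least-squares residualization before scanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ShapeError, ValidationError
from .genetics import MISSING, GenotypeMatrix

__all__ = [
    "SNPAssociation",
    "residualize",
    "cca_snp",
    "gwas_scan",
    "select_components",
    "manhattan_table",
    "manhattan_plot",
    "MultivariateGWAS",
    "GWASResults",
]

P_FLOOR = 1e-300

_TABLE_COLS = ["chrom", "pos", "id", "n_used", "r", "wilks", "F", "df1", "df2", "p"]


@dataclass
class SNPAssociation:
    """Per-SNP canonical-correlation association result."""

    id: str
    chrom: str
    pos: int
    n_used: int
    r: float
    wilks: float
    F: float
    df1: int
    df2: int
    p: float
    loadings: np.ndarray
    testable: bool = True


def _design_matrix(covars: pd.DataFrame) -> np.ndarray:
    D = np.column_stack([np.ones(len(covars)), covars.to_numpy(dtype=float)])
    if not np.all(np.isfinite(D)):
        raise ValidationError("covariate table contains missing/non-finite values")
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # identify offending columns by incremental rank
        names, bad = ["intercept", *covars.columns], []
        for c in range(1, D.shape[1]):
            if np.linalg.matrix_rank(D[:, : c + 1]) == np.linalg.matrix_rank(D[:, :c]):
                bad.append(names[c])
        raise ValidationError(f"design matrix is rank deficient; collinear columns: {bad}")
    return D


def residualize(scores: np.ndarray | pd.DataFrame, covars: pd.DataFrame) -> np.ndarray:
    """Replace each trait by its least-squares residual against [1, covariates].

    Residuals are exactly uncorrelated with every covariate column (and have
    zero mean, because of the intercept).
    """
    Y = scores.to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(scores, dtype=float)
    Y = np.atleast_2d(Y.T).T if Y.ndim == 1 else Y
    if Y.shape[0] != len(covars):
        raise ShapeError(
            f"{Y.shape[0]} score rows but {len(covars)} covariate rows"
        )
    D = _design_matrix(covars)
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    return Y - D @ beta


def cca_snp(
    dosage: np.ndarray,
    traits: np.ndarray,
    snp_id: str = "snp",
    chrom: str = "0",
    pos: int = 0,
) -> SNPAssociation:
    """Single-SNP canonical correlation against a trait block.

    Missing dosages (:data:`locmorph.genetics.MISSING` or NaN) are dropped
    per SNP (complete-case).  SNPs that are monomorphic after complete-case
    removal, or with too few observations (``n_used <= k + 1``), are marked
    untestable (``p`` = NaN).
    """
    dosage = np.asarray(dosage, dtype=float).ravel()
    traits = np.asarray(traits, dtype=float)
    if traits.ndim != 2 or traits.shape[0] != dosage.size:
        raise ShapeError(
            f"traits shape {traits.shape} incompatible with dosage length {dosage.size}"
        )
    k = traits.shape[1]
    obs = np.isfinite(dosage) & (dosage != MISSING)
    d = dosage[obs]
    T = traits[obs]
    n_used = int(d.size)

    def _untestable() -> SNPAssociation:
        return SNPAssociation(
            id=snp_id, chrom=str(chrom), pos=int(pos), n_used=n_used,
            r=np.nan, wilks=np.nan, F=np.nan, df1=k, df2=max(n_used - k - 1, 0),
            p=np.nan, loadings=np.full(k, np.nan), testable=False,
        )

    if n_used <= k + 1:
        return _untestable()
    d = d - d.mean()
    ss_d = float(d @ d)
    if ss_d <= 0.0:
        return _untestable()
    Tc = T - T.mean(axis=0)
    if np.any(Tc.std(axis=0) == 0):
        raise ValidationError("trait block contains a constant column")
    Q, _ = np.linalg.qr(Tc)
    proj = Q.T @ d
    r2 = float(proj @ proj) / ss_d
    r2 = min(max(r2, 0.0), 1.0)
    df1, df2 = k, n_used - k - 1
    if r2 >= 1.0:
        F = np.inf
        p = P_FLOOR
    else:
        F = (df2 / df1) * r2 / (1.0 - r2)
        p = max(float(stats.f.sf(F, df1, df2)), P_FLOOR)
    variate = Q @ proj  # fitted canonical variate on the traits side
    v_sd = variate.std()
    if v_sd > 0:
        vz = (variate - variate.mean()) / v_sd
        tz = Tc / Tc.std(axis=0)
        loadings = (tz * vz[:, None]).mean(axis=0)
    else:
        loadings = np.zeros(k)
    return SNPAssociation(
        id=snp_id, chrom=str(chrom), pos=int(pos), n_used=n_used,
        r=float(np.sqrt(r2)), wilks=float(1.0 - r2), F=float(F),
        df1=df1, df2=df2, p=p, loadings=loadings, testable=True,
    )


def _chrom_key(c: str):
    c = str(c)
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


def gwas_scan(
    g: GenotypeMatrix,
    traits: np.ndarray,
    progress: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-SNP CCA over a genotype matrix.

    Returns the association table (sorted by chromosome then position) and
    the matched ``(m, k)`` loadings matrix.  Untestable SNPs carry NaN
    statistics but remain in the table for bookkeeping.
    """
    traits = np.asarray(traits, dtype=float)
    if traits.shape[0] != g.n:
        raise ShapeError(f"{g.n} samples but {traits.shape[0]} trait rows")
    rows, loadings = [], []
    for j in range(g.m):
        meta = g.snps.iloc[j]
        assoc = cca_snp(
            g.dosage[:, j], traits,
            snp_id=str(meta["id"]), chrom=str(meta["chrom"]), pos=int(meta["pos"]),
        )
        rows.append([assoc.chrom, assoc.pos, assoc.id, assoc.n_used, assoc.r,
                     assoc.wilks, assoc.F, assoc.df1, assoc.df2, assoc.p])
        loadings.append(assoc.loadings)
    table = pd.DataFrame(rows, columns=_TABLE_COLS)
    loadings = np.asarray(loadings) if loadings else np.empty((0, traits.shape[1]))
    order = sorted(range(len(table)),
                   key=lambda i: (_chrom_key(table["chrom"].iloc[i]), table["pos"].iloc[i]))
    table = table.iloc[order].reset_index(drop=True)
    loadings = loadings[order]
    if table["id"].duplicated().any():
        raise ValidationError("duplicate SNP ids in scan output")
    return table, loadings


def select_components(
    loadings: np.ndarray,
    primary_threshold: float = 0.2,
    fallback_threshold: float = 0.15,
) -> set[int]:
    """Indices with |loading| > 0.2; if none, fall back to |loading| > 0.15."""
    loadings = np.asarray(loadings, dtype=float)
    sel = set(np.flatnonzero(np.abs(loadings) > primary_threshold).tolist())
    if not sel:
        sel = set(np.flatnonzero(np.abs(loadings) > fallback_threshold).tolist())
    return sel


def manhattan_table(table: pd.DataFrame, significance_line: float = 1e-8) -> pd.DataFrame:
    """Plot-ready table: -log10(p) and a cumulative genome coordinate."""
    if len(table) == 0:
        raise ValidationError("empty GWAS table")
    t = table[np.isfinite(table["p"])].copy()
    t["neglog10p"] = -np.log10(t["p"].clip(lower=P_FLOOR))
    t = t.iloc[sorted(range(len(t)),
                      key=lambda i: (_chrom_key(t["chrom"].iloc[i]), t["pos"].iloc[i]))]
    t = t.reset_index(drop=True)
    offset, cum = 0.0, np.empty(len(t))
    for chrom in t["chrom"].unique():
        sel = t["chrom"] == chrom
        pos = t.loc[sel, "pos"].to_numpy(dtype=float)
        cum[sel.to_numpy()] = offset + pos
        offset += pos.max() + 1.0
    t["cum_pos"] = cum
    t.attrs["significance_line"] = significance_line
    return t


def manhattan_plot(
    table: pd.DataFrame,
    path: str | Path,
    significance_line: float = 1e-8,
    title: str | None = None,
) -> pd.DataFrame:
    """Write a Manhattan plot image; returns the plot-ready table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = manhattan_table(table, significance_line)
    fig, ax = plt.subplots(figsize=(9, 3.2))
    for i, chrom in enumerate(t["chrom"].unique()):
        sel = t["chrom"] == chrom
        ax.scatter(t.loc[sel, "cum_pos"], t.loc[sel, "neglog10p"],
                   s=8, color=f"C{i % 2}", label=None)
    ax.axhline(-np.log10(significance_line), color="red", lw=0.8, ls="--")
    ax.set_xlabel("genome position")
    ax.set_ylabel(r"$-\log_{10} p$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return t


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class MultivariateGWAS:
    """Per-SNP multivariate association model.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        Post-QC genotypes.
    scores : ndarray (n, k)
        Component scores (imaging-derived phenotypes), one row per sample,
        aligned with ``genotypes.samples``.
    covariates : DataFrame, optional
        Per-sample covariates (e.g. age, sex, genetic PCs); if given, scores
        are residualized against ``[1, covariates]`` before scanning.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        scores: np.ndarray,
        covariates: pd.DataFrame | None = None,
    ):
        scores = np.asarray(scores, dtype=float)
        if scores.ndim != 2 or scores.shape[0] != genotypes.n:
            raise ShapeError(
                f"scores shape {scores.shape} incompatible with n={genotypes.n}"
            )
        self.genotypes = genotypes
        self.raw_scores = scores
        self.covariates = covariates

    def fit(self) -> "GWASResults":
        traits = (
            residualize(self.raw_scores, self.covariates)
            if self.covariates is not None
            else self.raw_scores
        )
        table, loadings = gwas_scan(self.genotypes, traits)
        return GWASResults(model=self, table=table, loadings=loadings, traits=traits)


@dataclass
class GWASResults:
    """Scan output: association table plus per-SNP component loadings."""

    model: MultivariateGWAS
    table: pd.DataFrame
    loadings: np.ndarray
    traits: np.ndarray
    _index: dict = dc_field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {sid: i for i, sid in enumerate(self.table["id"])}

    @property
    def n_testable(self) -> int:
        return int(np.isfinite(self.table["p"]).sum())

    def loadings_for(self, snp_id: str) -> np.ndarray:
        if snp_id not in self._index:
            raise KeyError(f"SNP {snp_id!r} not in scan results")
        return self.loadings[self._index[snp_id]]

    def select_components(self, snp_id: str,
                          primary_threshold: float = 0.2,
                          fallback_threshold: float = 0.15) -> set[int]:
        return select_components(self.loadings_for(snp_id),
                                 primary_threshold, fallback_threshold)

    def top_snp(self) -> pd.Series:
        """Minimum-p SNP; ties broken by genome order (table is genome-sorted)."""
        p = self.table["p"].to_numpy()
        if not np.isfinite(p).any():
            raise ValidationError("no testable SNPs in scan")
        return self.table.iloc[int(np.nanargmin(p))]

    def rank_of(self, snp_id: str) -> int:
        """1-based rank of a SNP by ascending p among testable SNPs."""
        t = self.table[np.isfinite(self.table["p"])].reset_index(drop=True)
        if snp_id not in set(t["id"]):
            raise KeyError(f"SNP {snp_id!r} not testable")
        order = t.sort_values(["p", "chrom", "pos"], kind="stable")
        return int(np.flatnonzero(order["id"].to_numpy() == snp_id)[0]) + 1

    def manhattan(self, path: str | Path | None = None,
                  significance_line: float = 1e-8,
                  title: str | None = None) -> pd.DataFrame:
        if path is None:
            return manhattan_table(self.table, significance_line)
        return manhattan_plot(self.table, path, significance_line, title)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        top = self.top_snp()
        lines = [
            "Multivariate GWAS (single-SNP CCA) results",
            "=" * 44,
            f"{'SNPs scanned':<28}{len(self.table)}",
            f"{'SNPs testable':<28}{self.n_testable}",
            f"{'traits k':<28}{self.traits.shape[1]}",
            f"{'top SNP':<28}{top['id']} (chr{top['chrom']}:{top['pos']})",
            f"{'top SNP p':<28}{top['p']:.3e}",
            f"{'top SNP r':<28}{top['r']:.4f}",
        ]
        return "\n".join(lines)
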