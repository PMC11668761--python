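"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately written in the most direct way possible
(dense linear algebra, explicit loops, exact rational arithmetic) and
shares no code with the implementation paths it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def dense_pca(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full eigendecomposition of the sample covariance of rows of X.

    Returns (mean, eigenvalues descending, eigenvectors as columns).
    """
    mean = X.mean(axis=0)
    Xc = X - mean
    C = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    return mean, vals[order], vecs[:, order]


def dense_localized_spectrum(X: np.ndarray, locations: np.ndarray,
                             sigma_mm: float) -> np.ndarray:
    """Eigenvalues (descending) of C ∘ K with the exact Gaussian kernel."""
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (X.shape[0] - 1)
    d2 = ((locations[:, None, :] - locations[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2.0 * sigma_mm ** 2)) if np.isfinite(sigma_mm) else np.ones_like(d2)
    return np.linalg.eigvalsh(C * K)[::-1]


def principal_angles(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Principal angles (radians) between the column spans of A and B."""
    Qa, _ = np.linalg.qr(A)
    Qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return np.arccos(np.clip(s, -1.0, 1.0))


def hwe_exact_fraction(n0: int, n1: int, n2: int) -> float:
    """Exact-rational two-sided HWE test by explicit enumeration.

    Enumerates every heterozygote count attainable given the observed
    allele counts, computes each conditional probability as a Fraction,
    and sums those with probability <= the observed configuration's.
    """
    n = n0 + n1 + n2
    na = n1 + 2 * min(n0, n2)       # rare allele count
    nb = 2 * n - na

    def prob(h: int) -> Fraction:
        naa = (na - h) // 2
        nbb = (nb - h) // 2
        # multinomial genotype count over multivariate hypergeometric alleles
        num = Fraction(
            comb(n, naa) * comb(n - naa, h) * (2 ** h)
        )
        den = Fraction(comb(2 * n, na))
        return num / den

    hs = list(range(na % 2, na + 1, 2))
    probs = {h: prob(h) for h in hs}
    assert sum(probs.values()) == 1
    p_obs = probs[n1]
    return float(sum(p for p in probs.values() if p <= p_obs))


def trilinear_sample(image: np.ndarray, x: float, y: float, z: float) -> float:
    """Single-point trilinear interpolation with zero padding, by hand."""
    out = 0.0
    x0, y0, z0 = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
    fx, fy, fz = x - x0, y - y0, z - z0
    for dx, wx in ((0, 1 - fx), (1, fx)):
        for dy, wy in ((0, 1 - fy), (1, fy)):
            for dz, wz in ((0, 1 - fz), (1, fz)):
                xi, yi, zi = x0 + dx, y0 + dy, z0 + dz
                if (0 <= xi < image.shape[0] and 0 <= yi < image.shape[1]
                        and 0 <= zi < image.shape[2]):
                    out += wx * wy * wz * image[xi, yi, zi]
    return out


def hat_matrix_residuals(Y: np.ndarray, D: np.ndarray) -> np.ndarray:
    """(I - H) Y with the explicit hat matrix H = D (D'D)^-1 D'."""
    H = D @ np.linalg.inv(D.T @ D) @ D.T
    return Y - H @ Y


def multiple_regression_r2(y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of y on [1, X] via the normal equations."""
    D = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(D.T @ D, D.T @ y)
    resid = y - D @ beta
    yc = y - y.mean()
    return 1.0 - float(resid @ resid) / float(yc @ yc)
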