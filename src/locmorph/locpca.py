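"""Spatially localized PCA of deformation-field cohorts.

Standard PCA of a vectorized deformation-field cohort diagonalizes the
sample covariance ``C`` and yields spatially global components: distant,
anatomically unrelated regions co-vary in a single component, which makes
region-level interpretation hard.  The localized variant instead
diagonalizes the Hadamard (element-wise) product ``C ∘ K``, where ``K`` is a
Gaussian distance kernel over feature locations,

    K[i, j] = exp(-||x_i - x_j||^2 / (2 sigma^2)),

so correlations between spatially distant features are damped and the
leading eigenvectors concentrate on compact regions.  The kernel width is
parameterized as a *locality fraction* of the diagonal of the bounding box
around the brain mask; ``GLOBAL`` (fraction = inf) gives ``K ≡ 1`` and
recovers standard PCA exactly.  Because ``K`` is positive semidefinite with
unit diagonal, the Schur product theorem guarantees ``C ∘ K`` is PSD, and
``trace(C ∘ K) = trace(C)`` so retained-variance fractions remain
comparable across localities.

``C ∘ K`` is never materialized densely.  Its matrix-vector product is
assembled from the training rows:

    (C ∘ K) v = (1 / (n - 1)) * sum_r  x_r ∘ (K (x_r ∘ v)),

with ``K`` applied at voxel resolution (the three displacement components
of one voxel are co-located, so their pairwise kernel weight is 1) — as a
separable truncated Gaussian correlation on the regular grid, or through a
truncated sparse kernel for generic point sets.  Leading eigenpairs are
extracted with an iterative Lanczos solver in adaptively doubling blocks
until the configured variance fraction (default 90 %) of ``trace(C)`` is
retained.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import LinearOperator, eigsh
from scipy.spatial import cKDTree

from .exceptions import ShapeError, ValidationError
from .fieldio import BrainMask, Cohort, VectorField, bounding_box_diagonal, vector_to_field

__all__ = [
    "GLOBAL",
    "LocalityParameter",
    "LocalityKernel",
    "gaussian_locality_weight",
    "build_locality_kernel",
    "LocalizedPCA",
    "LocalizedPCAResults",
    "localized_pca",
]

#: Symbolic locality fraction for standard (non-localized) PCA.
GLOBAL: float = math.inf

_EIGVAL_FLOOR_REL = 1e-12    # eigenvalues below this fraction of trace are dropped
_SCHEMA_VERSION = "locmorph-model-1"


@dataclass(frozen=True)
class LocalityParameter:
    """Kernel width: a fraction of the mask bounding-box diagonal.

    ``fraction = GLOBAL`` (infinity) means no localization (kernel weight 1
    for every pair of locations).
    """

    fraction: float
    sigma_mm: float
    truncation_radius_mm: float

    @classmethod
    def from_fraction(
        cls,
        fraction: float,
        diagonal_mm: float,
        truncation_sigma_mult: float = 3.0,
    ) -> "LocalityParameter":
        if not (fraction > 0):
            raise ValidationError(f"locality fraction must be > 0, got {fraction}")
        sigma = fraction * diagonal_mm
        if not math.isinf(fraction) and sigma <= 0:
            raise ValidationError(
                f"sigma = fraction * diagonal = {sigma} must be > 0"
            )
        return cls(
            fraction=float(fraction),
            sigma_mm=float(sigma),
            truncation_radius_mm=float(truncation_sigma_mult * sigma),
        )

    @property
    def is_global(self) -> bool:
        return math.isinf(self.fraction) or math.isinf(self.sigma_mm)


def gaussian_locality_weight(d, sigma_mm: float):
    """Gaussian kernel weight ``exp(-d^2 / (2 sigma^2))`` for distance d (mm).

    ``sigma_mm = inf`` (GLOBAL) returns 1 for every distance.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValidationError("distances must be >= 0")
    if math.isinf(sigma_mm):
        out = np.ones_like(d)
    else:
        if sigma_mm <= 0:
            raise ValidationError(f"sigma_mm must be > 0, got {sigma_mm}")
        out = np.exp(-(d ** 2) / (2.0 * sigma_mm ** 2))
    return float(out) if out.ndim == 0 else out


class LocalityKernel:
    """Sparse symmetric Gaussian weight structure over feature locations.

    Features sharing a location (the three components of one voxel) are
    grouped, and the kernel is stored at unique-location resolution; weights
    beyond the truncation radius are exactly 0, the diagonal is exactly 1.
    """

    def __init__(self, locations: np.ndarray, param: LocalityParameter):
        locations = np.asarray(locations, dtype=float)
        if locations.ndim != 2 or locations.shape[1] != 3:
            raise ShapeError(f"locations must be (p, 3), got {locations.shape}")
        self.param = param
        self.p = locations.shape[0]
        uniq, inverse = np.unique(locations, axis=0, return_inverse=True)
        self._inverse = inverse.ravel()
        self._n_uniq = uniq.shape[0]
        # p x n_uniq indicator used to pool features sharing a voxel
        self._pool = sparse.csr_matrix(
            (np.ones(self.p), (np.arange(self.p), self._inverse)),
            shape=(self.p, self._n_uniq),
        )
        if param.is_global:
            self.voxel_weights = None
        else:
            tree = cKDTree(uniq)
            coo = tree.sparse_distance_matrix(
                tree, param.truncation_radius_mm, output_type="coo_matrix"
            )
            w = gaussian_locality_weight(coo.data, param.sigma_mm)
            K = sparse.coo_matrix((w, (coo.row, coo.col)), shape=coo.shape).tocsr()
            K.setdiag(1.0)  # exact unit diagonal
            self.voxel_weights = K

    def matvec(self, u: np.ndarray) -> np.ndarray:
        """Apply the p x p feature-level kernel to a vector."""
        u = np.asarray(u, dtype=float).ravel()
        if u.size != self.p:
            raise ShapeError(f"vector length {u.size} != p {self.p}")
        s = self._pool.T @ u
        w = np.full(self._n_uniq, s.sum()) if self.voxel_weights is None else self.voxel_weights @ s
        return w[self._inverse]

    def matmat(self, U: np.ndarray) -> np.ndarray:
        """Apply the kernel to the rows of an (r, p) matrix."""
        S = U @ self._pool  # (r, n_uniq)
        if self.voxel_weights is None:
            W = np.repeat(S.sum(axis=1)[:, None], self._n_uniq, axis=1)
        else:
            W = (self.voxel_weights @ S.T).T
        return W[:, self._inverse]

    def dense(self) -> np.ndarray:
        """Dense p x p kernel matrix (small problems / tests only)."""
        if self.voxel_weights is None:
            return np.ones((self.p, self.p))
        Kv = np.asarray(self.voxel_weights.todense())
        return Kv[np.ix_(self._inverse, self._inverse)]


def build_locality_kernel(
    locations: np.ndarray,
    param: LocalityParameter,
) -> LocalityKernel:
    """Construct the truncated sparse locality kernel for feature locations."""
    return LocalityKernel(locations, param)


class GridLocalityKernel:
    """Separable Gaussian kernel over masked voxels of a regular grid.

    On a regular grid the Gaussian kernel factorizes over axes,
    ``K = Kx ⊗ Ky ⊗ Kz``, so applying it is three 1-D correlations over the
    full grid (zeros outside the mask) instead of a sparse p x p product.
    Truncation is per axis at ``truncate * sigma`` (a box support with exact
    Gaussian weights inside, rather than the radial cut of
    :class:`LocalityKernel`); the diagonal weight is exactly 1.
    """

    def __init__(
        self,
        dims: tuple[int, int, int],
        spacing: tuple[float, float, float],
        voxel_index: np.ndarray,
        sigma_mm: float,
        truncate: float = 3.0,
    ):
        if not (sigma_mm > 0) or math.isinf(sigma_mm):
            raise ValidationError(f"grid kernel needs finite sigma > 0, got {sigma_mm}")
        self.dims = tuple(int(d) for d in dims)
        self.voxel_index = np.asarray(voxel_index)
        self.weights = []
        for a in range(3):
            h = float(spacing[a])
            r = int(truncate * sigma_mm / h + 0.5)
            offs = np.arange(-r, r + 1) * h
            self.weights.append(np.exp(-(offs ** 2) / (2.0 * sigma_mm ** 2)))

    def apply_voxel(self, S: np.ndarray) -> np.ndarray:
        """Apply the kernel to per-voxel values; rows of S are independent."""
        S = np.atleast_2d(S)
        n = S.shape[0]
        vi, vj, vk = self.voxel_index.T
        vol = np.zeros((n,) + self.dims)
        vol[:, vi, vj, vk] = S
        for a in range(3):
            vol = ndimage.correlate1d(vol, self.weights[a], axis=a + 1,
                                      mode="constant", cval=0.0)
        return vol[:, vi, vj, vk]

    def dense_voxel(self) -> np.ndarray:
        """Dense voxel-level kernel matrix (tests / small grids only)."""
        vox = self.voxel_index
        nv = vox.shape[0]
        K = np.ones((nv, nv))
        for a in range(3):
            w = self.weights[a]
            r = (w.size - 1) // 2
            delta = vox[:, a][:, None] - vox[:, a][None, :]
            wa = np.zeros_like(K)
            inside = np.abs(delta) <= r
            wa[inside] = w[delta[inside] + r]
            K *= wa
        return K


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class LocalizedPCA:
    """Localized PCA model of a deformation-field cohort.

    Parameters
    ----------
    cohort : Cohort
        Vectorized masked fields (n subjects x p features).
    mask : BrainMask, optional
        Defaults to ``cohort.mask``; defines the bounding-box diagonal that
        scales the locality fraction into a kernel width in mm.
    fraction : float
        Locality fraction; ``GLOBAL`` reproduces standard PCA.
    variance_target : float
        Fraction of total variance to retain (default 0.90).
    train_fraction : float
        Fraction of subjects used to fit the model (default 0.80); the
        held-out remainder is used only to report generalization.
    truncation_sigma_mult : float
        Kernel support cut-off in units of sigma (default 3).
    seed : int
        Seed for the train/test split and the eigensolver start vector.
    """

    def __init__(
        self,
        cohort: Cohort,
        mask: BrainMask | None = None,
        fraction: float = GLOBAL,
        variance_target: float = 0.9,
        train_fraction: float = 0.8,
        truncation_sigma_mult: float = 3.0,
        seed: int = 0,
    ):
        if cohort.n < 2:
            raise ValidationError(f"need n >= 2 subjects, got {cohort.n}")
        if not 0.0 < variance_target <= 1.0:
            raise ValidationError(f"variance_target must be in (0, 1], got {variance_target}")
        if not 0.0 < train_fraction <= 1.0:
            raise ValidationError(f"train_fraction must be in (0, 1], got {train_fraction}")
        self.cohort = cohort
        self.mask = mask if mask is not None else cohort.mask
        self.diagonal_mm = bounding_box_diagonal(self.mask)
        self.param = LocalityParameter.from_fraction(
            fraction, self.diagonal_mm, truncation_sigma_mult
        )
        self.variance_target = float(variance_target)
        self.train_fraction = float(train_fraction)
        self.seed = int(seed)

    # -- internals ----------------------------------------------------------

    def _split(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.cohort.n
        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(n)
        n_train = max(2, int(round(self.train_fraction * n)))
        n_train = min(n_train, n)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])

    def _cov_operator(self, Xc: np.ndarray) -> LinearOperator:
        """Matrix-free (C ∘ K) v assembled from the training rows.

        The three features of a voxel are co-located (kernel weight 1), so
        the kernel acts at voxel resolution on pooled per-voxel sums; on the
        regular grid it is applied as a separable Gaussian correlation.
        """
        n_train, p = Xc.shape
        denom = n_train - 1
        n_vox = p // 3
        cohort = self.cohort
        if self.param.is_global:
            kernel = None
        else:
            kernel = GridLocalityKernel(
                cohort.mask.dims, cohort.mask.spacing, cohort.voxel_index,
                self.param.sigma_mm,
                truncate=self.param.truncation_radius_mm / self.param.sigma_mm,
            )
        X3 = Xc.reshape(n_train, n_vox, 3)

        def matvec(v: np.ndarray) -> np.ndarray:
            v = np.asarray(v, dtype=float).ravel()
            Y = (Xc * v).reshape(n_train, n_vox, 3).sum(axis=2)  # pooled x_r ∘ v
            if kernel is None:
                W = np.repeat(Y.sum(axis=1)[:, None], n_vox, axis=1)
            else:
                W = kernel.apply_voxel(Y)
            return np.einsum("rva,rv->va", X3, W).ravel() / denom

        return LinearOperator((p, p), matvec=matvec, dtype=float)

    def fit(self) -> "LocalizedPCAResults":
        """Estimate mean, components and eigenvalues; return a results object."""
        cohort = self.cohort
        train_idx, test_idx = self._split()
        X_train = cohort.X[train_idx]
        n_train = X_train.shape[0]
        p = cohort.p
        mean = X_train.mean(axis=0)
        Xc = X_train - mean
        total_variance = float((Xc ** 2).sum() / (n_train - 1))
        # variance at rounding-noise level counts as zero (identical subjects)
        data_scale = float((X_train ** 2).mean())
        degenerate = total_variance <= max(data_scale, 1.0) * 1e-18

        if degenerate or p == 0:
            total_variance = 0.0
            # all training subjects identical: zero-variance convention
            components = np.zeros((p, 0))
            eigenvalues = np.zeros(0)
            retained = 1.0
            rank_limited = False
        else:
            op = self._cov_operator(Xc)
            floor = _EIGVAL_FLOOR_REL * total_variance
            target = self.variance_target * total_variance
            rng = np.random.default_rng(self.seed + 1)
            v0 = rng.standard_normal(p)
            k_req = min(32, p - 1)
            vals = vecs = None
            rank_limited = False
            while True:
                vals, vecs = eigsh(op, k=k_req, which="LA", v0=v0,
                                   ncv=min(p, max(2 * k_req + 1, 32)))
                order = np.argsort(vals)[::-1]
                vals, vecs = vals[order], vecs[:, order]
                keep = vals > floor
                if (not keep.all()) or np.cumsum(vals[keep])[-1] >= target:
                    # spectrum exhausted below the floor, or target met
                    break
                if k_req >= p - 1:
                    rank_limited = True
                    break
                k_req = min(2 * k_req, p - 1)
            vals = np.clip(vals, 0.0, None)
            keep = vals > floor
            vals, vecs = vals[keep], vecs[:, keep]
            cum = np.cumsum(vals)
            if cum.size and cum[-1] >= target:
                k = int(np.searchsorted(cum, target) + 1)
            else:
                k = vals.size
                rank_limited = True
            eigenvalues = vals[:k]
            components = _orthonormal_sign_fixed(vecs[:, :k])
            retained = float(eigenvalues.sum() / total_variance)

        res = LocalizedPCAResults(
            model=self,
            mean=mean,
            components=components,
            eigenvalues=eigenvalues,
            total_variance=total_variance,
            retained_fraction=retained,
            rank_limited=rank_limited,
            n_train=n_train,
            train_idx=train_idx,
            test_idx=test_idx,
        )
        return res


def _orthonormal_sign_fixed(vecs: np.ndarray) -> np.ndarray:
    """Re-orthonormalize (QR) and apply the deterministic sign convention.

    Each component's largest-absolute entry is made positive; ties are
    broken by the lowest feature index (numpy argmax takes the first max).
    """
    if vecs.shape[1] == 0:
        return vecs
    q, r = np.linalg.qr(vecs)
    # keep the original column directions (QR may flip signs)
    q = q * np.sign(np.diag(r))[None, :]
    for c in range(q.shape[1]):
        col = q[:, c]
        idx = int(np.argmax(np.abs(col)))
        if col[idx] < 0:
            q[:, c] = -col
    return q


class LocalizedPCAResults:
    """Fitted localized PCA: mean, orthonormal components, eigenvalues.

    Component scores for the full cohort (training-fit model applied to all
    subjects) are in ``scores``; ``scores_train`` / ``scores_test`` hold the
    80/20 partitions.
    """

    def __init__(
        self,
        model: LocalizedPCA,
        mean: np.ndarray,
        components: np.ndarray,
        eigenvalues: np.ndarray,
        total_variance: float,
        retained_fraction: float,
        rank_limited: bool,
        n_train: int,
        train_idx: np.ndarray,
        test_idx: np.ndarray,
    ):
        self.model = model
        self.mean = mean
        self.components = components
        self.eigenvalues = eigenvalues
        self.total_variance = total_variance
        self.retained_fraction = retained_fraction
        self.rank_limited = rank_limited
        self.n_train = n_train
        self.train_idx = train_idx
        self.test_idx = test_idx

    # -- basic properties ---------------------------------------------------

    @property
    def k(self) -> int:
        return self.components.shape[1]

    @property
    def fraction(self) -> float:
        return self.model.param.fraction

    @property
    def sigma_mm(self) -> float:
        return self.model.param.sigma_mm

    @property
    def scores(self) -> np.ndarray:
        """Scores of every cohort subject on the training-fit model."""
        return self.project(self.model.cohort.X)

    @property
    def scores_train(self) -> np.ndarray:
        return self.project(self.model.cohort.X[self.train_idx])

    @property
    def scores_test(self) -> np.ndarray:
        return self.project(self.model.cohort.X[self.test_idx])

    # -- projection / reconstruction ---------------------------------------

    def project(self, X: np.ndarray) -> np.ndarray:
        """Orthogonal projection of (rows of) X onto the component basis."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.mean.size:
            raise ShapeError(
                f"feature count {X.shape[1]} != model p {self.mean.size}"
            )
        scores = (X - self.mean) @ self.components
        return scores[0] if single else scores

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """Map scores back to feature space: mean + components @ scores."""
        scores = np.asarray(scores, dtype=float)
        single = scores.ndim == 1
        scores = np.atleast_2d(scores)
        if scores.shape[1] != self.k:
            raise ShapeError(f"score length {scores.shape[1]} != k {self.k}")
        out = self.mean + scores @ self.components.T
        return out[0] if single else out

    def sample_component(self, component_index: int, alpha: float) -> VectorField:
        """Generative sample at ``alpha`` standard deviations along one component.

        Returns the field ``mean + alpha * sqrt(lambda_i) * v_i`` reshaped to
        the atlas grid (zeros outside the mask).
        """
        if not 0 <= component_index < self.k:
            raise ValidationError(
                f"component index {component_index} out of range for k={self.k}"
            )
        scores = np.zeros(self.k)
        scores[component_index] = alpha * math.sqrt(self.eigenvalues[component_index])
        return vector_to_field(self.reconstruct(scores), self.model.cohort)

    def mean_field(self) -> VectorField:
        return vector_to_field(self.mean, self.model.cohort)

    def component_field(self, component_index: int) -> VectorField:
        """The unit component vector itself on the atlas grid (for attribution)."""
        if not 0 <= component_index < self.k:
            raise ValidationError(
                f"component index {component_index} out of range for k={self.k}"
            )
        return vector_to_field(self.components[:, component_index], self.model.cohort)

    def reconstruction_error(self, X: np.ndarray | None = None) -> float:
        """Root-mean-square residual after project/reconstruct (held-out by default)."""
        if X is None:
            X = self.model.cohort.X[self.test_idx]
            if X.shape[0] == 0:
                X = self.model.cohort.X[self.train_idx]
        X = np.atleast_2d(np.asarray(X, dtype=float))
        resid = X - self.reconstruct(self.project(X))
        return float(np.sqrt((resid ** 2).mean()))

    # -- reporting / persistence -------------------------------------------

    def summary(self) -> str:
        frac = "global" if self.model.param.is_global else f"{self.fraction:g}"
        lines = [
            "Localized PCA results",
            "=" * 44,
            f"{'locality fraction':<28}{frac}",
            f"{'kernel sigma (mm)':<28}{self.sigma_mm:.4g}",
            f"{'subjects (train/test)':<28}{self.n_train}/{len(self.test_idx)}",
            f"{'features p':<28}{self.mean.size}",
            f"{'components k':<28}{self.k}",
            f"{'total variance':<28}{self.total_variance:.6g}",
            f"{'retained fraction':<28}{self.retained_fraction:.4f}",
            f"{'rank limited':<28}{self.rank_limited}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize the fitted model to a single .npz archive."""
        meta = {
            "schema": _SCHEMA_VERSION,
            "fraction": "inf" if math.isinf(self.fraction) else self.fraction,
            "sigma_mm": "inf" if math.isinf(self.sigma_mm) else self.sigma_mm,
            "truncation_radius_mm": (
                "inf" if math.isinf(self.model.param.truncation_radius_mm)
                else self.model.param.truncation_radius_mm
            ),
            "variance_target": self.model.variance_target,
            "train_fraction": self.model.train_fraction,
            "seed": self.model.seed,
            "total_variance": self.total_variance,
            "retained_fraction": self.retained_fraction,
            "rank_limited": self.rank_limited,
            "n_train": self.n_train,
            "feature_order": "x-fastest, 3 components per voxel contiguous",
            "spacing": list(self.model.mask.spacing),
            "subject_ids": list(self.model.cohort.subject_ids),
        }
        np.savez_compressed(
            path,
            meta=json.dumps(meta),
            mean=self.mean,
            components=self.components,
            eigenvalues=self.eigenvalues,
            mask=self.model.mask.voxels,
            train_idx=self.train_idx,
            test_idx=self.test_idx,
        )

    @staticmethod
    def load_arrays(path) -> dict:
        """Load a saved model archive into a plain dict (arrays + meta)."""
        with np.load(path, allow_pickle=False) as z:
            out = {k: z[k] for k in z.files if k != "meta"}
            out["meta"] = json.loads(str(z["meta"]))
        if out["meta"].get("schema") != _SCHEMA_VERSION:
            raise ValidationError(
                f"unsupported model schema: {out['meta'].get('schema')!r}"
            )
        return out


def localized_pca(
    cohort: Cohort,
    mask: BrainMask | None = None,
    fraction: float = GLOBAL,
    variance_target: float = 0.9,
    split: float = 0.8,
    truncation_sigma_mult: float = 3.0,
    seed: int = 0,
) -> LocalizedPCAResults:
    """Fit a localized PCA model; convenience wrapper over :class:`LocalizedPCA`."""
    return LocalizedPCA(
        cohort,
        mask=mask,
        fraction=fraction,
        variance_target=variance_target,
        train_fraction=split,
        truncation_sigma_mult=truncation_sigma_mult,
        seed=seed,
    ).fit()
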