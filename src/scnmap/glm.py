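"""Voxelwise covariance GLM and max-statistic permutation FWE control.

The core model regresses every voxel's gray-matter value on a per-subject
seed covariate (plus nuisance columns), yielding a t map for the seed
coefficient.  Family-wise error over voxels is controlled by the
permutation distribution of the map-wide maximum t (height) and, at a
primary cluster-forming threshold, of the maximum cluster size (extent).

Permutation scheme (Freedman–Lane style): the effect column is
residualized on the nuisance columns, its entries are permuted, the result
is re-residualized, and the contrast t is recomputed against the
nuisance-residualized data via the Frisch–Waugh–Lovell identity.  This
keeps nuisance structure (intercept, gender, group main effects) intact
under the null while breaking the seed–voxel association.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .errors import DegenerateDesignError, GeometryError
from .morphometry import GMImage
from .seeds import SeedVector

__all__ = [
    "DesignMatrix",
    "VoxelGLMResult",
    "FWEResult",
    "build_covariance_design",
    "fit_voxelwise_glm",
    "permutation_fwe",
    "threshold_map",
    "compute_gm_mask",
    "stack_images",
    "connectivity_structure",
]

_SIGMA2_TOL = 1e-12  # below this, residual variance counts as exactly zero


@dataclass
class DesignMatrix:
    """Named regressors for the voxelwise GLM.

    ``columns`` names the regressors in order; ``values`` is the
    n_subjects × p array; ``contrasts`` maps a contrast name to its vector.
    The matrix must be full column rank with an all-ones intercept first.
    """

    columns: list[str]
    values: np.ndarray
    contrasts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise DegenerateDesignError("values shape does not match column names")
        if not np.allclose(self.values[:, 0], 1.0):
            raise DegenerateDesignError("first column must be the all-ones intercept")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise DegenerateDesignError(
                "design matrix is rank deficient; drop constant or collinear "
                f"columns (columns: {self.columns})"
            )
        self.contrasts = {
            k: np.asarray(v, dtype=np.float64) for k, v in self.contrasts.items()
        }

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def contrast(self, name: str) -> np.ndarray:
        if name not in self.contrasts:
            raise KeyError(f"unknown contrast {name!r}; have {list(self.contrasts)}")
        return self.contrasts[name]


@dataclass
class VoxelGLMResult:
    """Per-voxel GLM output on the image grid.

    ``beta`` has shape (p,) + grid; ``sigma2`` is RSS/(n-p); ``tmap`` is
    c'β̂ / sqrt(σ̂²·c'(X'X)⁻¹c), NaN where the residual variance is zero
    (an exactly-fit voxel has no defined t) or outside the analysis mask.
    """

    beta: np.ndarray
    sigma2: np.ndarray
    tmap: np.ndarray
    df: int
    contrast_name: str
    affine: np.ndarray
    mask: np.ndarray  # analysis mask actually used


@dataclass
class FWEResult:
    """Permutation FWE thresholds for one contrast.

    ``height_threshold`` is the ceil((1-alpha)(n_perm+1))-th order statistic
    of the max-t null distribution (observed statistic included);
    ``extent_threshold`` the same order statistic of the max cluster size at
    the primary ``cluster_forming_p`` threshold.
    """

    alpha: float
    height_threshold: float
    cluster_forming_p: float
    cluster_forming_t: float
    extent_threshold: int
    n_perm: int
    rng_seed: int
    null_max_t: np.ndarray
    null_max_cluster: np.ndarray
    connectivity: int = 18


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D binary structure for 6- (face), 18- (face+edge) or 26-connectivity."""
    try:
        order = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError(
            f"connectivity must be one of 6, 18, 26; got {connectivity}"
        ) from None
    return ndimage.generate_binary_structure(3, order)


def stack_images(images: list[GMImage]) -> tuple[np.ndarray, np.ndarray]:
    """Stack cohort images into an (n_subjects, n_voxels) matrix.

    All images must share one grid and affine; returns (Y, affine).
    """
    if not images:
        raise ValueError("no images given")
    shape, affine = images[0].shape, images[0].affine
    for img in images[1:]:
        if img.shape != shape:
            raise GeometryError("images do not share one grid shape")
        if not np.allclose(img.affine, affine, atol=1e-6):
            raise GeometryError("images do not share one affine")
    Y = np.stack([img.data.reshape(-1) for img in images], axis=0)
    return Y, affine


def compute_gm_mask(images: list[GMImage], threshold: float = 0.1) -> np.ndarray:
    """Implicit analysis mask: voxels whose mean GM across subjects exceeds
    ``threshold`` (the usual VBM in-brain restriction)."""
    Y, _ = stack_images(images)
    return (Y.mean(axis=0) > threshold).reshape(images[0].shape)


def build_covariance_design(seed: SeedVector | np.ndarray, gender) -> DesignMatrix:
    """Design for the single-group covariance model Y ~ 1 + seed + gender.

    The seed regressor is mean-centered (leaves its t unchanged, stabilizes
    the intercept).  Contrast ``"seed+"`` tests positive seed covariance.
    """
    s = np.asarray(seed.values if isinstance(seed, SeedVector) else seed, dtype=float)
    g = np.asarray(gender, dtype=np.float64)
    if s.shape != g.shape or s.ndim != 1:
        raise ValueError("seed and gender must be 1D arrays of equal length")
    if np.ptp(s) == 0:
        raise DegenerateDesignError("seed covariate is constant")
    X = np.column_stack([np.ones(len(s)), s - s.mean(), g])
    return DesignMatrix(
        columns=["intercept", "seed", "gender"],
        values=X,
        contrasts={"seed+": np.array([0.0, 1.0, 0.0])},
    )


def _fit_stacked(Y: np.ndarray, X: np.ndarray, c: np.ndarray):
    """OLS of every column of Y on X; returns beta (p,V), sigma2 (V,), t (V,), df."""
    n, p = X.shape
    if n <= p:
        raise DegenerateDesignError(
            f"insufficient degrees of freedom: n={n} subjects, p={p} regressors"
        )
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    df = n - p
    sigma2 = rss / df
    cvar = float(c @ XtX_inv @ c)
    eff = c @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t = eff / np.sqrt(sigma2 * cvar)
    t[sigma2 <= _SIGMA2_TOL] = np.nan
    return beta, sigma2, t, df


def fit_voxelwise_glm(
    images: list[GMImage],
    design: DesignMatrix,
    contrast: str,
    mask: np.ndarray | None = None,
) -> VoxelGLMResult:
    """Independent OLS at every voxel; t map for the named contrast.

    ``mask`` restricts the analysis (None analyses the full grid); voxels
    outside it, and voxels with zero residual variance, get ``tmap`` NaN.
    """
    Y, affine = stack_images(images)
    shape = images[0].shape
    if design.n != Y.shape[0]:
        raise DegenerateDesignError(
            f"design has {design.n} rows but {Y.shape[0]} images were given"
        )
    c = design.contrast(contrast)
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise GeometryError("analysis mask shape does not match images")
    flat = mask.reshape(-1)
    beta_m, sigma2_m, t_m, df = _fit_stacked(Y[:, flat], design.values, c)

    p = design.p
    beta = np.full((p,) + shape, np.nan)
    sigma2 = np.full(shape, np.nan)
    tmap = np.full(shape, np.nan)
    beta.reshape(p, -1)[:, flat] = beta_m
    sigma2.reshape(-1)[flat] = sigma2_m
    tmap.reshape(-1)[flat] = t_m
    return VoxelGLMResult(
        beta=beta,
        sigma2=sigma2,
        tmap=tmap,
        df=df,
        contrast_name=contrast,
        affine=affine,
        mask=mask,
    )


def _effect_column(design: DesignMatrix, contrast: str) -> tuple[int, float]:
    """Index and sign of the single effect column a contrast addresses."""
    c = design.contrast(contrast)
    nz = np.flatnonzero(c)
    if len(nz) != 1:
        raise ValueError(
            "permutation inference supports single-column contrasts; "
            f"{contrast!r} touches columns {nz.tolist()}"
        )
    return int(nz[0]), float(np.sign(c[nz[0]]))


def _residualize(A: np.ndarray, Z: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(Z, A, rcond=None)
    return A - Z @ coef


def _max_cluster_size(
    above: np.ndarray, structure: np.ndarray
) -> int:
    if not above.any():
        return 0
    labels, n_lab = ndimage.label(above, structure=structure)
    if n_lab == 0:
        return 0
    return int(np.bincount(labels.reshape(-1))[1:].max())


def permutation_fwe(
    images: list[GMImage],
    design: DesignMatrix,
    contrast: str,
    alpha: float = 0.05,
    cluster_forming_p: float = 0.001,
    n_perm: int = 1000,
    rng_seed: int = 0,
    mask: np.ndarray | None = None,
    connectivity: int = 18,
) -> FWEResult:
    """Max-statistic permutation thresholds for height and extent FWE.

    Runs ``n_perm`` Freedman–Lane permutations of the (residualized) effect
    column, records the map-wide maximum t and the maximum cluster size at
    the primary threshold per permutation, and returns the empirical
    (1 - alpha) thresholds with the observed statistic included in each
    null distribution.  Voxels with zero residual variance are excluded
    from the maxima rather than treated as infinite.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if not 0.0 < cluster_forming_p < 1.0:
        raise ValueError("cluster_forming_p must lie in (0, 1)")
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    structure = connectivity_structure(connectivity)

    Y, _ = stack_images(images)
    shape = images[0].shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise GeometryError("analysis mask shape does not match images")
    flat = mask.reshape(-1)
    Ym = Y[:, flat]

    X = design.values
    n, p = X.shape
    if n <= p:
        raise DegenerateDesignError("insufficient degrees of freedom for permutation")
    j, sign = _effect_column(design, contrast)
    Z = np.delete(X, j, axis=1)
    x = X[:, j]
    df = n - p
    t_form = float(stats.t.isf(cluster_forming_p, df))

    # Nuisance-residualized data and effect (Frisch–Waugh–Lovell): the
    # contrast t from the full model equals the t of regressing Rz·Y on Rz·x
    # with df = n - p.
    E = _residualize(Ym, Z)
    e2 = np.einsum("ij,ij->j", E, E)
    x_res = _residualize(x, Z)
    if float(x_res @ x_res) <= _SIGMA2_TOL:
        raise DegenerateDesignError(
            "effect column is collinear with the nuisance columns"
        )

    rng = np.random.default_rng(rng_seed)
    # Column r of P holds the r-th permuted, re-residualized effect vector;
    # column 0 is the observed (identity) assignment.
    P = np.empty((n, n_perm + 1))
    P[:, 0] = x_res
    for r in range(1, n_perm + 1):
        P[:, r] = rng.permutation(x_res)
    P[:, 1:] = _residualize(P[:, 1:], Z)

    ss = np.einsum("ij,ij->j", P, P)  # (n_perm+1,)
    B = P.T @ E  # (n_perm+1, V)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = B / ss[:, None]
        rss = np.maximum(e2[None, :] - beta**2 * ss[:, None], 0.0)
        t_all = sign * beta * np.sqrt(ss[:, None]) / np.sqrt(rss / df)
    undefined = rss <= _SIGMA2_TOL * np.maximum(e2[None, :], 1.0)
    t_all[undefined] = np.nan

    max_t = np.nanmax(
        np.where(np.isnan(t_all), -np.inf, t_all), axis=1
    )
    max_clu = np.empty(n_perm + 1, dtype=np.int64)
    grid_above = np.zeros(shape, dtype=bool)
    for r in range(n_perm + 1):
        row = t_all[r]
        grid_above.reshape(-1)[flat] = np.where(np.isnan(row), False, row >= t_form)
        max_clu[r] = _max_cluster_size(grid_above, structure)

    k = math.ceil((1.0 - alpha) * (n_perm + 1))  # 1-based order statistic
    height = float(np.sort(max_t)[k - 1])
    # Cluster sizes are small integers with heavy ties, so the plain order
    # statistic can land on a value exceeded by far more than alpha of the
    # null; take the smallest size whose null exceedance probability is
    # <= alpha instead (identical to the order statistic when ties are absent).
    extent = int(
        np.min(
            [
                kk
                for kk in range(0, int(max_clu.max()) + 2)
                if (max_clu >= kk).sum() <= alpha * (n_perm + 1)
            ]
        )
    )
    return FWEResult(
        alpha=alpha,
        height_threshold=height,
        cluster_forming_p=cluster_forming_p,
        cluster_forming_t=t_form,
        extent_threshold=extent,
        n_perm=n_perm,
        rng_seed=rng_seed,
        null_max_t=max_t,
        null_max_cluster=max_clu,
        connectivity=connectivity,
    )


def threshold_map(result: VoxelGLMResult, fwe: FWEResult) -> np.ndarray:
    """Apply height-OR-extent FWE thresholding to a t map.

    A voxel survives if its t reaches the height threshold, or if it
    belongs to a cluster (at the primary cluster-forming threshold) whose
    size reaches the extent threshold.  Surviving voxels keep their t
    values; everything else is zero.
    """
    t = result.tmap
    finite = np.isfinite(t)
    survived = finite & (t >= fwe.height_threshold)
    forming = finite & (t >= fwe.cluster_forming_t)
    if forming.any():
        structure = connectivity_structure(fwe.connectivity)
        labels, n_lab = ndimage.label(forming, structure=structure)
        if n_lab:
            sizes = np.bincount(labels.reshape(-1))
            # an extent threshold of 0 lets every forming cluster through
            big = np.flatnonzero(sizes >= max(fwe.extent_threshold, 1))
            big = big[big != 0]
            if len(big):
                survived |= np.isin(labels, big)
    out = np.zeros_like(t)
    out[survived] = t[survived]
    return out
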