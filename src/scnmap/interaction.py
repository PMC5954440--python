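"""Group × seed interaction inference and peak-sphere reporting.

For any two age groups, the voxel value is modelled as

    Y ~ β0 + β1·seed + β2·group + β3·gender + β4·(group × seed)

and the interaction coefficient β4 tests whether the seed–voxel covariance
slope differs between the groups.  Directional contrasts on β4 give the
"a > b" and "a < b" tables; family-wise error is controlled per direction
by the same max-statistic permutation scheme as the single-group model,
permuting the residualized interaction column.

Peak-sphere extraction (mean GM in a small sphere around a cluster peak)
and within-group Pearson correlations support scatter-style reporting of
how the covariance differs between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clusters import ClusterRecord, extract_clusters
from .errors import DegenerateDesignError, GeometryError
from .glm import (
    DesignMatrix,
    FWEResult,
    compute_gm_mask,
    fit_voxelwise_glm,
    permutation_fwe,
    threshold_map,
)
from .morphometry import GMImage
from .seeds import ROIMask, SeedVector, extract_roi_mean

__all__ = [
    "GroupComparison",
    "build_interaction_design",
    "compare_groups",
    "extract_sphere_values",
    "group_correlations",
]


@dataclass
class GroupComparison:
    """Directional interaction result for one group pair.

    ``direction`` "a>b" lists clusters where group_a's seed coupling exceeds
    group_b's; "a<b" the reverse.  Every cluster's max t reached the
    applicable FWE threshold.
    """

    group_a: str
    group_b: str
    direction: str
    clusters: list[ClusterRecord]
    fwe: FWEResult
    tmap: np.ndarray | None = None
    thresholded: np.ndarray | None = None


def build_interaction_design(
    seed: SeedVector | np.ndarray, group, gender
) -> DesignMatrix:
    """Design [1, seed_c, group, gender, group·seed_c] for two groups.

    ``group`` is 0/1 coded (0 = group a, 1 = group b); the seed is
    mean-centered over the pooled sample.  Contrasts ``"interaction+"``
    (+β4, slope larger in group b) and ``"interaction-"`` (−β4) are
    attached.  Requires both groups nonempty and a non-constant seed within
    each group.
    """
    s = np.asarray(seed.values if isinstance(seed, SeedVector) else seed, dtype=float)
    g = np.asarray(group, dtype=np.float64)
    sex = np.asarray(gender, dtype=np.float64)
    if not (s.shape == g.shape == sex.shape) or s.ndim != 1:
        raise ValueError("seed, group and gender must be 1D arrays of equal length")
    levels = np.unique(g)
    if len(levels) != 2:
        if len(levels) > 2:
            raise DegenerateDesignError(
                "more than two group levels: run pairwise comparisons, one "
                "two-group design per pair"
            )
        raise DegenerateDesignError("one group is empty: need two nonempty groups")
    if not np.array_equal(levels, [0.0, 1.0]):
        raise DegenerateDesignError("group must be 0/1 coded")
    for lev in (0.0, 1.0):
        if np.ptp(s[g == lev]) == 0:
            raise DegenerateDesignError(
                f"seed covariate is constant within group {int(lev)}"
            )
    sc = s - s.mean()
    X = np.column_stack([np.ones(len(s)), sc, g, sex, g * sc])
    return DesignMatrix(
        columns=["intercept", "seed", "group", "gender", "group_x_seed"],
        values=X,
        contrasts={
            "interaction+": np.array([0.0, 0.0, 0.0, 0.0, 1.0]),
            "interaction-": np.array([0.0, 0.0, 0.0, 0.0, -1.0]),
        },
    )


def compare_groups(
    images: list[GMImage],
    subjects: pd.DataFrame,
    seed_mask: ROIMask,
    group_pair: tuple[str, str] | None = None,
    alpha: float = 0.05,
    cluster_forming_p: float = 0.001,
    n_perm: int = 1000,
    rng_seed: int = 0,
    gm_threshold: float = 0.1,
    connectivity: int = 18,
    exclude_seed_mask: bool = False,
) -> tuple[GroupComparison, GroupComparison]:
    """Directional group × seed interaction maps for one group pair.

    ``subjects`` must carry columns id, age, gender (0/1), group, in image
    order.  ``group_pair`` (a, b) selects the two groups (default: the two
    labels present, in order of first appearance).  Returns the
    (a>b, a<b) comparisons, each with its own permutation FWE thresholds
    and Table-style cluster records.

    The analysis grid is restricted to the implicit GM mask (mean GM >
    ``gm_threshold``); ``exclude_seed_mask`` additionally removes the seed's
    own voxels from the target map.
    """
    if len(images) != len(subjects):
        raise ValueError("images and subject table differ in length")
    labels = list(dict.fromkeys(subjects["group"]))
    if group_pair is None:
        if len(labels) != 2:
            raise DegenerateDesignError(
                f"subject table holds groups {labels}; pass group_pair to "
                "select two of them"
            )
        group_pair = (labels[0], labels[1])
    a, b = group_pair
    sel = subjects["group"].isin([a, b]).to_numpy()
    if not sel.any() or not (subjects["group"] == a).any() or not (
        subjects["group"] == b
    ).any():
        raise DegenerateDesignError(f"groups {a!r} and {b!r} must both be nonempty")
    sub = subjects.loc[sel].reset_index(drop=True)
    imgs = [img for img, keep in zip(images, sel) if keep]

    seed = extract_roi_mean(imgs, seed_mask)
    g = (sub["group"] == b).astype(float).to_numpy()
    design = build_interaction_design(seed, g, sub["gender"].to_numpy(dtype=float))

    mask = compute_gm_mask(imgs, threshold=gm_threshold)
    if exclude_seed_mask:
        mask = mask & ~seed_mask.voxels
    if not mask.any():
        raise GeometryError("analysis mask is empty; lower gm_threshold")

    out = []
    seeds = np.random.SeedSequence(rng_seed).generate_state(2) % (2**31)
    for direction, contrast, child_seed in (
        (f"{a}>{b}", "interaction-", int(seeds[0])),
        (f"{a}<{b}", "interaction+", int(seeds[1])),
    ):
        fit = fit_voxelwise_glm(imgs, design, contrast, mask=mask)
        fwe = permutation_fwe(
            imgs,
            design,
            contrast,
            alpha=alpha,
            cluster_forming_p=cluster_forming_p,
            n_perm=n_perm,
            rng_seed=child_seed,
            mask=mask,
            connectivity=connectivity,
        )
        thr = threshold_map(fit, fwe)
        clusters = extract_clusters(
            thr,
            fit.affine,
            connectivity=connectivity,
            seed_name=seed_mask.name,
            contrast=direction,
        )
        out.append(
            GroupComparison(
                group_a=a,
                group_b=b,
                direction=direction,
                clusters=clusters,
                fwe=fwe,
                tmap=fit.tmap,
                thresholded=thr,
            )
        )
    return out[0], out[1]


def extract_sphere_values(
    images: list[GMImage], center_mm, radius_mm: float = 4.0
) -> np.ndarray:
    """Per-subject mean GM in a closed ball around a world-mm center.

    Membership is by voxel-center Euclidean distance <= radius; the voxel
    whose center is nearest the requested center is always included, so a
    zero radius returns that voxel's value.
    """
    if radius_mm < 0:
        raise ValueError(f"radius_mm must be non-negative, got {radius_mm}")
    if not images:
        raise ValueError("no images given")
    center = np.asarray(center_mm, dtype=np.float64)
    img0 = images[0]
    inv = np.linalg.inv(img0.affine)
    vox = inv[:3, :3] @ center + inv[:3, 3]
    nearest = np.round(vox).astype(int)
    if np.any(nearest < 0) or np.any(nearest >= np.asarray(img0.shape)):
        raise GeometryError(
            f"sphere center {tuple(center)} mm falls outside the image grid"
        )
    x, y, z = img0.world_coords()
    dist2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    member = dist2 <= radius_mm**2
    member[tuple(nearest)] = True
    values = np.empty(len(images), dtype=np.float64)
    for i, img in enumerate(images):
        if img.shape != img0.shape or not np.allclose(img.affine, img0.affine):
            raise GeometryError("images do not share one grid")
        values[i] = float(img.data[member].mean())
    return values


def group_correlations(
    sphere_values, seed: SeedVector | np.ndarray, group_labels
) -> dict[str, float]:
    """Within-group Pearson r between seed values and peak-sphere values.

    Groups need at least three subjects; a zero-variance variable within a
    group yields NaN (undefined correlation) rather than an error.
    """
    from scipy import stats

    v = np.asarray(sphere_values, dtype=np.float64)
    s = np.asarray(seed.values if isinstance(seed, SeedVector) else seed, dtype=float)
    labels = np.asarray(group_labels)
    if not (v.shape == s.shape == labels.shape):
        raise ValueError("sphere_values, seed and group_labels must align")
    out: dict[str, float] = {}
    for lab in dict.fromkeys(labels.tolist()):
        sel = labels == lab
        if sel.sum() < 3:
            raise ValueError(f"group {lab!r} has fewer than 3 subjects")
        a, b2 = s[sel], v[sel]
        if np.ptp(a) == 0 or np.ptp(b2) == 0:
            out[str(lab)] = float("nan")
            continue
        out[str(lab)] = float(stats.pearsonr(a, b2).statistic)
    return out
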