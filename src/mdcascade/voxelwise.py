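"""Voxel-wise GLM inference on skeleton MD with TFCE permutation correction.

The primary model regresses each skeleton voxel's MD on the interaction
EYO x mutation status plus EYO, mutation status, sex and years of education.
Family-wise error is controlled non-parametrically: the data are permuted
under the reduced (nuisance-only) model following the Freedman-Lane scheme,
each permuted t-map is enhanced with threshold-free cluster enhancement
(TFCE), and the permutation distribution of the image-wise maximum enhanced
statistic calibrates corrected p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "DESIGN_COLUMNS",
    "DesignMatrix",
    "StatMap",
    "TFCEParams",
    "PermutationResult",
    "build_design",
    "glm_tstats",
    "fit_glm_tmap",
    "tfce_enhance",
    "permutation_fwe",
    "group_contrast_maps",
    "intersect_binarized_maps",
]

#: Fixed column order of the interaction design.
DESIGN_COLUMNS = ("intercept", "eyo", "mutation", "eyo_x_mutation", "sex", "education")


@dataclass
class DesignMatrix:
    """Subjects-by-predictors design with a fixed, named column order."""

    X: np.ndarray
    column_names: tuple
    subject_ids: tuple = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("design must be 2-D")
        if len(self.column_names) != self.X.shape[1]:
            raise ValueError("column_names length mismatch")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def column_index(self, name: str) -> int:
        return self.column_names.index(name)

    def contrast(self, name: str) -> np.ndarray:
        """Unit contrast vector selecting a single named column."""
        c = np.zeros(self.X.shape[1])
        c[self.column_index(name)] = 1.0
        return c


@dataclass
class StatMap:
    """A voxel-wise t-statistic map on the skeleton."""

    tmap: np.ndarray
    mask: np.ndarray
    dof: int
    contrast: np.ndarray


@dataclass(frozen=True)
class TFCEParams:
    """TFCE constants: enhanced(v) = sum_h extent(v,h)^E * h^H * dh.

    Defaults are the standard constants of the method (H=2, E=0.5,
    26-neighbourhood); ``dh`` defaults to max-statistic/n_steps.
    """

    H: float = 2.0
    E: float = 0.5
    dh: float | None = None
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.H < 0 or self.E < 0:
            raise ValueError("H and E must be non-negative")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def structure(self) -> np.ndarray:
        order = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, order)


@dataclass
class PermutationResult:
    """FWE-corrected p-values and the permutation null of the maximum statistic."""

    fwe_p: np.ndarray
    enhanced_obs: np.ndarray
    mask: np.ndarray
    n_permutations: int
    max_stat_null: np.ndarray
    seed: int


def build_design(subjects: pd.DataFrame) -> DesignMatrix:
    """Build the interaction design from a subject table.

    Required columns: ``subject_id``, ``mutation_carrier`` (bool/0-1), ``eyo``
    (years), ``sex`` (1 = female, 0 = male), ``education`` (years).  Column
    order is fixed: intercept, eyo, mutation, eyo x mutation, sex, education.
    """
    required = {"subject_id", "mutation_carrier", "eyo", "sex", "education"}
    missing = required - set(subjects.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    if subjects[["mutation_carrier", "eyo", "sex", "education"]].isna().any().any():
        raise ValueError("missing covariate values in subject table")
    eyo = subjects["eyo"].to_numpy(dtype=float)
    mut = subjects["mutation_carrier"].to_numpy(dtype=float)
    sex = subjects["sex"].to_numpy(dtype=float)
    edu = subjects["education"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(eyo), eyo, mut, eyo * mut, sex, edu])
    return DesignMatrix(
        X=X,
        column_names=tuple(DESIGN_COLUMNS),
        subject_ids=tuple(subjects["subject_id"].astype(str)),
    )


def glm_tstats(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray) -> tuple[np.ndarray, int]:
    """OLS t-statistics of contrast'beta for many responses at once.

    Parameters
    ----------
    Y : ndarray, shape (n_subjects, n_voxels)
    X : ndarray, shape (n_subjects, p)
    contrast : ndarray, shape (p,)

    Returns
    -------
    t : ndarray, shape (n_voxels,)
        Voxels with zero residual variance get t = 0 (they carry no evidence).
    dof : int
        Residual degrees of freedom, n - rank(X).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    contrast = np.asarray(contrast, dtype=float)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("Y and X row counts differ")
    if contrast.shape != (X.shape[1],):
        raise ValueError("contrast length does not match design")
    if not np.any(contrast):
        raise ValueError("contrast is the zero vector")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = Y.shape[0] - np.linalg.matrix_rank(X)
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    denom2 = sigma2 * float(contrast @ xtx_inv @ contrast)
    num = contrast @ beta
    t = np.zeros_like(num)
    ok = denom2 > 0
    if not np.all(ok):
        logger.warning("%d voxels with zero residual variance set to t=0", (~ok).sum())
    t[ok] = num[ok] / np.sqrt(denom2[ok])
    return t, int(dof)


def fit_glm_tmap(
    Y: np.ndarray, design: DesignMatrix, contrast: np.ndarray, mask: np.ndarray
) -> StatMap:
    """Fit the voxel-wise GLM and return a 3-D t-map on the skeleton mask.

    ``Y`` is subjects x masked-voxels, aligned with ``mask``'s True entries in
    C order.
    """
    mask = np.asarray(mask, dtype=bool)
    if Y.shape[1] != int(mask.sum()):
        raise ValueError("Y column count does not match mask voxel count")
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite values in Y")
    t, dof = glm_tstats(Y, design.X, contrast)
    tmap = np.zeros(mask.shape)
    tmap[mask] = t
    return StatMap(tmap=tmap, mask=mask, dof=dof, contrast=np.asarray(contrast, float))


def _tfce_one_sided(pos: np.ndarray, params: TFCEParams) -> np.ndarray:
    """TFCE of a non-negative map: per-threshold connected-component integration."""
    out = np.zeros_like(pos)
    hmax = float(pos.max())
    if hmax <= 0:
        return out
    dh = params.dh if params.dh is not None else hmax / params.n_steps
    structure = params.structure()
    h = dh
    # integrate h = dh, 2dh, ... <= hmax (tolerance for float accumulation)
    while h <= hmax * (1 + 1e-12):
        supra = pos >= h
        labels, n = ndimage.label(supra, structure=structure)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel())
        contrib = sizes[labels] ** params.E * h**params.H * dh
        out[supra] += contrib[supra]
        h += dh
    return out


def tfce_enhance(tmap: np.ndarray, mask: np.ndarray, params: TFCEParams | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a signed statistic map.

    For each voxel the suprathreshold cluster extent and height are integrated
    over all thresholds, ``enhanced(v) = sum_h extent(v,h)^E * h^H * dh``,
    removing the need for an arbitrary cluster-forming cut-off.  Negative
    values are enhanced by applying the same integral to the negated map; the
    output carries the sign of the input.
    """
    params = params or TFCEParams()
    mask = np.asarray(mask, dtype=bool)
    tmap = np.asarray(tmap, dtype=float)
    if tmap.shape != mask.shape:
        raise ValueError("tmap and mask shapes differ")
    if not np.all(np.isfinite(tmap[mask])):
        raise ValueError("non-finite statistics inside the mask")
    pos = np.where(mask, np.clip(tmap, 0, None), 0.0)
    neg = np.where(mask, np.clip(-tmap, 0, None), 0.0)
    out = _tfce_one_sided(pos, params)
    if neg.any():
        out -= _tfce_one_sided(neg, params)
    return out


def permutation_fwe(
    Y: np.ndarray,
    design: DesignMatrix,
    contrast: np.ndarray,
    mask: np.ndarray,
    params: TFCEParams | None = None,
    n_perm: int = 500,
    seed: int = 0,
) -> PermutationResult:
    """Freedman-Lane permutation test with TFCE max-statistic FWE correction.

    The nuisance design Z (all columns not involved in the contrast) is fitted
    and the permutation acts on its residuals: Y* = Z b_Z + P (Y - Z b_Z).
    Each Y* is refitted under the full model, the one-sided (contrast
    direction) t-map is TFCE-enhanced, and its maximum over the mask enters
    the null.  The observed statistic is included in its own null, so
    fwe_p >= 1/n_perm.

    Returns corrected p-values per voxel: the proportion of null maxima at
    least as large as the voxel's observed enhanced statistic.
    """
    params = params or TFCEParams()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    contrast = np.asarray(contrast, dtype=float)
    X = design.X
    interest = contrast != 0
    if not interest.any():
        raise ValueError("contrast is the zero vector")
    Z = X[:, ~interest]
    rng = np.random.default_rng(seed)

    if Z.shape[1] > 0:
        bz = np.linalg.lstsq(Z, Y, rcond=None)[0]
        fitted_z = Z @ bz
    else:
        fitted_z = np.zeros_like(Y)
    resid_z = Y - fitted_z

    def enhanced(Yk: np.ndarray) -> np.ndarray:
        t, _ = glm_tstats(Yk, X, contrast)
        tmap = np.zeros(mask.shape)
        tmap[mask] = t
        # one-sided in the contrast direction
        return _tfce_one_sided(np.where(mask, np.clip(tmap, 0, None), 0.0), params)

    enh_obs = enhanced(Y)
    obs_vals = enh_obs[mask]
    max_null = np.empty(n_perm)
    max_null[0] = obs_vals.max(initial=0.0)
    n = Y.shape[0]
    for k in range(1, n_perm):
        perm = rng.permutation(n)
        Ystar = fitted_z + resid_z[perm]
        max_null[k] = enhanced(Ystar)[mask].max(initial=0.0)

    # observed is null[0]; p = (#{null maxima >= observed(v)}) / n_perm >= 1/n_perm
    exceed = (max_null[None, :] >= obs_vals[:, None]).sum(axis=1)
    pvals = exceed / n_perm
    fwe_p = np.ones(mask.shape)
    fwe_p[mask] = pvals
    return PermutationResult(
        fwe_p=fwe_p,
        enhanced_obs=enh_obs,
        mask=mask,
        n_permutations=n_perm,
        max_stat_null=max_null,
        seed=seed,
    )


def group_contrast_maps(
    Y: np.ndarray, subjects: pd.DataFrame, mask: np.ndarray
) -> dict:
    """Pairwise two-group t-maps between symptomatic carriers, asymptomatic
    carriers and non-carriers, adjusting for sex and education.

    Group membership comes from ``mutation_carrier`` and ``cdr_positive``
    (clinical dementia rating > 0).  Returns a dict keyed by
    ``"groupA_vs_groupB"`` with :class:`StatMap` values (positive t = group A
    higher).
    """
    carrier = subjects["mutation_carrier"].to_numpy(bool)
    cdr = subjects["cdr_positive"].to_numpy(bool)
    groups = {
        "symptomatic": carrier & cdr,
        "asymptomatic": carrier & ~cdr,
        "noncarrier": ~carrier,
    }
    for name, sel in groups.items():
        if sel.sum() < 2:
            raise ValueError(f"group '{name}' has fewer than 2 subjects")
    sex = subjects["sex"].to_numpy(float)
    edu = subjects["education"].to_numpy(float)
    out = {}
    pairs = [
        ("symptomatic", "noncarrier"),
        ("asymptomatic", "noncarrier"),
        ("symptomatic", "asymptomatic"),
    ]
    for a, b in pairs:
        sel = groups[a] | groups[b]
        ind = groups[a][sel].astype(float)
        X = np.column_stack(
            [np.ones(sel.sum()), ind, sex[sel], edu[sel]]
        )
        design = DesignMatrix(X=X, column_names=("intercept", "group", "sex", "education"))
        c = design.contrast("group")
        out[f"{a}_vs_{b}"] = fit_glm_tmap(Y[sel], design, c, mask)
    return out


def intersect_binarized_maps(maps: list) -> np.ndarray:
    """Logical AND of binarized significance masks on a shared grid."""
    if not maps:
        raise ValueError("no maps to intersect")
    arrs = [np.asarray(m, dtype=bool) for m in maps]
    shape = arrs[0].shape
    for a in arrs:
        if a.shape != shape:
            raise ValueError("masks have mismatching shapes")
    return np.logical_and.reduce(arrs)
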