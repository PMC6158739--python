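"""White-matter hyperintensity (WMH) frequency maps and sensitivity analysis.

WMHs are macroscopic lesions visible on FLAIR MRI, delivered here as binary
masks on the analysis grid.  Two questions are addressed: where do WMHs
occur in each group (voxel-wise lesion frequency maps), and do the
EYO x mutation interaction effects on tract MD persist when MD is averaged
only over normal-appearing (non-WMH) tissue — i.e. are the diffusivity
changes merely a WMH artefact?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .skeleton import SkeletonVolume
from .tracts import robust_fit, tukey_filter
from .voxelwise import build_design

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyMap",
    "wmh_frequency",
    "split_md_by_wmh",
    "compare_interactions",
]


@dataclass
class FrequencyMap:
    """Voxel-wise lesion frequency: fraction of group subjects lesioned."""

    data: np.ndarray
    group: str
    n_subjects: int


def wmh_frequency(masks: list, group: str = "") -> FrequencyMap:
    """Voxel-wise mean of per-subject binary WMH masks.

    Each voxel's value is (number of subjects lesioned there) / (group size),
    hence lies in [0, 1] and times n_subjects is an integer.
    """
    if not masks:
        raise ValueError("empty group: no WMH masks")
    arrs = [np.asarray(m, dtype=bool) for m in masks]
    shape = arrs[0].shape
    for a in arrs:
        if a.shape != shape:
            raise ValueError("WMH masks have mismatching shapes")
    freq = np.mean(np.stack(arrs), axis=0)
    return FrequencyMap(data=freq, group=group, n_subjects=len(arrs))


def split_md_by_wmh(
    md: SkeletonVolume,
    wmh_mask: np.ndarray,
    tract_mask: np.ndarray,
    min_voxels: int = 5,
) -> tuple:
    """Average MD inside and outside WMH within a tract.

    Returns ``(mean_inside, mean_outside)``; a side with fewer than
    ``min_voxels`` voxels is reported as None (missing), never as zero.
    """
    wmh_mask = np.asarray(wmh_mask, dtype=bool)
    tract_mask = np.asarray(tract_mask, dtype=bool)
    if wmh_mask.shape != md.data.shape or tract_mask.shape != md.data.shape:
        raise ValueError("masks must share the MD grid")
    if not tract_mask.any():
        raise ValueError("empty tract mask")
    inside = tract_mask & wmh_mask
    outside = tract_mask & ~wmh_mask
    mean_in = float(md.data[inside].mean()) if inside.sum() >= min_voxels else None
    mean_out = float(md.data[outside].mean()) if outside.sum() >= min_voxels else None
    return mean_in, mean_out


def compare_interactions(
    inside: pd.DataFrame,
    outside: pd.DataFrame,
    subjects: pd.DataFrame,
    huber_t: float = 1.345,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Side-by-side EYO x mutation interaction fits within vs outside WMH.

    Both tables are tidy long (``subject_id``, ``measure``, ``value``) with
    missing sides absent (not zero).  For every tract with both sides usable
    the tract-analysis robust fit is run per side; the output row carries the
    interaction coefficient, SE and normal-quantile CI for each side.  Tracts
    missing a side are skipped with a log entry.
    """
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    rows = []
    tracts = sorted(set(inside["measure"]) | set(outside["measure"]))
    for tract in tracts:
        sides = {}
        for side, table in (("inside", inside), ("outside", outside)):
            sub = table[(table["measure"] == tract) & table["value"].notna()]
            merged = sub.merge(subjects, on="subject_id", how="inner")
            if len(merged) < 8 or merged["mutation_carrier"].nunique() < 2:
                sides[side] = None
                continue
            vals = merged["value"].to_numpy(float)
            grp = merged["mutation_carrier"].to_numpy(bool)
            kept, removed = tukey_filter(vals, grp)
            kept_df = merged.iloc[kept]
            fit = robust_fit(
                kept_df["value"].to_numpy(float),
                build_design(kept_df),
                huber_t=huber_t,
                n_outliers_removed=int(removed.size),
            )
            sides[side] = fit
        if sides["inside"] is None or sides["outside"] is None:
            logger.info("tract %r skipped: one side missing or too small", tract)
            continue
        row = {"measure": tract}
        for side, fit in sides.items():
            ii = fit.column_names.index("eyo_x_mutation")
            b, se = fit.beta[ii], fit.se[ii]
            row[f"{side}_b"] = b
            row[f"{side}_se"] = se
            row[f"{side}_ci_low"] = b - z * se
            row[f"{side}_ci_high"] = b + z * se
            row[f"{side}_n"] = fit.n_used
        rows.append(row)
    if not rows:
        raise ValueError("no tract with both WMH sides usable")
    return pd.DataFrame(rows)
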