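"""Biomarker-versus-EYO trajectory curves and PSMD-biomarker associations.

Each biomarker (CSF amyloid-beta 1-42, total tau, P-tau181, soluble TREM2,
precuneus PIB-PET binding, ICV-adjusted hippocampal volume) and the white-
matter measures (tract MD, PSMD) are modelled as polynomial functions of EYO
with group-specific coefficients.  Model order is chosen by forward term
addition: starting from linear terms, higher-order terms (base and carrier-
interaction jointly) are added while the Akaike information criterion keeps
decreasing.  The fitted equations, not a scatter smoother, provide the curves
for the biomarker-cascade figure, standardized against the non-carrier
distribution so that heterogeneous assays can share one axis.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .tracts import RobustFitResult, robust_fit

__all__ = [
    "TrajectoryModel",
    "adjust_for_icv",
    "fit_trajectory",
    "predict_curves",
    "associate_psmd_biomarkers",
]

BIOMARKER_NAMES = (
    "csf_abeta42",
    "csf_ttau",
    "csf_ptau181",
    "csf_strem2",
    "pib_precuneus",
    "hippocampal_volume",
)


@dataclass
class TrajectoryModel:
    """Group-specific polynomial trajectory of a measure over EYO.

    ``coefficients`` holds, in order, the base polynomial coefficients
    (intercept, eyo, eyo^2, ...) followed by the carrier offset and the
    carrier-interaction polynomial (carrier, carrier*eyo, ...), each of
    length ``selected_order + 1``.
    """

    measure: str
    selected_order: int
    coefficients: np.ndarray
    fit: RobustFitResult
    aic_path: dict
    eyo_range: tuple
    noncarrier_mean: float
    noncarrier_sd: float

    def group_coefficients(self, carrier: bool) -> np.ndarray:
        k = self.selected_order + 1
        base = self.coefficients[:k]
        if not carrier:
            return base
        return base + self.coefficients[k : 2 * k]


def adjust_for_icv(
    volumes: np.ndarray, icv: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Regression-based intracranial-volume correction of regional volumes.

    The slope ``b`` of volume on ICV is estimated by least squares within the
    reference group (non-carriers, whose volumes are unaffected by disease)
    and applied to everyone: ``adjusted = raw - b * (icv - mean(icv))``.
    """
    volumes = np.asarray(volumes, dtype=float)
    icv = np.asarray(icv, dtype=float)
    reference = np.asarray(reference, dtype=bool)
    if volumes.shape != icv.shape or volumes.shape != reference.shape:
        raise ValueError("volumes, icv and reference must align")
    if reference.sum() < 2:
        raise ValueError("need at least 2 reference subjects")
    icv_ref = icv[reference]
    var = icv_ref.var()
    if var <= 0:
        raise ValueError("degenerate ICV variance in reference group")
    b = np.cov(icv_ref, volumes[reference], ddof=1)[0, 1] / icv_ref.var(ddof=1)
    return volumes - b * (icv - icv.mean())


def _poly_design(eyo: np.ndarray, carrier: np.ndarray, order: int) -> np.ndarray:
    cols = [eyo**p for p in range(order + 1)]
    cols += [carrier * eyo**p for p in range(order + 1)]
    return np.column_stack(cols)


def _gaussian_aic(resid: np.ndarray, n_params: int) -> float:
    """AIC from the Gaussian quasi-likelihood of the residuals."""
    n = resid.size
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)
    return n * np.log(2 * np.pi * sigma2) + n + 2 * (n_params + 1)


def fit_trajectory(
    values: np.ndarray,
    eyo: np.ndarray,
    carrier: np.ndarray,
    measure: str = "",
    max_order: int = 3,
    huber_t: float = 1.345,
) -> TrajectoryModel:
    """Forward polynomial-order selection with AIC stopping.

    Candidate models of increasing EYO polynomial order carry an order-matched
    carrier-interaction polynomial; each is fitted by Huber M-estimation and
    scored by the Gaussian quasi-likelihood AIC of its residuals.  Term
    addition stops as soon as AIC fails to decrease; the last improving model
    is returned.
    """
    values = np.asarray(values, dtype=float)
    eyo = np.asarray(eyo, dtype=float)
    carrier = np.asarray(carrier, dtype=float)
    if not (carrier.min() == 0 and carrier.max() == 1):
        raise ValueError("both groups must be represented")
    if values.size < 2 * (max_order + 1) + 2:
        raise ValueError("too few observations for the requested max_order")
    aic_path = {}
    best = None
    for order in range(1, max_order + 1):
        X = _poly_design(eyo, carrier, order)
        fit = robust_fit(values, X, huber_t=huber_t)
        resid = values - X @ fit.beta
        aic = _gaussian_aic(resid, X.shape[1])
        aic_path[order] = aic
        if best is not None and aic >= aic_path[best[0]]:
            break
        best = (order, fit)
    order, fit = best
    nc = carrier == 0
    return TrajectoryModel(
        measure=measure,
        selected_order=order,
        coefficients=fit.beta.copy(),
        fit=fit,
        aic_path=aic_path,
        eyo_range=(float(eyo.min()), float(eyo.max())),
        noncarrier_mean=float(values[nc].mean()),
        noncarrier_sd=float(values[nc].std(ddof=1)),
    )


def predict_curves(
    model: TrajectoryModel,
    eyo_grid: np.ndarray,
    standardize: bool = False,
    flip_sign: bool = False,
) -> pd.DataFrame:
    """Evaluate the fitted group trajectories on an EYO grid.

    With ``standardize=True`` curves are z-scored against the non-carrier
    mean/SD of the fitted sample; ``flip_sign`` additionally negates the
    curves so that the abnormal direction points upward for measures that
    decrease with disease.  Grid points outside the fitted EYO range trigger
    an extrapolation warning.
    """
    eyo_grid = np.asarray(eyo_grid, dtype=float)
    lo, hi = model.eyo_range
    if eyo_grid.min() < lo or eyo_grid.max() > hi:
        warnings.warn(
            f"extrapolating {model.measure!r} outside fitted EYO range [{lo}, {hi}]",
            stacklevel=2,
        )
    out = {"eyo": eyo_grid}
    for carrier in (False, True):
        coef = model.group_coefficients(carrier)
        y = np.polynomial.polynomial.polyval(eyo_grid, coef)
        if standardize:
            y = (y - model.noncarrier_mean) / model.noncarrier_sd
            if flip_sign:
                y = -y
        out["carrier" if carrier else "noncarrier"] = y
    return pd.DataFrame(out)


def associate_psmd_biomarkers(
    psmd: pd.DataFrame,
    biomarkers: pd.DataFrame,
    subjects: pd.DataFrame,
    carrier_only: bool = True,
    huber_t: float = 1.345,
) -> pd.DataFrame:
    """Robust regressions of PSMD on each biomarker (carrier group).

    Outcome and predictor are z-standardized over the analysis sample so the
    coefficients are comparable across assays; sex and education enter as
    covariates.  Returns a tidy table with one row per biomarker:
    ``(measure, B, SE, p, n)``; p-values are normal-approximation Wald tests
    from the robust fit.
    """
    from scipy.stats import norm

    merged = psmd.merge(subjects, on="subject_id", how="inner")
    if carrier_only:
        merged = merged[merged["mutation_carrier"].astype(bool)]
    if merged.empty:
        raise ValueError("no carrier subjects available for association analysis")
    rows = []
    for measure, sub in biomarkers.groupby("measure", sort=True):
        m = merged.merge(sub[["subject_id", "value"]], on="subject_id", how="inner")
        y = m["psmd"].to_numpy(float)
        x = m["value"].to_numpy(float)
        yz = (y - y.mean()) / y.std(ddof=1)
        xz = (x - x.mean()) / x.std(ddof=1)
        X = np.column_stack(
            [np.ones(len(m)), xz, m["sex"].to_numpy(float), m["education"].to_numpy(float)]
        )
        fit = robust_fit(yz, X, huber_t=huber_t)
        b, se = fit.beta[1], fit.se[1]
        p = 2 * norm.sf(abs(b / se)) if se > 0 else np.nan
        rows.append({"measure": measure, "B": b, "SE": se, "p": p, "n": len(m)})
    return pd.DataFrame(rows)
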