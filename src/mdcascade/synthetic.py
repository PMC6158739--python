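"""Synthetic autosomal-dominant Alzheimer's-type cohort generator.

Emulates the data structure of a two-group mutation-carrier / non-carrier
cohort observed across estimated years to symptom onset (EYO): per-subject
skeletonized mean-diffusivity (MD) volumes with planted regional divergence
onsets, a labelled tract atlas, posterior/periventricular white-matter-
hyperintensity masks, group-dependent biomarker trajectories, grey-matter
density maps coupled to tract pathology, and streamline bundles terminating
at a grey-matter slab.  Every planted quantity is recorded in a truth object
so downstream estimators can be validated against known ground truth.

The default configuration encodes the study conditions the analysis assumes:
64 carriers and 45 non-carriers spanning EYO -25..+10, MD ramp onsets per
tract staggered between EYO -10 and 0, biomarker onsets ordered amyloid ->
tau -> white matter/microglia -> hippocampal atrophy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .projection import Streamline
from .tracts import TractAtlas

__all__ = [
    "RegionSpec",
    "BiomarkerSpec",
    "CohortConfig",
    "SyntheticTruth",
    "CohortData",
    "GMSlabGeometry",
    "generate_cohort",
    "generate_streamline_set",
]


@dataclass
class RegionSpec:
    """A planted MD effect region: box placement (grid fractions) + effect."""

    name: str
    onset_eyo: float
    slope: float  # MD units (mm^2/s) per EYO year past onset, carriers only
    x0: float = 0.1
    y0: float = 0.1
    z0: float = 0.3
    xf: float = 0.18  # box extent as fraction of each grid dimension
    yf: float = 0.14
    zf: float = 0.25
    a_priori: bool = False

    def box(self, shape: tuple) -> tuple:
        """Integer slices of the region's box on a given grid."""
        sl = []
        for frac0, fracw, dim in ((self.x0, self.xf, shape[0]),
                                  (self.y0, self.yf, shape[1]),
                                  (self.z0, self.zf, shape[2])):
            lo = int(round(frac0 * dim))
            w = max(2, int(round(fracw * dim)))
            if lo + w > dim:
                raise ValueError(f"region {self.name!r} does not fit grid {shape}")
            sl.append(slice(lo, lo + w))
        return tuple(sl)


def _default_regions(base_slope: float = 2e-6) -> list:
    """Ten tract-like regions in two columns, staggered divergence onsets."""
    names = [
        ("forceps_major", -10.0, 1.0, False),
        ("forceps_minor", -10.0, 0.8, False),
        ("ifof_l", -5.0, 0.75, False),
        ("ifof_r", -5.0, 0.75, False),
        ("slf_l", -5.0, 0.6, False),
        ("slf_r", -5.0, 0.6, False),
        ("ilf_l", -5.0, 0.6, False),
        ("atr_l", 0.0, 0.5, False),
        ("atr_r", 0.0, 0.5, False),
        ("cingulum_hippocampal", 0.0, 0.4, True),
    ]
    regions = []
    for i, (name, onset, mult, apriori) in enumerate(names):
        col, row = divmod(i, 5)
        regions.append(
            RegionSpec(
                name=name,
                onset_eyo=onset,
                slope=mult * base_slope,
                x0=0.08 + 0.34 * col,
                y0=0.04 + 0.19 * row,
                z0=0.3,
                xf=0.18,
                yf=0.14,
                zf=0.25,
                a_priori=apriori,
            )
        )
    return regions


@dataclass
class BiomarkerSpec:
    """Group-dependent biomarker trajectory: flat in non-carriers, monotone
    departure past ``onset_eyo`` in carriers."""

    baseline_mean: float
    baseline_sd: float
    onset_eyo: float
    rate: float  # signed units per EYO year past onset ("ramp" shape)
    shape: str = "ramp"  # or "sigmoid"
    sigmoid_width: float = 3.0

    def carrier_effect(self, eyo: np.ndarray) -> np.ndarray:
        eyo = np.asarray(eyo, dtype=float)
        if self.shape == "ramp":
            return self.rate * np.clip(eyo - self.onset_eyo, 0.0, None)
        if self.shape == "sigmoid":
            magnitude = self.rate * 20.0  # total change over a 20-year window
            return magnitude * expit((eyo - self.onset_eyo) / self.sigmoid_width)
        raise ValueError(f"unknown trajectory shape {self.shape!r}")


def _default_biomarkers() -> dict:
    # Onsets follow the amyloid -> tau -> microglia/WM -> atrophy ordering.
    return {
        "csf_abeta42": BiomarkerSpec(450.0, 80.0, -15.0, -10.0),
        "csf_ttau": BiomarkerSpec(60.0, 18.0, -20.0, 2.5),
        "csf_ptau181": BiomarkerSpec(30.0, 9.0, -20.0, 1.2),
        "csf_strem2": BiomarkerSpec(3200.0, 700.0, -10.0, 110.0),
        "pib_precuneus": BiomarkerSpec(0.03, 0.05, -20.0, 0.035),
        "hippocampal_volume": BiomarkerSpec(8800.0, 500.0, -5.0, -150.0),
    }


@dataclass
class CohortConfig:
    """Full parameterisation of the synthetic cohort.

    Units: MD in mm^2/s, EYO in years.  ``noise_sd`` is iid per voxel;
    ``subject_sd`` is a per-subject global MD offset (biological between-
    subject variability, which voxel-averaging does not remove).
    """

    n_carriers: int = 64
    n_noncarriers: int = 45
    eyo_range: tuple = (-25.0, 10.0)
    grid_shape: tuple = (32, 32, 16)
    skeleton_fraction: float = 0.15
    baseline_md: float = 7.0e-4
    regions: list = field(default_factory=_default_regions)
    effect_shape: str = "ramp"  # or "sigmoid"
    sigmoid_width: float = 3.0
    noise_sd: float = 3.0e-5
    subject_sd: float = 1.0e-5
    smooth_noise_sigma: float = 0.0  # voxels; >0 spatially smooths the noise field
    covariate_effects: dict = field(
        default_factory=lambda: {"sex": 0.0, "education": 0.0}
    )
    biomarker_params: dict = field(default_factory=_default_biomarkers)
    wmh_base_rate: float = 0.01
    posterior_gradient: float = 0.10
    wmh_eyo_gain: float = 1.0
    gm_slab_x: tuple = (0.82, 0.97)  # GM slab position, fractions of x extent
    gm_baseline_density: float = 0.6
    gm_coupling: float = 1.0
    gm_noise_sd: float = 0.03
    n_streamlines_per_tract: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_carriers <= 0 or self.n_noncarriers <= 0:
            raise ValueError("group sizes must be positive")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not (0 < self.skeleton_fraction <= 1):
            raise ValueError("skeleton_fraction must be in (0, 1]")
        if self.eyo_range[0] >= self.eyo_range[1]:
            raise ValueError("eyo_range must be increasing")


@dataclass
class SyntheticTruth:
    """Planted ground truth of a generated cohort."""

    region_params: dict  # name -> {"onset_eyo", "slope"}
    biomarker_params: dict  # name -> parameter dict
    noiseless_tract_md: pd.DataFrame  # subject_id, measure, value (no noise)
    wmh_prob_noncarrier: np.ndarray
    gm_patches: dict  # tract -> boolean mask of the planted GM coupling patch
    config: CohortConfig


@dataclass
class CohortData:
    """Bundle of all generated arrays and tables."""

    subjects: pd.DataFrame
    md: np.ndarray  # (n_subjects, *grid_shape)
    skeleton_mask: np.ndarray
    atlas: TractAtlas
    wmh: np.ndarray  # (n_subjects, *grid_shape) boolean
    biomarkers: pd.DataFrame  # long: subject_id, measure, value
    gm_mask: np.ndarray
    gm_density: np.ndarray  # (n_subjects, *grid_shape)
    streamlines: dict  # tract -> list[Streamline]
    truth: SyntheticTruth
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def md_matrix(self) -> np.ndarray:
        """Subjects x skeleton-voxels MD matrix (C-order of mask voxels)."""
        return self.md[:, self.skeleton_mask]


def _effect_profile(eyo: np.ndarray, region: RegionSpec, config: CohortConfig) -> np.ndarray:
    """Carrier effect magnitude (MD units) at each EYO for one region."""
    if config.effect_shape == "ramp":
        return region.slope * np.clip(eyo - region.onset_eyo, 0.0, None)
    if config.effect_shape == "sigmoid":
        magnitude = region.slope * 20.0
        return magnitude * expit((eyo - region.onset_eyo) / config.sigmoid_width)
    raise ValueError(f"unknown effect_shape {config.effect_shape!r}")


def _make_subjects(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_carriers + config.n_noncarriers
    carrier = np.concatenate(
        [np.ones(config.n_carriers, bool), np.zeros(config.n_noncarriers, bool)]
    )
    lo, hi = config.eyo_range
    eyo = rng.uniform(lo, hi, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    education = np.clip(rng.normal(14.0, 3.0, size=n), 6.0, 22.0)
    # symptomatic status: carriers past their estimated onset
    cdr_positive = carrier & (eyo > 0)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "mutation_carrier": carrier,
            "eyo": eyo,
            "sex": sex,
            "education": education,
            "cdr_positive": cdr_positive,
        }
    )


def generate_cohort(config: CohortConfig | None = None) -> CohortData:
    """Generate a full synthetic cohort.

    Per-voxel MD is regional baseline + (carriers only) a monotone divergence
    term past the region's onset EYO + additive covariate terms + a
    per-subject offset + iid Gaussian voxel noise.  WMH masks are voxel-wise
    Bernoulli with probability increasing toward posterior/periventricular
    coordinates and, in carriers, with proximity to symptom onset.
    Biomarkers follow flat non-carrier distributions with monotone carrier
    departures.  Identical config and seed give bit-identical outputs.
    """
    config = config or CohortConfig()
    shape = tuple(config.grid_shape)
    rng = np.random.default_rng(config.seed)

    subjects = _make_subjects(config, rng)
    n = len(subjects)
    eyo = subjects["eyo"].to_numpy()
    carrier = subjects["mutation_carrier"].to_numpy(bool)
    sex = subjects["sex"].to_numpy()
    edu = subjects["education"].to_numpy()

    # --- atlas: labelled non-overlapping boxes -----------------------------
    labels = np.zeros(shape, dtype=np.int32)
    names = {}
    for i, region in enumerate(config.regions, start=1):
        box = region.box(shape)
        if np.any(labels[box] != 0):
            raise ValueError(f"region {region.name!r} overlaps another region")
        labels[box] = i
        names[i] = region.name
    atlas = TractAtlas(labels=labels, names=names)

    # --- skeleton: tract boxes + random filler voxels ----------------------
    skeleton = labels > 0
    target = int(round(config.skeleton_fraction * np.prod(shape)))
    deficit = target - int(skeleton.sum())
    if deficit > 0:
        candidates = np.flatnonzero(~skeleton.ravel())
        chosen = rng.choice(candidates, size=min(deficit, candidates.size), replace=False)
        flat = skeleton.ravel()
        flat[np.sort(chosen)] = True
        skeleton = flat.reshape(shape)

    # --- MD volumes --------------------------------------------------------
    cov_term = (
        config.covariate_effects.get("sex", 0.0) * sex
        + config.covariate_effects.get("education", 0.0) * (edu - 14.0)
    )
    subj_offset = rng.normal(0.0, config.subject_sd, size=n) if config.subject_sd else np.zeros(n)
    md = np.zeros((n,) + shape)
    md[:, skeleton] = config.baseline_md
    region_effects = {}
    for region in config.regions:
        eff = np.where(carrier, _effect_profile(eyo, region, config), 0.0)
        region_effects[region.name] = eff
        box = region.box(shape)
        md[(slice(None),) + box] += eff[:, None, None, None]
    md[:, skeleton] += (cov_term + subj_offset)[:, None]
    if config.noise_sd > 0:
        noise = rng.standard_normal((n,) + shape)
        if config.smooth_noise_sigma > 0:
            for i in range(n):
                f = gaussian_filter(noise[i], config.smooth_noise_sigma)
                sd = f.std()
                noise[i] = f / sd if sd > 0 else f
        md[:, skeleton] += config.noise_sd * noise[:, skeleton]
    md[:, ~skeleton] = 0.0

    # --- WMH masks ---------------------------------------------------------
    yy = np.arange(shape[1]) / max(shape[1] - 1, 1)
    zz = np.arange(shape[2]) / max(shape[2] - 1, 1)
    periv = np.exp(-(((zz - 0.5) / 0.35) ** 2))
    p0 = config.wmh_base_rate + config.posterior_gradient * (yy[:, None] ** 2) * periv[None, :]
    p0 = np.clip(p0, 0.0, 0.95)[None, :, :] * np.ones(shape)
    severity = np.where(carrier, np.clip(eyo + 10.0, 0.0, None) / 20.0, 0.0)
    wmh = np.zeros((n,) + shape, dtype=bool)
    for i in range(n):
        p = np.clip(p0 * (1.0 + config.wmh_eyo_gain * severity[i]), 0.0, 1.0)
        wmh[i] = rng.random(shape) < p

    # --- biomarkers --------------------------------------------------------
    icv = rng.normal(1.45e6, 1.3e5, size=n)
    rows = []
    for name, spec in config.biomarker_params.items():
        base = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)
        vals = base + np.where(carrier, spec.carrier_effect(eyo), 0.0)
        if name == "hippocampal_volume":
            vals = vals + 0.003 * (icv - icv.mean())
        for sid, v in zip(subjects["subject_id"], vals):
            rows.append({"subject_id": sid, "measure": name, "value": float(v)})
    for sid, v in zip(subjects["subject_id"], icv):
        rows.append({"subject_id": sid, "measure": "icv", "value": float(v)})
    biomarkers = pd.DataFrame(rows)

    # --- grey matter slab, planted coupling patches, density maps ----------
    x_lo = int(round(config.gm_slab_x[0] * shape[0]))
    x_hi = int(round(config.gm_slab_x[1] * shape[0]))
    gm_mask = np.zeros(shape, dtype=bool)
    gm_mask[x_lo:x_hi, :, :] = True
    gm_patches = {}
    ref_scale = max(r.slope for r in config.regions) * 20.0 or 1.0
    gm_density = np.zeros((n,) + shape)
    gm_subj = rng.normal(0.0, 0.02, size=n)
    gm_density[:, gm_mask] = config.gm_baseline_density + gm_subj[:, None]
    for region in config.regions:
        box = region.box(shape)
        patch = np.zeros(shape, dtype=bool)
        patch[x_lo:x_hi, box[1], box[2]] = True
        gm_patches[region.name] = patch
        z = region_effects[region.name] / ref_scale  # 0..~1 severity
        gm_density[:, patch] -= (config.gm_coupling * 0.15 * z)[:, None]
    if config.gm_noise_sd > 0:
        gm_density[:, gm_mask] += rng.normal(
            0.0, config.gm_noise_sd, size=(n, int(gm_mask.sum()))
        )
    gm_density = np.clip(gm_density, 0.0, 1.2)

    # --- streamlines: bundles ending just before the GM slab ---------------
    streamlines = {}
    for region in config.regions:
        box = region.box(shape)
        bundle = []
        for k in range(config.n_streamlines_per_tract):
            y = rng.uniform(box[1].start, box[1].stop - 1)
            z = rng.uniform(box[2].start, box[2].stop - 1)
            x_end = x_lo - 1.0  # terminate one voxel before the slab
            xs = np.arange(x_end - 9.0, x_end + 1.0)
            ys = np.full_like(xs, y)
            if k % 3 == 2:  # gently curved fibres
                ys = y + 0.8 * np.sin(np.linspace(0, np.pi, xs.size))
            pts = np.column_stack([xs, ys, np.full_like(xs, z)])
            bundle.append(Streamline(points=pts))
        streamlines[region.name] = bundle

    # --- truth -------------------------------------------------------------
    truth_rows = []
    for region in config.regions:
        box = region.box(shape)
        noiseless = config.baseline_md + region_effects[region.name] + cov_term
        for sid, v in zip(subjects["subject_id"], noiseless):
            truth_rows.append({"subject_id": sid, "measure": region.name, "value": float(v)})
    truth = SyntheticTruth(
        region_params={
            r.name: {"onset_eyo": r.onset_eyo, "slope": r.slope} for r in config.regions
        },
        biomarker_params={k: asdict(v) for k, v in config.biomarker_params.items()},
        noiseless_tract_md=pd.DataFrame(truth_rows),
        wmh_prob_noncarrier=p0,
        gm_patches=gm_patches,
        config=config,
    )

    return CohortData(
        subjects=subjects,
        md=md,
        skeleton_mask=skeleton,
        atlas=atlas,
        wmh=wmh,
        biomarkers=biomarkers,
        gm_mask=gm_mask,
        gm_density=gm_density,
        streamlines=streamlines,
        truth=truth,
    )


@dataclass
class GMSlabGeometry:
    """An axis-aligned grey-matter slab inside a voxel grid."""

    shape: tuple = (24, 16, 16)
    axis: int = 0
    lo: int = 16
    hi: int = 22

    def __post_init__(self) -> None:
        if self.hi <= self.lo:
            raise ValueError("degenerate slab: zero thickness")

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        sl = [slice(None)] * 3
        sl[self.axis] = slice(self.lo, self.hi)
        m[tuple(sl)] = True
        return m


def generate_streamline_set(
    n: int, slab: GMSlabGeometry | None = None, seed: int = 0
) -> tuple:
    """Generate a fixture streamline set with known projection geometry.

    Returns ``(streamlines, gm_mask, truth)`` where ``truth`` is a list of
    dicts per streamline: kind (straight/curved/away), expected GM entry
    voxel for the last endpoint (or None when the fibre points away from the
    slab).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    slab = slab or GMSlabGeometry()
    rng = np.random.default_rng(seed)
    gm_mask = slab.mask()
    shape = slab.shape
    streamlines, truth = [], []
    for k in range(n):
        kind = ("straight", "curved", "away")[k % 3]
        y = float(rng.integers(2, shape[1] - 2))
        z = float(rng.integers(2, shape[2] - 2))
        if kind == "away":
            xs = np.arange(slab.lo - 2.0, slab.lo - 12.0, -1.0)  # marching -x
            entry = None
        else:
            xs = np.arange(slab.lo - 10.0, slab.lo)  # ends 1 voxel before slab
            entry = (slab.lo, int(round(y)), int(round(z)))
        ys = np.full_like(xs, y)
        if kind == "curved":
            ys = y + 0.8 * np.sin(np.linspace(0, np.pi, xs.size))
        pts = np.column_stack([xs, ys, np.full_like(xs, z)])
        streamlines.append(Streamline(points=pts))
        truth.append({"kind": kind, "entry_voxel": entry})
    return streamlines, gm_mask, truth
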