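"""Synthetic study generator.

Emulates a three-group (Heat / Salt / Sugar) cue-conditioning experiment:
each subject sees High/Low visual cues followed by calibrated stimulus
outcomes over 5 fMRI runs of 12 trials (10 conditioning trials with a
deterministic cue-outcome pairing, then 50 test trials in which each cue is
followed by its conditioned level or a medium-intensity outcome with
probability 0.5).  The generator produces the trial design, mixed-effects
intensity/valence ratings on visual-analogue scales, per-trial voxelwise
coefficient images with planted mediator regions, and synthetic signature
weight maps, so the downstream estimators can be validated by parameter
recovery without any human data.

Coding conventions (shared with the analysis side):
    stimulus level Low/Medium/High -> -1 / 0 / +1
    cue High/Low                   -> +0.5 / -0.5  (mean-centered)
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

GROUPS = ("Heat", "Salt", "Sugar")
LEVEL_CODE = {"Low": -1.0, "Medium": 0.0, "High": 1.0}
CUE_CODE = {"High": 0.5, "Low": -0.5}

#: columns of a TrialTable, in canonical order
TRIAL_COLUMNS = [
    "subject", "group", "run", "trial", "cue", "level",
    "intensity", "valence", "missing",
]


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Trial schedule of the two-day conditioning experiment (Day-2 task)."""

    n_subjects_per_group: int = 10
    groups: Sequence[str] = GROUPS
    n_runs: int = 5
    trials_per_run: int = 12
    n_conditioning: int = 10
    n_test: int = 50
    medium_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_runs * self.trials_per_run != self.n_conditioning + self.n_test:
            raise ConfigurationError(
                f"n_runs*trials_per_run ({self.n_runs * self.trials_per_run}) "
                f"!= n_conditioning+n_test ({self.n_conditioning + self.n_test})"
            )
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ConfigurationError(f"unknown groups: {sorted(unknown)}")
        if not 0.0 <= self.medium_prob <= 1.0:
            raise ConfigurationError("medium_prob must be in [0, 1]")

    @property
    def n_trials(self) -> int:
        return self.n_conditioning + self.n_test


def _balanced_cues(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random order of n cues with High/Low as balanced as n allows."""
    half = n // 2
    cues = np.array(["High"] * half + ["Low"] * (n - half), dtype=object)
    rng.shuffle(cues)
    return cues


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Generate the trial schedule for every subject; ratings left NaN.

    Conditioning trials come first and pair each cue deterministically with
    its own level (High cue -> High level, Low -> Low).  On test trials each
    cue is followed by the conditioned level or a Medium stimulus with
    probability ``spec.medium_prob``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group in spec.groups:
        for s in range(spec.n_subjects_per_group):
            subject = f"{group.lower()}{s + 1:02d}"
            cond_cues = _balanced_cues(spec.n_conditioning, rng)
            test_cues = _balanced_cues(spec.n_test, rng)
            cues = np.concatenate([cond_cues, test_cues])
            levels = np.empty(spec.n_trials, dtype=object)
            levels[: spec.n_conditioning] = cond_cues  # cue == level name
            medium = rng.random(spec.n_test) < spec.medium_prob
            levels[spec.n_conditioning:] = np.where(medium, "Medium", test_cues)
            for t in range(spec.n_trials):
                rows.append({
                    "subject": subject,
                    "group": group,
                    "run": t // spec.trials_per_run + 1,
                    "trial": t + 1,
                    "cue": cues[t],
                    "level": levels[t],
                    "intensity": np.nan,
                    "valence": np.nan,
                    "missing": False,
                })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatingParams:
    """Fixed and random effects of the rating-generating mixed model.

    ``paper_defaults`` plants the published fixed-effect estimates: the
    stimulus-level slopes on intensity (1.940) and valence (1.662, negative
    for the aversive Heat/Salt groups and positive for Sugar), the cue
    effects on intensity (0.301) and valence (-0.201), and a Heat-vs-Salt
    group contrast of -1.146 rating units on intensity.
    """

    intensity_intercepts: Mapping[str, float]
    intensity_level_slope: float
    intensity_cue_effect: float
    intensity_drift: float
    valence_intercepts: Mapping[str, float]
    valence_level_slope: float
    valence_level_signs: Mapping[str, float]
    valence_cue_effect: float
    valence_drift: float
    subject_intercept_sd: float = 1.0
    cue_slope_sd: float = 0.2
    residual_sd: float = 1.2
    missing_rate: float = 0.05
    missing_cap: float = 0.13

    def __post_init__(self):
        for name in ("subject_intercept_sd", "cue_slope_sd", "residual_sd",
                     "missing_rate", "missing_cap"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @classmethod
    def paper_defaults(cls) -> "RatingParams":
        return cls(
            intensity_intercepts={"Heat": 4.354, "Salt": 5.5, "Sugar": 5.5},
            intensity_level_slope=1.940,
            intensity_cue_effect=0.301,
            intensity_drift=-0.005,
            valence_intercepts={"Heat": -0.505, "Salt": -0.505, "Sugar": 2.956},
            valence_level_slope=1.662,
            valence_level_signs={"Heat": -1.0, "Salt": -1.0, "Sugar": 1.0},
            valence_cue_effect=-0.201,
            valence_drift=0.0,
        )

    @classmethod
    def noiseless(cls, **overrides) -> "RatingParams":
        """paper_defaults with every random term zeroed (deterministic limit)."""
        base = cls.paper_defaults()
        zeros = dict(subject_intercept_sd=0.0, cue_slope_sd=0.0,
                     residual_sd=0.0, missing_rate=0.0,
                     intensity_drift=0.0, valence_drift=0.0)
        zeros.update(overrides)
        return dataclasses.replace(base, **zeros)


def generate_ratings(table: pd.DataFrame, params: RatingParams,
                     seed: int) -> pd.DataFrame:
    """Fill intensity (0-10) and valence (-10..10) ratings into a design table.

    Ratings follow a linear mixed model in the centered level / cue / trial
    codes with per-subject random intercepts and cue slopes, then are clipped
    at the scale bounds.  Missing trials are independent Bernoulli draws,
    capped per subject; their ratings are set to NaN.
    """
    unknown = set(table["group"]) - set(GROUPS)
    if unknown:
        raise ConfigurationError(f"unknown group labels: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = table.copy()
    lev = out["level"].map(LEVEL_CODE).to_numpy(float)
    cue = out["cue"].map(CUE_CODE).to_numpy(float)

    n_clipped = 0
    for subject, idx in out.groupby("subject", sort=False).groups.items():
        idx = np.asarray(idx)
        group = out.loc[idx[0], "group"]
        n = idx.size
        t_c = out.loc[idx, "trial"].to_numpy(float)
        t_c = t_c - t_c.mean()
        u_int = rng.normal(0.0, params.subject_intercept_sd, size=2)
        u_cue = rng.normal(0.0, params.cue_slope_sd, size=2)
        eps = rng.normal(0.0, params.residual_sd, size=(2, n))

        mu_i = (params.intensity_intercepts[group]
                + params.intensity_level_slope * lev[idx]
                + (params.intensity_cue_effect + u_cue[0]) * cue[idx]
                + params.intensity_drift * t_c + u_int[0] + eps[0])
        sign = params.valence_level_signs[group]
        mu_v = (params.valence_intercepts[group]
                + sign * params.valence_level_slope * lev[idx]
                + (params.valence_cue_effect + u_cue[1]) * cue[idx]
                + params.valence_drift * t_c + u_int[1] + eps[1])

        intensity = np.clip(mu_i, 0.0, 10.0)
        valence = np.clip(mu_v, -10.0, 10.0)
        n_clipped += int((intensity != mu_i).sum() + (valence != mu_v).sum())

        miss = rng.random(n) < params.missing_rate
        cap = int(np.floor(params.missing_cap * n))
        if miss.sum() > cap:
            keep = rng.choice(np.flatnonzero(miss), size=cap, replace=False)
            miss = np.zeros(n, dtype=bool)
            miss[keep] = True
        intensity[miss] = np.nan
        valence[miss] = np.nan

        out.loc[idx, "intensity"] = intensity
        out.loc[idx, "valence"] = valence
        out.loc[idx, "missing"] = miss
    out.attrs["n_clipped"] = n_clipped
    return out


# ---------------------------------------------------------------------------
# brain images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MediatorRegion:
    """A set of voxels carrying a planted cue->activation->rating pathway."""

    name: str
    coords: np.ndarray            # (n_voxels, 3) integer indices
    a_mean: float = 0.0           # cue -> activation effect, population mean
    a_sd: float = 0.0             # between-subject SD of a_i
    b_mean: float = 0.0           # activation -> rating slope, population mean
    b_sd: float = 0.0
    ab_corr: float = 0.0          # correlation of (a_i, b_i) across subjects

    def __post_init__(self):
        object.__setattr__(self, "coords",
                           np.atleast_2d(np.asarray(self.coords, dtype=int)))
        if not -1.0 <= self.ab_corr <= 1.0:
            raise ConfigurationError("ab_corr must be in [-1, 1]")


@dataclass(frozen=True)
class BrainSimSpec:
    """Geometry and planted effects for simulated single-trial images."""

    shape: tuple = (12, 12, 12)
    mask: np.ndarray | None = None
    regions: Sequence[MediatorRegion] = ()
    region_noise_sd: float = 1.0  # trial-level activation noise within a region
    voxel_noise_sd: float = 1.0   # independent voxel nuisance noise
    rating_outcome: str = "intensity"
    seed: int = 0

    def __post_init__(self):
        mask = self.mask
        if mask is None:
            mask = np.ones(self.shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != tuple(self.shape):
            raise ConfigurationError("mask shape must equal grid shape")
        object.__setattr__(self, "mask", mask)
        for region in self.regions:
            c = region.coords
            if (c < 0).any() or (c >= np.asarray(self.shape)).any():
                raise ConfigurationError(f"region {region.name} outside grid")
            if not mask[tuple(c.T)].all():
                raise ConfigurationError(f"region {region.name} outside mask")
        if self.region_noise_sd < 0 or self.voxel_noise_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")


@dataclass
class BrainDataset:
    """Per-subject stacks of per-trial coefficient images plus ground truth."""

    images: dict                  # subject -> (nx, ny, nz, n_trials) array
    table: pd.DataFrame           # copy of the input with mediator coupling added
    truth: pd.DataFrame           # subject x region planted (a_i, b_i)
    mask: np.ndarray
    affine: np.ndarray

    @property
    def subjects(self):
        return list(self.images)


def generate_brain(table: pd.DataFrame, spec: BrainSimSpec,
                   seed: int) -> BrainDataset:
    """Simulate per-trial coefficient images with planted mediator regions.

    Within each region, trial activation is ``m_t = a_i * x_t + eta_t`` where
    ``x_t`` is the centered cue code and ``eta_t`` is trial-level noise; the
    subject's rating is incremented by ``b_i * m_t`` so the region genuinely
    mediates the cue effect.  Subject slopes (a_i, b_i) are drawn bivariate
    normal with the configured means, SDs and correlation.  Voxels outside
    every region carry pure nuisance noise.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    cue = out["cue"].map(CUE_CODE).to_numpy(float)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])

    images: dict = {}
    truth_rows = []
    subjects = out["subject"].unique()
    for subject in subjects:
        idx = np.flatnonzero((out["subject"] == subject).to_numpy())
        n = idx.size
        img = rng.normal(0.0, spec.voxel_noise_sd,
                         size=spec.shape + (n,))
        img[~spec.mask] = 0.0
        for region in spec.regions:
            cov = region.ab_corr * region.a_sd * region.b_sd
            a_i, b_i = rng.multivariate_normal(
                [region.a_mean, region.b_mean],
                [[region.a_sd ** 2, cov], [cov, region.b_sd ** 2]])
            eta = rng.normal(0.0, spec.region_noise_sd, size=n)
            m = a_i * cue[idx] + eta
            cx, cy, cz = region.coords.T
            img[cx, cy, cz, :] += m[None, :]
            col = spec.rating_outcome
            out.loc[out.index[idx], col] = (
                out.loc[out.index[idx], col].to_numpy(float) + b_i * m)
            truth_rows.append({"subject": subject, "region": region.name,
                               "a": a_i, "b": b_i})
        images[subject] = img
    truth = pd.DataFrame(truth_rows,
                         columns=["subject", "region", "a", "b"])
    return BrainDataset(images=images, table=out, truth=truth,
                        mask=spec.mask.copy(), affine=affine)


# ---------------------------------------------------------------------------
# signature patterns
# ---------------------------------------------------------------------------

def generate_pattern(spec: BrainSimSpec, name: str, kind: str = "uniform",
                     region: str | None = None, seed: int = 0):
    """Synthetic signature weight map supported on the analysis mask.

    kind='uniform' gives weight 1 on every masked voxel; 'region' puts an
    indicator on the named mediator region; 'random' draws standard-normal
    weights on the mask.  Stands in for published weight maps, which are
    external artifacts.
    """
    from .signatures import SignaturePattern  # local import, no cycle at load

    if not spec.mask.any():
        raise ConfigurationError("empty mask")
    weights = np.zeros(spec.shape, dtype=float)
    if kind == "uniform":
        weights[spec.mask] = 1.0
    elif kind == "random":
        rng = np.random.default_rng(seed)
        weights[spec.mask] = rng.standard_normal(int(spec.mask.sum()))
    elif kind == "region":
        match = [r for r in spec.regions if r.name == region]
        if not match:
            raise ConfigurationError(f"unknown region {region!r}")
        cx, cy, cz = match[0].coords.T
        weights[cx, cy, cz] = 1.0
    else:
        raise ConfigurationError(f"unknown pattern kind {kind!r}")
    return SignaturePattern(name=name, weights=weights,
                            support=spec.mask.copy())


# ---------------------------------------------------------------------------
# motion quality control
# ---------------------------------------------------------------------------

def qc_exclude_motion(summaries: Mapping[str, float],
                      threshold: float = 0.3):
    """Exclude subjects whose mean Euclidean-norm motion derivative is > 0.3.

    The rule is strictly greater-than: a summary exactly at the threshold is
    retained.  Returns (retained subject list, report dict).
    """
    retained, excluded = [], []
    for subject, value in summaries.items():
        if value < 0:
            raise ValueError(f"negative motion summary for {subject}: {value}")
        (excluded if value > threshold else retained).append(subject)
    report = {"threshold": threshold, "excluded": excluded,
              "n_excluded": len(excluded), "n_retained": len(retained)}
    return retained, report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_trial_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing_cols = set(TRIAL_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ConfigurationError(f"trial table missing columns: {sorted(missing_cols)}")
    return table[TRIAL_COLUMNS]


def write_brain_nifti(dataset: BrainDataset, directory) -> dict:
    """One 4D NIfTI per subject (trial on the 4th axis) plus the mask."""
    import os

    import nibabel as nib

    paths = {}
    os.makedirs(directory, exist_ok=True)
    mask_path = os.path.join(directory, "mask.nii")
    nib.save(nib.Nifti1Image(dataset.mask.astype(np.uint8), dataset.affine),
             mask_path)
    paths["mask"] = mask_path
    for subject, img in dataset.images.items():
        p = os.path.join(directory, f"{subject}_trial_betas.nii")
        nib.save(nib.Nifti1Image(img.astype(np.float64), dataset.affine), p)
        paths[subject] = p
    return paths
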