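"""Multilevel (subject-level) mediation with bootstrap inference.

The model asks whether trial-by-trial brain activation (M) explains the
effect of a predictive cue (X, High-Low contrast code) on perception (Y).
Within each subject, ordinary least squares gives

    path a:  M = i1 + a X            (cue -> activation)
    path b, c': Y = i2 + c' X + b M  (activation -> rating, controlling cue)
    path c:  Y = i3 + c X            (total effect)

and the OLS nested-model identity c - c' = a * b holds per subject.  At the
population level the mediation (indirect) effect is

    ab = mean(a_i) * mean(b_i) + cov_n(a_i, b_i) = mean(a_i * b_i),

where cov_n uses the 1/n denominator so the decomposition is exact: a
covariance between subjects' a and b paths contributes to mediation even
when either average path is null.  Significance comes from a percentile
bootstrap over subjects, which accounts for that covariance.

Cue coding: for intensity outcomes X is High-Low for every group; for
valence outcomes the contrast is reversed (Low-High) in the aversive Heat
and Salt groups so that X aligns with "more pleasant" in all groups.

Second level: moderated mediation regresses subject path coefficients on a
between-subject design (Group, Modality, Aversiveness dummies), with
bootstrap p-values; the intercept of a design containing a factor is the
path estimate "controlling for" that factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SingularFitError
from .synthetic import CUE_CODE

DEFAULT_N_BOOT = 10_000

#: sign applied to the High-Low cue contrast, per (group, outcome kind)
_VALENCE_SIGN = {"Heat": -1.0, "Salt": -1.0, "Sugar": 1.0}


def code_cue_contrast(group: str, outcome_kind: str) -> float:
    """Sign of the cue contrast: X = sign * (+0.5 High / -0.5 Low).

    Intensity models use High-Low (+1) for all groups.  Valence models
    reverse the contrast (Low-High) for Heat and Salt, whose high cue
    predicts the more unpleasant outcome, so that X predicts increased
    pleasantness in every group.
    """
    if group not in _VALENCE_SIGN:
        raise ConfigurationError(f"unknown group {group!r}")
    if outcome_kind == "intensity":
        return 1.0
    if outcome_kind == "valence":
        return _VALENCE_SIGN[group]
    raise ConfigurationError(f"unknown outcome kind {outcome_kind!r}")


def cue_to_x(cues, group: str, outcome_kind: str) -> np.ndarray:
    """Map High/Low cue labels to the signed centered contrast code."""
    sign = code_cue_contrast(group, outcome_kind)
    return sign * np.asarray([CUE_CODE[c] for c in cues], dtype=float)


# ---------------------------------------------------------------------------
# subject level
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectPaths:
    """Per-subject OLS path coefficients (scalars or per-voxel arrays)."""

    a: np.ndarray | float
    b: np.ndarray | float
    c: np.ndarray | float
    c_prime: np.ndarray | float
    subject: str = ""


def _paths_2d(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Closed-form OLS paths for m of shape (n_trials, n_cols).

    The same code path serves scalar and voxelwise fits, so a single-voxel
    voxelwise call is bitwise identical to the scalar pipeline.  Columns
    where the mediator is collinear with x (zero residual variance) come
    back NaN.
    """
    xc = x - x.mean()
    mc = m - m.mean(axis=0)
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise SingularFitError("cue contrast X is constant within subject")
    sxm = xc @ mc
    smm = (mc * mc).sum(axis=0)
    sxy = float(xc @ yc)
    smy = yc @ mc
    a = sxm / sxx
    c = sxy / sxx
    det = sxx * smm - sxm * sxm
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(det > 0, (sxx * smy - sxm * sxy) / det, np.nan)
        c_prime = np.where(det > 0, (sxy * smm - sxm * smy) / det, np.nan)
    return a, b, np.full_like(a, c), c_prime


def fit_subject_paths(x, m, y, subject: str = "") -> SubjectPaths:
    """OLS path coefficients (a, b, c, c') for one subject's trials.

    Requires >= 3 trials, non-constant x and a mediator not perfectly
    collinear with x.  The identity c - c' = a*b holds to rounding.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (x.shape == y.shape and x.ndim == 1 and m.shape[0] == x.size):
        raise ValueError("x, m, y must be aligned per-trial vectors")
    if x.size < 3:
        raise SingularFitError("need >= 3 trials per subject")
    scalar = m.ndim == 1
    a, b, c, cp = _paths_2d(x, m[:, None] if scalar else m, y)
    if scalar:
        if np.isnan(b[0]):
            raise SingularFitError("mediator constant or collinear with X")
        return SubjectPaths(a=float(a[0]), b=float(b[0]), c=float(c[0]),
                            c_prime=float(cp[0]), subject=subject)
    return SubjectPaths(a=a, b=b, c=c, c_prime=cp, subject=subject)


# ---------------------------------------------------------------------------
# population level
# ---------------------------------------------------------------------------

@dataclass
class MediationResult:
    a: np.ndarray | float
    b: np.ndarray | float
    c: np.ndarray | float
    c_prime: np.ndarray | float
    ab: np.ndarray | float
    cov_ab: np.ndarray | float
    n_subjects: int
    p: dict = field(default_factory=dict)     # stat name -> p-value(s)
    n_boot: int = 0
    seed: int | None = None
    moderators: dict = field(default_factory=dict)
    n_redrawn: int = 0


def _stack(paths: Sequence[SubjectPaths]):
    A = np.stack([np.atleast_1d(np.asarray(p.a, dtype=float)) for p in paths])
    B = np.stack([np.atleast_1d(np.asarray(p.b, dtype=float)) for p in paths])
    C = np.stack([np.atleast_1d(np.asarray(p.c, dtype=float)) for p in paths])
    Cp = np.stack([np.atleast_1d(np.asarray(p.c_prime, dtype=float))
                   for p in paths])
    return A, B, C, Cp


def population_mediation(paths: Sequence[SubjectPaths]) -> MediationResult:
    """Population path means and the covariance-corrected mediation effect.

    ab = mean(a)*mean(b) + cov_n(a, b), with cov_n the 1/n-denominator
    covariance across subjects; algebraically ab = mean(a_i * b_i).
    """
    if len(paths) < 2:
        raise SingularFitError("population mediation needs >= 2 subjects")
    A, B, C, Cp = _stack(paths)
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    ab = (A * B).mean(axis=0)
    cov_ab = ab - mean_a * mean_b
    squeeze = A.shape[1] == 1

    def _out(v):
        return float(v[0]) if squeeze else v

    return MediationResult(
        a=_out(mean_a), b=_out(mean_b), c=_out(C.mean(axis=0)),
        c_prime=_out(Cp.mean(axis=0)), ab=_out(ab), cov_ab=_out(cov_ab),
        n_subjects=len(paths))


def _resample_counts(n: int, n_boot: int, rng: np.random.Generator):
    """Multinomial subject-resampling weights; degenerate draws redrawn.

    A draw consisting of a single unique subject leaves every path variance
    undefined, so such rows are redrawn (count reported for logging).
    """
    idx = rng.integers(0, n, size=(n_boot, n))
    n_redrawn = 0
    if n > 1:
        for _ in range(100):
            bad = np.flatnonzero((idx == idx[:, :1]).all(axis=1))
            if bad.size == 0:
                break
            n_redrawn += bad.size
            idx[bad] = rng.integers(0, n, size=(bad.size, n))
    counts = np.zeros((n_boot, n))
    np.add.at(counts, (np.arange(n_boot)[:, None], idx), 1.0)
    return counts / n, n_redrawn


def _two_tailed_p(draws: np.ndarray, n_boot: int) -> np.ndarray:
    """Percentile bootstrap p: 2 * min(P(<=0), P(>=0)), floored at 1/n_boot."""
    lo = (draws <= 0).mean(axis=0)
    hi = (draws >= 0).mean(axis=0)
    p = 2.0 * np.minimum(lo, hi)
    return np.clip(p, 1.0 / n_boot, 1.0)


def bootstrap_test(paths: Sequence[SubjectPaths],
                   n_boot: int = DEFAULT_N_BOOT, seed: int | None = None,
                   ) -> MediationResult:
    """Subject-level percentile bootstrap of a, b, c, c' and ab.

    Subjects are resampled with replacement n_boot times; each draw
    recomputes the population means and the covariance-corrected ab.  The
    two-tailed p-value is twice the smaller tail fraction, floored at
    1/n_boot.  Deterministic under a fixed seed.
    """
    import warnings

    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is too small for stable p-values",
                      stacklevel=2)
    result = population_mediation(paths)
    A, B, C, Cp = _stack(paths)
    n = A.shape[0]
    rng = np.random.default_rng(seed)
    W, n_redrawn = _resample_counts(n, n_boot, rng)
    squeeze = A.shape[1] == 1

    draws = {
        "a": W @ A,
        "b": W @ B,
        "c": W @ C,
        "c_prime": W @ Cp,
        "ab": W @ (A * B),     # = mean(a)mean(b) + cov_n per resample
    }
    for name, d in draws.items():
        p = _two_tailed_p(d, n_boot)
        result.p[name] = float(p[0]) if squeeze else p
    result.n_boot = n_boot
    result.seed = seed
    result.n_redrawn = n_redrawn
    return result


# ---------------------------------------------------------------------------
# moderated mediation (level 2)
# ---------------------------------------------------------------------------

def level2_design(groups: Sequence[str], factors: Sequence[str] = ("group",),
                  ) -> pd.DataFrame:
    """Between-subject design with intercept and documented dummy codes.

    'group' adds Heat>Salt and Salt>Sugar dummies; 'modality' the Heat-vs-
    Tastes dummy (Heat=1); 'aversiveness' the Appetitive-vs-Aversive dummy
    (Sugar=1).
    """
    groups = list(groups)
    cols = {"intercept": np.ones(len(groups))}
    for factor in factors:
        if factor == "group":
            cols["heat_gt_salt"] = np.array(
                [1.0 if g == "Heat" else 0.0 for g in groups])
            cols["salt_gt_sugar"] = np.array(
                [1.0 if g == "Salt" else 0.0 for g in groups])
        elif factor == "modality":
            cols["modality_heat"] = np.array(
                [1.0 if g == "Heat" else 0.0 for g in groups])
        elif factor == "aversiveness":
            cols["appetitive"] = np.array(
                [1.0 if g == "Sugar" else 0.0 for g in groups])
        else:
            raise ConfigurationError(f"unknown level-2 factor {factor!r}")
    return pd.DataFrame(cols)


def moderated_mediation(paths: Sequence[SubjectPaths], design: pd.DataFrame,
                        n_boot: int = DEFAULT_N_BOOT,
                        seed: int | None = None) -> dict:
    """Second-level OLS of subject paths on moderator codes, with bootstrap.

    For each path quantity (a, b, subjectwise ab = a_i*b_i, c, c') the
    subject coefficients are regressed on the level-2 design; moderator
    p-values come from resampling subjects (rows of design and outcome
    jointly).  The intercept is the adjusted path estimate controlling for
    the included factors.
    """
    if "intercept" not in design.columns:
        raise ConfigurationError("level-2 design must include an intercept")
    Z = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ConfigurationError("collinear level-2 design")
    A, B, C, Cp = _stack(paths)
    if A.shape[1] != 1:
        raise ValueError("moderated mediation expects scalar subject paths")
    outcomes = {"a": A[:, 0], "b": B[:, 0], "ab": (A * B)[:, 0],
                "c": C[:, 0], "c_prime": Cp[:, 0]}
    n = Z.shape[0]
    rng = np.random.default_rng(seed)
    pinv = np.linalg.pinv(Z)
    results = {}
    idx = rng.integers(0, n, size=(n_boot, n))
    for name, v in outcomes.items():
        coef = pinv @ v
        boot = np.empty((n_boot, Z.shape[1]))
        for r in range(n_boot):
            Zi = Z[idx[r]]
            try:
                boot[r] = np.linalg.lstsq(Zi, v[idx[r]], rcond=None)[0]
            except np.linalg.LinAlgError:
                boot[r] = np.nan
        p = _two_tailed_p(boot[~np.isnan(boot).any(axis=1)], n_boot)
        results[name] = {
            "estimate": pd.Series(coef, index=design.columns),
            "p": pd.Series(p, index=design.columns),
        }
    return results


# ---------------------------------------------------------------------------
# voxelwise wrapper
# ---------------------------------------------------------------------------

def voxelwise_mediation(betas: Mapping[str, np.ndarray],
                        x: Mapping[str, np.ndarray],
                        y: Mapping[str, np.ndarray],
                        n_boot: int = DEFAULT_N_BOOT,
                        seed: int | None = None) -> MediationResult:
    """Run the scalar mediation pipeline independently at every voxel.

    ``betas[s]`` is subject s's (n_trials, n_voxels) single-trial matrix
    (excluded/missing trials already removed), with ``x[s]`` and ``y[s]``
    the aligned cue codes and ratings.  Estimates and bootstrap p maps come
    back as length-n_voxels arrays.  Voxels where any subject's mediator is
    collinear with the cue are NaN (count available from the result arrays).
    """
    paths = [fit_subject_paths(x[s], betas[s], y[s], subject=s)
             for s in betas]
    return bootstrap_test(paths, n_boot=n_boot, seed=seed)


def dataset_mediation_inputs(dataset, outcome_kind: str = "intensity",
                             medium_only: bool = True):
    """Assemble (betas, x, y) mappings for voxelwise mediation.

    Uses the synthetic BrainDataset: flattens each subject's image stack to
    (n_trials, n_masked_voxels), restricts to medium-level, non-missing
    trials, and applies the outcome-appropriate cue contrast coding.
    """
    table = dataset.table
    mask = dataset.mask
    betas, xs, ys = {}, {}, {}
    for subject, img in dataset.images.items():
        sub = table[table["subject"] == subject].reset_index(drop=True)
        keep = ~sub["missing"].to_numpy(bool)
        if medium_only:
            keep &= (sub["level"] == "Medium").to_numpy()
        keep &= ~sub[outcome_kind].isna().to_numpy()
        group = sub.loc[0, "group"]
        betas[subject] = img[mask].T[keep]
        xs[subject] = cue_to_x(sub.loc[keep, "cue"], group, outcome_kind)
        ys[subject] = sub.loc[keep, outcome_kind].to_numpy(float)
    return betas, xs, ys
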