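"""Psychophysical calibration: stimulus-response fits and level selection.

On the calibration visit each participant rates the intensity of graded
stimuli (temperatures or tastant concentrations).  A per-subject linear
regression of rating on stimulus magnitude is fit; participants whose r^2
strictly exceeds 0.4 are eligible, and the fitted line is inverted to find
the magnitudes predicted to evoke low (2), medium (5) and high (8) intensity
on the 0-10 visual-analogue scale.  Magnitudes above a delivery maximum
(e.g. 1M sucrose) are clamped and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (DegenerateDesignError, InsufficientDataError,
                     NonInvertibleCalibrationError)

ELIGIBILITY_R2 = 0.4
DEFAULT_TARGETS = (2.0, 5.0, 8.0)


@dataclass(frozen=True)
class CalibrationFit:
    intercept: float
    slope: float
    r_squared: float
    n_trials: int
    modality: str = ""


@dataclass(frozen=True)
class LevelSelection:
    targets: tuple
    magnitudes: tuple
    clamped: tuple
    max_magnitude: float | None = None


def fit_stimulus_response(magnitudes, ratings, modality: str = "",
                          aggregate: bool = True) -> CalibrationFit:
    """Ordinary least-squares line relating stimulus magnitude to rating.

    By default replicate trials at the same magnitude are averaged first
    (the fit relates magnitude to the *mean* rating); pass aggregate=False
    to fit raw trials.  r^2 is the squared sample correlation, defined as 0
    when the ratings have zero variance.
    """
    x = np.asarray(magnitudes, dtype=float)
    y = np.asarray(ratings, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("magnitudes and ratings must be equal-length vectors")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size >= 2 and np.ptp(x) == 0.0:
        raise DegenerateDesignError("all stimulus magnitudes identical")
    if aggregate and x.size:
        frame = pd.DataFrame({"x": x, "y": y}).groupby("x", sort=True)["y"].mean()
        x, y = frame.index.to_numpy(), frame.to_numpy()
    if x.size < 2:
        raise InsufficientDataError(f"need >=2 usable pairs, got {x.size}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise DegenerateDesignError("all stimulus magnitudes identical")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r_squared = 0.0 if syy == 0.0 else sxy * sxy / (sxx * syy)
    return CalibrationFit(intercept=intercept, slope=slope,
                          r_squared=r_squared, n_trials=int(x.size),
                          modality=modality)


def check_eligibility(fit: CalibrationFit,
                      threshold: float = ELIGIBILITY_R2) -> bool:
    """Eligible iff r^2 strictly exceeds the threshold (default 0.4)."""
    return fit.r_squared > threshold


def select_levels(fit: CalibrationFit,
                  targets: Sequence[float] = DEFAULT_TARGETS,
                  max_magnitude: float | None = None) -> LevelSelection:
    """Invert the fitted line to the magnitudes predicted to hit the targets.

    magnitude = (target - intercept) / slope; any magnitude above
    ``max_magnitude`` (e.g. the 1M sucrose delivery cap) is replaced by the
    maximum and flagged as clamped.
    """
    if fit.slope <= 0:
        raise NonInvertibleCalibrationError(
            f"slope {fit.slope} <= 0; perception must increase with magnitude")
    mags, clamped = [], []
    for target in targets:
        m = (target - fit.intercept) / fit.slope
        if max_magnitude is not None and m > max_magnitude:
            mags.append(float(max_magnitude))
            clamped.append(True)
        else:
            mags.append(float(m))
            clamped.append(False)
    return LevelSelection(targets=tuple(float(t) for t in targets),
                          magnitudes=tuple(mags), clamped=tuple(clamped),
                          max_magnitude=max_magnitude)


def propose_next_magnitude(fit: CalibrationFit, probe_target: float,
                           max_magnitude: float | None = None) -> float:
    """Adaptive-calibration step: inverse-predict the next probe magnitude.

    The iterative procedure appends each new (magnitude, rating) pair, refits
    with :func:`fit_stimulus_response`, and proposes the magnitude whose
    predicted rating equals the next probe target.  The full staircase
    schedule of the original protocol is not reproduced; this exposes the
    proposal rule only.
    """
    sel = select_levels(fit, targets=[probe_target], max_magnitude=max_magnitude)
    return sel.magnitudes[0]


def compute_valence(pleasantness, unpleasantness, sign: float = 1.0):
    """Bivalent valence score from the two unipolar scales.

    Defined as ``sign * (unpleasantness - pleasantness)``; the sign option is
    exposed because conventions differ on whether positive values should
    denote pleasant or unpleasant percepts.
    """
    p = np.asarray(pleasantness, dtype=float)
    u = np.asarray(unpleasantness, dtype=float)
    return sign * (u - p)


def calibration_report(magnitudes, ratings, modality: str = "",
                       targets: Sequence[float] = DEFAULT_TARGETS,
                       max_magnitude: float | None = None,
                       threshold: float = ELIGIBILITY_R2) -> dict:
    """Fit, gate and invert in one step; returns a JSON-serializable dict."""
    fit = fit_stimulus_response(magnitudes, ratings, modality=modality)
    eligible = check_eligibility(fit, threshold=threshold)
    report = {
        "modality": modality,
        "intercept": fit.intercept,
        "slope": fit.slope,
        "r_squared": fit.r_squared,
        "n_trials": fit.n_trials,
        "eligible": bool(eligible),
        "targets": list(targets),
        "magnitudes": None,
        "clamped": None,
    }
    if eligible and fit.slope > 0:
        sel = select_levels(fit, targets=targets, max_magnitude=max_magnitude)
        report["magnitudes"] = list(sel.magnitudes)
        report["clamped"] = list(sel.clamped)
    return report
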