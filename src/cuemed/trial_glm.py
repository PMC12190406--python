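"""Single-trial (beta-series) GLM: HRF, design matrices, OLS betas, VIF gate.

Event boxcars are convolved with a hemodynamic response function on a 0.1 s
microtime grid and decimated to scan times.  With ``trialwise=True`` each
outcome event gets its own regressor, yielding one coefficient per voxel per
trial; those single-trial estimates feed the multilevel mediation.  Because
closely spaced trial regressors are collinear, a variance-inflation-factor
gate removes trials whose VIF strictly exceeds 2 before mediation.

Estimation is ordinary least squares; generalized least squares with an
autoregressive noise model is a non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import ConfigurationError, EstimabilityError

MICROTIME_DT = 0.1   # s; convolution grid, decimated to scan times
HRF_SUPPORT = 50.0   # s; response treated as zero beyond this lag
VIF_THRESHOLD = 2.0


# ---------------------------------------------------------------------------
# hemodynamic response functions
# ---------------------------------------------------------------------------

# (weight, time constant s) of the contrast-agent-style impulse response;
# the raw response is negative-going and is sign-flipped here so that
# activation is positive, then scaled to unit peak.
_MION_TERMS = ((0.184, 1.5), (0.330, 4.5), (0.670, 13.5))
_MION_PEAK = sum(w / tau for w, tau in _MION_TERMS)  # value at t=0

_CANONICAL_SHAPES = (6.0, 16.0)   # gamma shape parameters, scale 1
_CANONICAL_RATIO = 1.0 / 6.0      # undershoot amplitude ratio


def hrf(t, kind: str = "mion_like"):
    """Evaluate a unit-peak HRF at times t (seconds, >= 0).

    'mion_like' is a monotone three-exponential mixture mimicking a
    contrast-agent response (sign-flipped to positive, peak at t=0);
    'canonical' is the usual difference of two gamma densities peaking
    near 5 s.  Both are scaled to a maximum of 1.
    """
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("HRF is defined for t >= 0 only")
    if kind == "mion_like":
        out = sum(w / tau * np.exp(-t / tau) for w, tau in _MION_TERMS)
        return out / _MION_PEAK
    if kind == "canonical":
        a1, a2 = _CANONICAL_SHAPES
        raw = stats.gamma.pdf(t, a1) - _CANONICAL_RATIO * stats.gamma.pdf(t, a2)
        grid = np.arange(0.0, HRF_SUPPORT, MICROTIME_DT)
        peak = np.max(stats.gamma.pdf(grid, a1)
                      - _CANONICAL_RATIO * stats.gamma.pdf(grid, a2))
        return raw / peak
    raise ValueError(f"unknown HRF kind {kind!r}")


# ---------------------------------------------------------------------------
# event schedules and design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    onset: float      # s
    duration: float   # s
    label: str


@dataclass(frozen=True)
class EventSchedule:
    events: Sequence[Event]
    scan_length: float   # s
    tr: float            # repetition time, s

    def __post_init__(self):
        if self.tr <= 0:
            raise ConfigurationError("repetition time must be > 0")
        for ev in self.events:
            if ev.onset < 0:
                raise ConfigurationError(f"negative onset in event {ev}")
            if ev.onset + ev.duration > self.scan_length + 1e-9:
                raise ConfigurationError(
                    f"event {ev} extends beyond scan end {self.scan_length}")

    @property
    def n_scans(self) -> int:
        return int(round(self.scan_length / self.tr))

    @property
    def scan_times(self) -> np.ndarray:
        return np.arange(self.n_scans) * self.tr

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scan_length: float, tr: float):
        """Build from a TSV-style frame with onset/duration/label columns."""
        events = [Event(float(r.onset), float(r.duration), str(r.label))
                  for r in frame.itertuples()]
        return cls(events=tuple(events), scan_length=scan_length, tr=tr)


def _convolved_column(schedule: EventSchedule, events, hrf_kind: str):
    grid = np.arange(0.0, schedule.scan_length, MICROTIME_DT)
    box = np.zeros_like(grid)
    for ev in events:
        box[(grid >= ev.onset) & (grid < ev.onset + ev.duration)] = 1.0
    kernel = hrf(np.arange(0.0, HRF_SUPPORT, MICROTIME_DT), kind=hrf_kind)
    conv = np.convolve(box, kernel)[: grid.size] * MICROTIME_DT
    sample = np.clip(np.round(schedule.scan_times / MICROTIME_DT).astype(int),
                     0, grid.size - 1)
    return conv[sample]


def build_design(schedule: EventSchedule, hrf_kind: str = "mion_like",
                 trialwise: bool = True,
                 nuisance: pd.DataFrame | None = None) -> pd.DataFrame:
    """Design matrix sampled at scan times (one row per scan).

    trialwise=True: one column per event, named ``label#k`` with k the
    within-label event index — the beta-series design.  trialwise=False:
    events pooled by condition label.  Nuisance columns (motion, swallow,
    rating, rinse regressors...) are appended unchanged and never analyzed.
    """
    columns = {}
    if trialwise:
        counter: dict = {}
        for ev in schedule.events:
            k = counter.get(ev.label, 0)
            counter[ev.label] = k + 1
            columns[f"{ev.label}#{k}"] = _convolved_column(
                schedule, [ev], hrf_kind)
    else:
        by_label: dict = {}
        for ev in schedule.events:
            by_label.setdefault(ev.label, []).append(ev)
        for label, events in by_label.items():
            columns[label] = _convolved_column(schedule, events, hrf_kind)
    X = pd.DataFrame(columns, index=schedule.scan_times)
    zero = [c for c in X.columns if not np.any(X[c].to_numpy())]
    if zero:
        raise ConfigurationError(f"all-zero regressor columns: {zero}")
    if nuisance is not None:
        if len(nuisance) != len(X):
            raise ConfigurationError("nuisance row count != number of scans")
        X = pd.concat([X, nuisance.set_index(X.index)], axis=1)
    return X


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

@dataclass
class TrialBetas:
    """Per-trial, per-voxel coefficients with their collinearity diagnostics."""

    betas: np.ndarray            # (n_trials, n_voxels)
    trial_names: list
    vif: np.ndarray | None = None
    excluded: np.ndarray | None = None   # bool per trial
    residual_variance: np.ndarray | None = None

    def retained(self) -> "TrialBetas":
        if self.excluded is None:
            return self
        keep = ~self.excluded
        return TrialBetas(
            betas=self.betas[keep],
            trial_names=[n for n, k in zip(self.trial_names, keep) if k],
            vif=self.vif[keep] if self.vif is not None else None,
            excluded=np.zeros(int(keep.sum()), dtype=bool),
            residual_variance=self.residual_variance,
        )


def fit_betas(Y: np.ndarray, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients per voxel: returns (betas, residual variance).

    Y is (n_scans, n_voxels); X must be full column rank, otherwise an
    :class:`EstimabilityError` names the offending columns.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and len(X) != 1:
        Y = Y.T
    A = X.to_numpy(dtype=float)
    if Y.shape[0] != A.shape[0]:
        raise ValueError("Y rows must match design rows (scans)")
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        _, _, piv = linalg.qr(A, mode="economic", pivoting=True)
        bad = sorted(X.columns[j] for j in piv[rank:])
        raise EstimabilityError(bad)
    beta, res, _, _ = np.linalg.lstsq(A, Y, rcond=None)
    dof = max(A.shape[0] - A.shape[1], 1)
    resid = Y - A @ beta
    sigma2 = (resid ** 2).sum(axis=0) / dof
    return beta, sigma2


def extract_trial_betas(Y: np.ndarray, X: pd.DataFrame,
                        trial_prefix: str) -> TrialBetas:
    """Fit the full design and keep the columns of one outcome condition.

    ``trial_prefix`` selects trialwise columns named ``prefix#k``; nuisance
    and cue columns are estimated jointly but not returned.
    """
    beta, sigma2 = fit_betas(Y, X)
    names = [c for c in X.columns if c.startswith(trial_prefix + "#")]
    rows = [X.columns.get_loc(c) for c in names]
    return TrialBetas(betas=beta[rows], trial_names=names,
                      residual_variance=sigma2)


# ---------------------------------------------------------------------------
# collinearity gate
# ---------------------------------------------------------------------------

def compute_vif(X: pd.DataFrame, center: bool = True) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R^2_j).

    R^2_j comes from regressing column j on all other columns.  Columns are
    mean-centered first (so an explicit intercept column, being constant,
    is dropped from the computation and reported as NaN).  A perfectly
    collinear column is reported as +inf.
    """
    A = X.to_numpy(dtype=float)
    if A.shape[1] < 2:
        raise ValueError("VIF needs at least 2 columns")
    if center:
        A = A - A.mean(axis=0)
    norms = np.linalg.norm(A, axis=0)
    usable = norms > 1e-12
    out = np.full(A.shape[1], np.nan)
    for j in np.flatnonzero(usable):
        others = np.flatnonzero(usable & (np.arange(A.shape[1]) != j))
        yj = A[:, j]
        Z = A[:, others]
        coef, _, _, _ = np.linalg.lstsq(Z, yj, rcond=None)
        rss = float(np.sum((yj - Z @ coef) ** 2))
        tss = float(np.sum(yj ** 2))
        r2 = 1.0 - rss / tss
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, index=X.columns, name="vif")


def exclude_trials(betas: TrialBetas, vif: pd.Series | np.ndarray | None = None,
                   threshold: float = VIF_THRESHOLD) -> TrialBetas:
    """Flag trials whose VIF strictly exceeds the threshold (default 2).

    A VIF exactly at the threshold is retained.  Returns a new TrialBetas
    with the ``excluded`` flags set; call :meth:`TrialBetas.retained` to drop
    them before mediation.
    """
    if vif is None:
        vif = betas.vif
    if vif is None:
        raise ValueError("VIFs not computed")
    v = np.asarray(vif, dtype=float)
    if v.size != len(betas.trial_names):
        raise ValueError("one VIF per trial required")
    excluded = v > threshold
    return TrialBetas(betas=betas.betas, trial_names=list(betas.trial_names),
                      vif=v, excluded=excluded,
                      residual_variance=betas.residual_variance)
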