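"""Behavioral linear mixed models for intensity/valence ratings.

Ratings are modeled with subject-level random effects and fixed effects for
Cue, Stimulus Level, Time (trial), and between-subject factors: Group
(dummy-coded, reference Salt, giving Heat-vs-Salt and Sugar-vs-Salt
contrasts), Modality (Heat vs Tastes) or Aversiveness (Heat+Salt vs Sugar).
Cue, Stimulus Level and Time are mean-centered within the analysis subset;
follow-up models restrict to medium-level trials, where the level term is
constant and dropped.

Fitting uses statsmodels MixedLM.  Fixed-effect p-values are Wald tests on
the normal approximation (the package does not provide Satterthwaite
degrees of freedom); with the trial counts of this design the difference is
negligible and the method is recorded in every FitResult.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ConfigurationError, InsufficientDataError
from .synthetic import CUE_CODE, GROUPS, LEVEL_CODE

#: fixed-term name -> model-frame column(s)
_TERM_COLUMNS = {
    "Cue": ["cue_c"],
    "StimulusLevel": ["level_c"],
    "Time": ["time_c"],
    "Group": ["group_heat", "group_sugar"],
    "Modality": ["modality_heat"],
    "Aversiveness": ["aversive"],
}


@dataclass(frozen=True)
class ModelSpec:
    """Which outcome, fixed terms and random terms to fit, on which subset."""

    outcome: str = "intensity"
    fixed: Sequence[str] = ("Cue", "StimulusLevel", "Time", "Group")
    interactions: Sequence[tuple] = ()
    random: Sequence[str] = ("intercept", "Cue")
    subset: str = "all"            # {all, medium_only}
    reml: bool = False

    def __post_init__(self):
        if self.outcome not in {"intensity", "valence",
                                "expected_intensity", "expected_valence"}:
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")
        unknown = set(self.fixed) - set(_TERM_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown fixed terms: {sorted(unknown)}")
        if self.subset not in {"all", "medium_only"}:
            raise ConfigurationError(f"unknown subset {self.subset!r}")

    def columns(self) -> list:
        cols = []
        for term in self.fixed:
            if self.subset == "medium_only" and term == "StimulusLevel":
                continue   # constant on medium trials
            cols.extend(_TERM_COLUMNS[term])
        for pair in self.interactions:
            if self.subset == "medium_only" and "StimulusLevel" in pair:
                continue
            cols.extend(interaction_columns(pair))
        return cols


def interaction_columns(pair) -> list:
    """One product column per combination of the two terms' code columns."""
    a, b = pair
    return [f"{ca}_x_{cb}"
            for ca in _TERM_COLUMNS[a] for cb in _TERM_COLUMNS[b]]


@dataclass
class FitResult:
    spec: ModelSpec
    params: pd.DataFrame          # estimate, se, stat, p per fixed term
    llf: float
    aic: float
    converged: bool
    n_obs: int
    n_subjects: int
    random_structure: str
    pvalue_method: str = "wald-normal"
    diagnostics: dict = field(default_factory=dict)


def encode_predictors(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Build the centered, dummy-coded model frame for one ModelSpec.

    Cue (+0.5/-0.5), level (-1/0/+1) and trial are mean-centered within the
    analysis subset; Group uses Salt as the reference (group_heat,
    group_sugar dummies); modality_heat is 1 for Heat; aversive is 1 for
    Heat and Salt, 0 for Sugar.
    """
    unknown = set(table["group"]) - set(GROUPS)
    if unknown:
        raise ConfigurationError(f"unknown group labels: {sorted(unknown)}")
    unknown = set(table["cue"]) - set(CUE_CODE)
    if unknown:
        raise ConfigurationError(f"unknown cue labels: {sorted(unknown)}")
    unknown = set(table["level"]) - set(LEVEL_CODE)
    if unknown:
        raise ConfigurationError(f"unknown level labels: {sorted(unknown)}")

    data = table.copy()
    if spec.subset == "medium_only":
        data = data[data["level"] == "Medium"]
    data = data[~data[spec.outcome].isna()].copy()
    if data.empty:
        raise InsufficientDataError("no usable rows after subsetting")

    cue = data["cue"].map(CUE_CODE).astype(float)
    lev = data["level"].map(LEVEL_CODE).astype(float)
    time = data["trial"].astype(float)
    frame = pd.DataFrame({
        "subject": data["subject"].to_numpy(),
        "group": data["group"].to_numpy(),
        spec.outcome: data[spec.outcome].to_numpy(float),
        "cue_c": (cue - cue.mean()).to_numpy(),
        "level_c": (lev - lev.mean()).to_numpy(),
        "time_c": (time - time.mean()).to_numpy(),
    })
    frame["group_heat"] = (frame["group"] == "Heat").astype(float)
    frame["group_sugar"] = (frame["group"] == "Sugar").astype(float)
    frame["modality_heat"] = (frame["group"] == "Heat").astype(float)
    frame["aversive"] = frame["group"].isin(["Heat", "Salt"]).astype(float)
    for pair in spec.interactions:
        for ca in _TERM_COLUMNS[pair[0]]:
            for cb in _TERM_COLUMNS[pair[1]]:
                frame[f"{ca}_x_{cb}"] = frame[ca] * frame[cb]
    return frame


def fit_lmm(frame: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit the mixed model with per-subject random intercept (+ slopes).

    Singular random-effect fits are flagged in the diagnostics and the
    structure simplified to a random intercept (the simplification path is
    recorded), not silently dropped.
    """
    if frame["subject"].nunique() < 2:
        raise InsufficientDataError("mixed model needs >= 2 subjects")
    if np.allclose(frame[spec.outcome].std(), 0.0):
        raise InsufficientDataError("outcome is constant")
    cols = spec.columns()
    formula = f"{spec.outcome} ~ " + (" + ".join(cols) if cols else "1")
    slopes = [c for t in spec.random if t != "intercept"
              for c in _TERM_COLUMNS[t] if c in cols]
    re_formula = "~" + " + ".join(slopes) if slopes else "~1"
    diagnostics: dict = {"re_formula": re_formula, "simplified": False}

    def _fit(re_f):
        model = smf.mixedlm(formula, frame, groups=frame["subject"],
                            re_formula=re_f)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=spec.reml, method=["bfgs", "powell", "cg"])

    fit = _fit(re_formula)
    converged = bool(fit.converged)
    if getattr(fit, "cov_re", None) is not None:
        singular = np.linalg.matrix_rank(np.asarray(fit.cov_re)) < fit.cov_re.shape[0]
        diagnostics["singular_cov_re"] = bool(singular)
        if (singular or not converged) and re_formula != "~1":
            diagnostics["simplified"] = True
            diagnostics["simplification_path"] = [re_formula, "~1"]
            fit = _fit("~1")
            converged = bool(fit.converged)

    fe = fit.fe_params
    params = pd.DataFrame({
        "estimate": fe,
        "se": fit.bse_fe.reindex(fe.index),
        "stat": (fe / fit.bse_fe.reindex(fe.index)),
        "p": fit.pvalues.reindex(fe.index),
    })
    return FitResult(spec=spec, params=params, llf=float(fit.llf),
                     aic=float(fit.aic) if np.isfinite(fit.aic) else np.nan,
                     converged=converged, n_obs=int(len(frame)),
                     n_subjects=int(frame["subject"].nunique()),
                     random_structure=diagnostics["re_formula"],
                     diagnostics=diagnostics)


def _is_nested(small: FitResult, big: FitResult) -> bool:
    return (set(small.spec.columns()) <= set(big.spec.columns())
            and small.n_obs == big.n_obs)


def compare_models(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fits by AIC; add likelihood-ratio tests for nested pairs.

    All fits must be on the same data subset (same n).  The returned frame
    is sorted best-first, with the LRT against the next-larger nested model
    where one exists.
    """
    from scipy import stats as sps

    if len({f.n_obs for f in fits}) != 1:
        raise ConfigurationError("model comparison requires identical data")
    rows = []
    for i, f in enumerate(fits):
        rows.append({"model": i, "terms": "+".join(f.spec.columns()) or "1",
                     "aic": f.aic, "llf": f.llf,
                     "df": len(f.params)})
    frame = pd.DataFrame(rows).sort_values("aic", kind="stable")
    frame["rank"] = np.arange(1, len(frame) + 1)
    lrt_p = []
    for _, row in frame.iterrows():
        f = fits[int(row["model"])]
        partners = [g for g in fits if g is not f and _is_nested(f, g)]
        if partners:
            g = max(partners, key=lambda m: len(m.params))
            stat = 2.0 * (g.llf - f.llf)
            ddf = len(g.params) - len(f.params)
            lrt_p.append(float(sps.chi2.sf(max(stat, 0.0), ddf)) if ddf > 0
                         else np.nan)
        else:
            lrt_p.append(np.nan)
    frame["lrt_p_vs_larger"] = lrt_p
    return frame.reset_index(drop=True)


def likelihood_ratio_test(small: FitResult, big: FitResult) -> dict:
    """LRT between two nested ML fits (errors if not nested)."""
    from scipy import stats as sps

    if not _is_nested(small, big):
        raise ConfigurationError("models are not nested on identical data")
    stat = 2.0 * (big.llf - small.llf)
    ddf = len(big.params) - len(small.params)
    if ddf <= 0:
        raise ConfigurationError("nested pair must differ in parameters")
    return {"stat": float(stat), "df": ddf,
            "p": float(sps.chi2.sf(max(stat, 0.0), ddf))}
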