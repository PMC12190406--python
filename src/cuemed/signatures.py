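"""Signature-pattern expression and its group-level tests.

A neural signature is a fixed voxel weight map (e.g. a validated pain
signature); its expression in a subject's coefficient or contrast map is
the dot product of weights and map values over the shared support.  Scores
are compared against zero with one-sample t-tests per group, and across
the Heat/Salt/Sugar groups with a one-way ANOVA whose pairwise follow-ups
are Bonferroni-corrected by the number of pairs.

Patterns and images must share a grid exactly; no spatial resampling is
performed, because interpolation choices would silently change dot
products.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import GridMismatchError


@dataclass(frozen=True)
class SignaturePattern:
    """Named voxel weight map with its support mask."""

    name: str
    weights: np.ndarray
    support: np.ndarray   # boolean, same grid

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        s = np.asarray(self.support, dtype=bool)
        if w.shape != s.shape:
            raise GridMismatchError("weights and support differ in shape")
        if not np.isfinite(w[s]).all():
            raise ValueError("non-finite weights on support")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "support", s)


@dataclass(frozen=True)
class ExpressionScore:
    subject: str
    map_label: str
    value: float
    coverage: float   # fraction of pattern support present in the image mask


def express(pattern: SignaturePattern, image: np.ndarray,
            image_mask: np.ndarray | None = None,
            subject: str = "", map_label: str = "") -> ExpressionScore:
    """Dot product of pattern weights and image values over the support.

    Voxels of the pattern support missing from the image mask contribute 0
    and are reported through ``coverage`` (1.0 = full overlap).  Grids must
    match exactly; resampling is out of scope.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != pattern.weights.shape:
        raise GridMismatchError(
            f"image grid {image.shape} != pattern grid {pattern.weights.shape}")
    if image_mask is None:
        used = pattern.support
    else:
        image_mask = np.asarray(image_mask, dtype=bool)
        if image_mask.shape != image.shape:
            raise GridMismatchError("image mask grid mismatch")
        used = pattern.support & image_mask
    n_support = int(pattern.support.sum())
    coverage = float(used.sum()) / n_support if n_support else 0.0
    value = float(np.sum(pattern.weights[used] * image[used]))
    return ExpressionScore(subject=subject, map_label=map_label,
                           value=value, coverage=coverage)


def group_ttest(scores: Sequence[float]) -> dict:
    """One-sample t-test of expression scores against zero (two-tailed).

    Zero-variance inputs are flagged degenerate rather than yielding an
    infinite statistic.
    """
    v = np.asarray(scores, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 scores")
    if np.allclose(v.std(ddof=1), 0.0):
        return {"t": np.nan, "p": np.nan, "df": v.size - 1,
                "mean": float(v.mean()), "degenerate": True}
    t, p = stats.ttest_1samp(v, 0.0)
    return {"t": float(t), "p": float(p), "df": v.size - 1,
            "mean": float(v.mean()), "sd": float(v.std(ddof=1)),
            "degenerate": False}


def group_anova(scores_by_group: Mapping[str, Sequence[float]]) -> dict:
    """One-way ANOVA across groups with Bonferroni-corrected pairwise tests.

    Pairwise two-sample t-tests have their p-values multiplied by the
    number of pairs and capped at 1.
    """
    names = list(scores_by_group)
    groups = [np.asarray(scores_by_group[g], dtype=float) for g in names]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 scores each")
    degenerate = all(np.allclose(g.std(ddof=1), 0.0) for g in groups)
    if degenerate and len({float(g.mean()) for g in groups}) == 1:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*groups)
    pairs = list(combinations(range(len(names)), 2))
    pairwise = {}
    for i, j in pairs:
        if degenerate:
            t, praw = 0.0, 1.0
        else:
            t, praw = stats.ttest_ind(groups[i], groups[j])
        pairwise[(names[i], names[j])] = {
            "t": float(t), "p_raw": float(praw),
            "p_bonferroni": min(1.0, float(praw) * len(pairs)),
        }
    return {"F": float(f_stat), "p": float(p), "pairwise": pairwise,
            "df_between": len(names) - 1,
            "df_within": int(sum(g.size for g in groups)) - len(names),
            "degenerate": degenerate}


def path_signature_tests(pattern: SignaturePattern,
                         path_maps: Mapping[str, np.ndarray],
                         groups: Mapping[str, str],
                         image_mask: np.ndarray | None = None) -> dict:
    """Express each subject's path-coefficient map, then t-test and ANOVA.

    ``path_maps[s]`` is subject s's 3D map for one mediation path;
    ``groups[s]`` the group label.  Returns per-group one-sample tests, the
    across-group ANOVA, and the raw scores.
    """
    scores = {s: express(pattern, m, image_mask=image_mask, subject=s).value
              for s, m in path_maps.items()}
    by_group: dict = {}
    for s, v in scores.items():
        by_group.setdefault(groups[s], []).append(v)
    ttests = {g: group_ttest(v) for g, v in by_group.items() if len(v) >= 2}
    anova = group_anova(by_group) if len(by_group) >= 2 else None
    return {"scores": scores, "ttests": ttests, "anova": anova}
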