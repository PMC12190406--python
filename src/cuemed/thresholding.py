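"""Statistical-map thresholding: FDR, cluster extent rules, SVC, conjunction.

Implements the map-level multiple-comparison conventions used for the
mediation and univariate results: Benjamini-Hochberg FDR at q < .05 over
masked voxels; an uncorrected primary threshold of p < .001 with a minimum
cluster extent (3 voxels for mediation maps, 10 for exploratory univariate
maps) where mediation clusters are then grown by annexing contiguous voxels
at p < .005 and p < .01; small-volume familywise correction within a priori
regions of interest (sign-flip permutation by default, Bonferroni as the
analytic fallback); and minimum-statistic conjunction as the voxelwise AND
of thresholded maps.

Contiguity defaults to 6-connectivity (shared faces) and is configurable
to 18 or 26.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, GridMismatchError

#: named presets: (primary p, minimum extent, growth thresholds)
THRESHOLD_PRESETS = {
    "mediation": {"primary_p": 0.001, "k_min": 3, "grow_ps": (0.005, 0.01)},
    "univariate": {"primary_p": 0.001, "k_min": 10, "grow_ps": ()},
}

_STRUCTURES = {6: 1, 18: 2, 26: 3}


@dataclass
class Cluster:
    coords: np.ndarray        # (n, 3) voxel indices, 0-based
    peak: tuple               # voxel index of the peak
    peak_stat: float
    size: int


@dataclass
class ClusterSet:
    clusters: list = field(default_factory=list)

    def __len__(self):
        return len(self.clusters)

    def label_map(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=int)
        for i, cl in enumerate(self.clusters, start=1):
            out[tuple(cl.coords.T)] = i
        return out

    def to_frame(self, affine: np.ndarray | None = None) -> pd.DataFrame:
        rows = []
        for i, cl in enumerate(self.clusters, start=1):
            row = {"cluster": i, "size": cl.size,
                   "peak_i": cl.peak[0], "peak_j": cl.peak[1],
                   "peak_k": cl.peak[2], "peak_stat": cl.peak_stat}
            if affine is not None:
                mm = affine @ np.array([*cl.peak, 1.0])
                row.update({"peak_x_mm": mm[0], "peak_y_mm": mm[1],
                            "peak_z_mm": mm[2]})
            rows.append(row)
        return pd.DataFrame(rows)


def fdr_bh(p_map: np.ndarray, mask: np.ndarray, q: float = 0.05):
    """Benjamini-Hochberg step-up over masked voxels.

    Returns (boolean significance map, realized p threshold) — the
    threshold is the largest rejected p-value, 0.0 if nothing survives.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ConfigurationError("empty mask")
    p = np.asarray(p_map, dtype=float)[mask]
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values on mask must lie in (0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    out = np.zeros(mask.shape, dtype=bool)
    out[mask] = reject
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return out, threshold


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _STRUCTURES:
        raise ConfigurationError(
            f"connectivity must be one of {sorted(_STRUCTURES)}")
    return ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])


def cluster_filter(p_map: np.ndarray, mask: np.ndarray,
                   primary_p: float = 0.001, k_min: int = 3,
                   grow_ps: Sequence[float] = (0.005, 0.01),
                   connectivity: int = 6,
                   stat_map: np.ndarray | None = None) -> ClusterSet:
    """Primary-threshold clusters with extent gate and iterative growth.

    Seed clusters are the connected components of ``p < primary_p`` within
    the mask that contain at least ``k_min`` voxels.  For each successive
    growth threshold, voxels passing it that touch an existing cluster are
    annexed iteratively (ties between adjacent clusters resolve to the
    lower cluster label); growth never creates new clusters.  Peaks are the
    maximum of ``stat_map`` within a cluster (minimum p if no statistic
    map is given).
    """
    grow_ps = tuple(grow_ps)
    if list(grow_ps) != sorted(grow_ps):
        raise ConfigurationError("growth thresholds must be ascending")
    if grow_ps and grow_ps[0] < primary_p:
        raise ConfigurationError("growth thresholds must be >= primary_p")
    mask = np.asarray(mask, dtype=bool)
    p = np.asarray(p_map, dtype=float)
    structure = _structure(connectivity)

    seeds = (p < primary_p) & mask
    labels, n = ndimage.label(seeds, structure=structure)
    if n:
        sizes = np.bincount(labels.ravel())
        for lab in range(1, n + 1):
            if sizes[lab] < k_min:
                labels[labels == lab] = 0
    # relabel survivors compactly, preserving order
    survivors = np.unique(labels[labels > 0])
    relabel = np.zeros(labels.max() + 1 if labels.size else 1, dtype=int)
    for new, old in enumerate(survivors, start=1):
        relabel[old] = new
    labels = relabel[labels]

    for grow_p in grow_ps:
        candidates = (p < grow_p) & mask
        while True:
            # neighbor label = min positive label among adjacent voxels
            big = np.where(labels > 0, labels.astype(float), np.inf)
            neighbor = -ndimage.grey_dilation(
                -big, footprint=structure, mode="constant", cval=-np.inf)
            annex = candidates & (labels == 0) & np.isfinite(neighbor)
            if not annex.any():
                break
            labels[annex] = neighbor[annex].astype(int)

    score = (-p if stat_map is None
             else np.asarray(stat_map, dtype=float))
    clusters = []
    for lab in range(1, labels.max() + 1):
        where = np.argwhere(labels == lab)
        if where.size == 0:
            continue
        vals = score[tuple(where.T)]
        peak = tuple(int(v) for v in where[np.argmax(vals)])
        peak_stat = (float(p[peak]) if stat_map is None
                     else float(score[peak]))
        clusters.append(Cluster(coords=where, peak=peak,
                                peak_stat=peak_stat, size=len(where)))
    return ClusterSet(clusters=clusters)


def small_volume_correction(roi: np.ndarray, alpha: float = 0.05,
                            method: str = "permutation",
                            p_map: np.ndarray | None = None,
                            subject_maps: np.ndarray | None = None,
                            mask: np.ndarray | None = None,
                            n_perm: int = 2000,
                            seed: int | None = None):
    """Familywise error control restricted to an a priori ROI.

    method='permutation' (default): sign-flip max-statistic permutation on
    the subject-level maps — ``subject_maps`` is (n_subjects, *grid); a
    voxel is significant when its one-sample t exceeds the (1-alpha)
    quantile of the permutation distribution of the ROI-wise max |t|.
    Exact under exchangeability of subject signs.

    method='bonferroni': analytic fallback on a voxelwise ``p_map``,
    significant where p < alpha / n_roi_voxels.

    Returns (boolean significance map, info dict).
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ConfigurationError("empty ROI")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not (roi <= mask).all():
            raise ConfigurationError("ROI extends outside the analysis mask")
    out = np.zeros(roi.shape, dtype=bool)

    if method == "bonferroni":
        if p_map is None:
            raise ConfigurationError("bonferroni SVC requires a p-map")
        n_roi = int(roi.sum())
        out[roi] = np.asarray(p_map, dtype=float)[roi] < alpha / n_roi
        return out, {"method": "bonferroni", "n_roi": n_roi,
                     "threshold": alpha / n_roi}

    if method == "permutation":
        if subject_maps is None:
            raise ConfigurationError("permutation SVC requires subject maps")
        data = np.asarray(subject_maps, dtype=float)
        if data.shape[1:] != roi.shape:
            raise GridMismatchError("subject maps and ROI differ in grid")
        V = data[:, roi]                       # (n_subjects, n_roi)
        n = V.shape[0]

        def tstat(mean, ss):
            # ss = mean of squares, invariant under sign flips
            var = (ss - mean ** 2) * n / (n - 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(var > 0, mean / np.sqrt(var / n), 0.0)

        ss = (V ** 2).mean(axis=0)
        t_obs = tstat(V.mean(axis=0), ss)
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        perm_means = signs @ V / n             # (n_perm, n_roi)
        max_t = np.abs(tstat(perm_means, ss[None, :])).max(axis=1)
        crit = float(np.quantile(max_t, 1.0 - alpha))
        out[roi] = np.abs(t_obs) > crit
        return out, {"method": "permutation", "n_perm": n_perm,
                     "critical_t": crit, "n_roi": int(roi.sum())}

    raise ConfigurationError(f"unknown SVC method {method!r}")


def conjunction(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Voxelwise AND of individually thresholded significance masks."""
    if not masks:
        raise ConfigurationError("no masks given")
    arrays = [np.asarray(m, dtype=bool) for m in masks]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise GridMismatchError(f"masks on different grids: {shapes}")
    out = arrays[0].copy()
    for a in arrays[1:]:
        out &= a
    return out
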