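"""Feature extraction and univariate feature selection.

Each subject volume is summarized by the mean and standard deviation of its
intensities over every cluster of a :class:`~petroi.roi_discovery.ClusterMap`
(or over every region of an atlas), giving a 2·C-dimensional vector for C
units.  Features are ranked by a univariate relevance score computed on
training rows only, and the top-m are kept for classification.

Also provides the voxel-wise two-sample t-test baseline: voxels whose
uncorrected p-value falls below a threshold are ranked by p, and the raw
intensities of the top-m voxels become the feature vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .roi_discovery import Cluster, ClusterMap
from .volume_io import Atlas, BrainMask, Volume

logger = logging.getLogger(__name__)

#: Default number of features kept after ranking, per selection criterion.
TOP_M_BY_CRITERION = {"bic": 150, "aic": 400}

#: Defaults of the t-test baseline.
TTEST_ALPHA = 0.001
TTEST_TOP_M = 150


@dataclass
class FeatureMatrix:
    """Subjects × features with labels and named columns."""

    subjects: list[str]
    labels: np.ndarray
    values: np.ndarray  # (S, F)
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.shape != (len(self.subjects), len(self.feature_names)):
            raise ConfigurationError("feature matrix shape inconsistent with names/subjects")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("feature matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subjects)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class FeatureRanking:
    """Features ordered by decreasing relevance score."""

    order: np.ndarray  # permutation of feature indices
    scores: np.ndarray  # same order, non-increasing
    method: str

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=np.float64)


def _unit_stats(values: np.ndarray) -> tuple[float, float]:
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return mean, sd


def cluster_feature_names(cmap: ClusterMap) -> list[str]:
    names = [f"c{c.id:04d}_mean" for c in cmap.clusters]
    names += [f"c{c.id:04d}_sd" for c in cmap.clusters]
    return names


def extract_features(volume: Volume, cmap: ClusterMap) -> np.ndarray:
    """Per-cluster mean and sample SD (n-1) of the volume's intensities.

    Returns a vector of length 2·#clusters: all means first, then all SDs,
    in cluster-id order.  A single-voxel cluster gets SD 0.
    """
    if volume.shape != cmap.shape:
        raise ConfigurationError(f"volume shape {volume.shape} != map shape {cmap.shape}")
    means = np.empty(len(cmap.clusters))
    sds = np.empty(len(cmap.clusters))
    for i, c in enumerate(cmap.clusters):
        means[i], sds[i] = _unit_stats(volume.data[tuple(c.coords.T)])
    return np.concatenate([means, sds])


def atlas_features(volume: Volume, atlas: Atlas) -> tuple[np.ndarray, list[str]]:
    """Per-atlas-region mean and SD, in region-code order.

    A region present in the name table but absent from the label volume
    yields the feature pair (0, 0) with a logged warning.
    """
    if volume.shape != atlas.shape:
        raise ConfigurationError(f"volume shape {volume.shape} != atlas shape {atlas.shape}")
    codes = sorted(atlas.names)
    means = np.zeros(len(codes))
    sds = np.zeros(len(codes))
    for i, code in enumerate(codes):
        vals = volume.data[atlas.labels == code]
        if vals.size == 0:
            logger.warning("atlas_features: region %d (%s) has no voxels", code, atlas.names[code])
            continue
        means[i], sds[i] = _unit_stats(vals)
    names = [f"r{c:04d}_mean" for c in codes] + [f"r{c:04d}_sd" for c in codes]
    return np.concatenate([means, sds]), names


def atlas_to_cluster_map(atlas: Atlas) -> ClusterMap:
    """View an atlas as a ClusterMap (one cluster per region, code order)."""
    clusters = []
    for i, code in enumerate(sorted(atlas.names)):
        coords = np.argwhere(atlas.labels == code)
        if coords.shape[0] == 0:
            continue
        clusters.append(Cluster(id=i, bin_index=0, component_index=i, coords=coords))
    return ClusterMap(
        clusters=clusters, n_bins=1, criterion="atlas", shape=atlas.shape, seed=0, source="atlas"
    )


def ttest_voxel_selection(
    volumes_a: list[Volume],
    volumes_b: list[Volume],
    mask: BrainMask,
    alpha: float = TTEST_ALPHA,
    top_m: int = TTEST_TOP_M,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise two-sample, two-tailed, equal-variance t-test selection.

    No multiple-comparison correction is applied.  Voxels with p < ``alpha``
    are kept and the ``top_m`` with the lowest p are returned as
    ((m, 3) coordinates, p-values), sorted by increasing p with mask order
    breaking ties.  A voxel with zero within-group variance gets p = 1 when
    the group means agree, otherwise its t is computed on a variance floor.
    """
    if len(volumes_a) < 2 or len(volumes_b) < 2:
        raise ConfigurationError("need at least 2 subjects per group for a t-test")
    A = np.stack([mask.values(v) for v in volumes_a])
    B = np.stack([mask.values(v) for v in volumes_b])
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-identical groups trigger scipy's catastrophic-cancellation
        # warning; those voxels are re-handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(A, B, axis=0, equal_var=True)
    bad = ~np.isfinite(p)
    if bad.any():
        mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
        na, nb = A.shape[0], B.shape[0]
        dof = na + nb - 2
        # zero pooled variance: equal means -> no evidence; unequal -> floor
        floor_se = np.sqrt(1e-12 * (1 / na + 1 / nb))
        t_floor = (mean_a - mean_b) / floor_se
        p_floor = 2 * stats.t.sf(np.abs(t_floor), dof)
        p = np.where(bad, np.where(mean_a == mean_b, 1.0, p_floor), p)
    keep = np.flatnonzero(p < alpha)
    if keep.size == 0:
        return np.empty((0, 3), dtype=np.int64), np.empty(0)
    order = keep[np.argsort(p[keep], kind="stable")][:top_m]
    return mask.indices[order], p[order]


def _abs_t_scores(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    classes = np.unique(labels)
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]
    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    va = a.var(axis=0, ddof=1) if a.shape[0] > 1 else np.zeros(values.shape[1])
    vb = b.var(axis=0, ddof=1) if b.shape[0] > 1 else np.zeros(values.shape[1])
    na, nb = a.shape[0], b.shape[0]
    pooled = ((na - 1) * va + (nb - 1) * vb) / max(na + nb - 2, 1)
    se = np.sqrt(pooled * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(mean_diff) / se
    # constant feature across everything -> no information, score 0;
    # zero variance but different means -> maximally informative
    t = np.where(se == 0, np.where(mean_diff == 0, 0.0, np.inf), t)
    return t


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _info_gain_scores(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Information gain of the best single-threshold split per feature."""
    classes, y = np.unique(labels, return_inverse=True)
    n = len(y)
    base = _entropy(np.bincount(y, minlength=2))
    scores = np.zeros(values.shape[1])
    for j in range(values.shape[1]):
        x = values[:, j]
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        best = 0.0
        left = np.zeros(2)
        right = np.bincount(ys, minlength=2).astype(float)
        for i in range(n - 1):
            left[ys[i]] += 1
            right[ys[i]] -= 1
            if xs[i] == xs[i + 1]:
                continue
            cond = ((i + 1) / n) * _entropy(left) + ((n - i - 1) / n) * _entropy(right)
            best = max(best, base - cond)
        scores[j] = best
    return scores


def rank_features(
    values: np.ndarray, labels: np.ndarray, method: str = "abs_t"
) -> FeatureRanking:
    """Rank features by a univariate relevance score on the given rows.

    ``abs_t`` (default): absolute two-sample t-statistic; ``info_gain``:
    entropy-based gain of the best supervised single-threshold
    discretization.  Constant features score 0 and sort last.  The
    ranking depends only on the rows passed in (no leakage by design).
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ConfigurationError("feature ranking needs exactly 2 classes")
    if method == "abs_t":
        scores = _abs_t_scores(values, labels)
    elif method == "info_gain":
        scores = _info_gain_scores(values, labels)
    else:
        raise ConfigurationError(f"unknown ranking method {method!r}")
    order = np.argsort(-scores, kind="stable")
    return FeatureRanking(order=order, scores=scores[order], method=method)


def select_top_m(ranking: FeatureRanking, m: int) -> np.ndarray:
    """First ``m`` feature indices of the ranking (a prefix).

    ``m`` outside [1, #features] is clipped with a logged warning.
    """
    n = ranking.order.shape[0]
    if m < 1 or m > n:
        logger.warning("select_top_m: m=%d clipped to [1, %d]", m, n)
        m = min(max(m, 1), n)
    return ranking.order[:m].copy()
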