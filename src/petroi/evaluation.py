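"""Repeated stratified cross-validated evaluation of the ROI pipelines.

Implements the nested workflow: an outer repeated stratified 10-fold CV;
inside each training split, discovery of clusters on the mean
reference (normal-control) image, selection of the intensity-bin count on a
sub-train/sub-test split, feature ranking, and a linear-margin classifier
with a grid-searched penalty C — all computed from training rows only, so
no information leaks from the held-out fold.

Also provides the summary metrics (accuracy / sensitivity / specificity
aggregated by instance within each repeat, then averaged over repeats),
the pooled-ROC AUC (Mann-Whitney statistic over all test predictions of
all repeats), the corrected resampled paired t-test for comparing two
pipelines, the weighted-Euclidean dissimilarity ratio for single-case
error analysis, and the informative-regions report that attributes the
top-scoring clusters to atlas regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .errors import ConfigurationError, EvaluationError
from .features import (
    FeatureRanking,
    TOP_M_BY_CRITERION,
    TTEST_ALPHA,
    TTEST_TOP_M,
    atlas_features,
    cluster_feature_names,
    extract_features,
    rank_features,
    select_top_m,
    ttest_voxel_selection,
)
from .roi_discovery import ClusterMap, discover_clusters
from .volume_io import Atlas, BrainMask, Volume, mean_reference_image

logger = logging.getLogger(__name__)

#: Impairment ordering used to pick the default positive (disease) class.
IMPAIRMENT_ORDER = {"NC": 0, "MCI": 1, "AD": 2}


def _seed_int(*parts: int) -> int:
    return int(np.random.SeedSequence([int(p) for p in parts]).generate_state(1)[0] % (2**31))


@dataclass
class CVPlan:
    """Fold assignment per subject per repeat (stratified)."""

    assignment: np.ndarray  # (n_repeats, n_subjects) fold ids
    n_folds: int
    n_repeats: int
    seed: int


def stratified_folds(labels, n_folds: int = 10, n_repeats: int = 10, seed: int = 0) -> CVPlan:
    """Repeated stratified fold assignment.

    Within each repeat the folds partition the subjects and, per class,
    fold sizes differ by at most one.  Deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    n = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ConfigurationError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} members < {n_folds} folds"
        )
    assignment = np.empty((n_repeats, n), dtype=np.int64)
    for r in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        for cls in classes:
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            for f, chunk in enumerate(np.array_split(idx, n_folds)):
                assignment[r, chunk] = f
    return CVPlan(assignment=assignment, n_folds=n_folds, n_repeats=n_repeats, seed=int(seed))


@dataclass
class ClassifierSpec:
    """A margin-based linear classifier with a penalty grid for C."""

    c_grid: tuple[float, ...] = (2**-5, 2**-3, 2**-1, 2**1, 2**3, 2**5)
    probability: bool = True

    def __post_init__(self) -> None:
        if len(self.c_grid) == 0:
            raise ConfigurationError("C grid must be non-empty")


@dataclass
class FoldResult:
    """Everything recorded for one (repeat, fold) evaluation."""

    repeat: int
    fold: int
    test_indices: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray  # probability (or decision value) of the positive class
    chosen_bins: int | None
    chosen_c: float
    top_units: list[tuple[bytes, np.ndarray, int]] = field(default_factory=list, repr=False)


@dataclass
class EvalSummary:
    """Metrics averaged over repeats plus the pooled ROC material."""

    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    positive_label: str
    per_repeat: pd.DataFrame
    pooled_truth: np.ndarray = field(repr=False, default=None)
    pooled_scores: np.ndarray = field(repr=False, default=None)


@dataclass
class EvalResult:
    summary: EvalSummary
    folds: list[FoldResult]
    plan: CVPlan


@dataclass
class RatioResult:
    """Mean weighted Euclidean distances to two groups and their ratio."""

    d_other: float
    d_target: float
    rho: float


# ---------------------------------------------------------------------------
# featurizers: each knows how to fit itself on training data only and turn
# any volume into a feature row
# ---------------------------------------------------------------------------


class GMMFeaturizer:
    """Cluster-based features with inner selection of the bin count.

    Clusters are discovered on the mean of the reference volumes (external
    ``reference_volumes`` when given, else the training members of
    ``reference_label``, defaulting to the least-impaired class present).
    When ``bin_grid`` has several values the count is chosen by accuracy on
    one stratified 80/20 sub-split of the training data, identical across
    bin sizes; ties go to the smaller count.
    """

    def __init__(
        self,
        mask: BrainMask,
        bin_grid=(50, 60, 70, 80, 90, 100, 110, 120, 130, 140, 150),
        criterion: str = "bic",
        top_m: int | None = None,
        reference_label: str | None = None,
        reference_volumes: list[Volume] | None = None,
        k_stride: int = 1,
        gmm_kws: dict | None = None,
        classifier: "ClassifierSpec | None" = None,
        ranking_method: str = "abs_t",
    ):
        self.mask = mask
        self.bin_grid = tuple(int(b) for b in bin_grid)
        if not self.bin_grid:
            raise ConfigurationError("bin_grid must be non-empty")
        self.criterion = criterion
        self.top_m = TOP_M_BY_CRITERION[criterion] if top_m is None else int(top_m)
        self.reference_label = reference_label
        self.reference_volumes = reference_volumes
        self.k_stride = k_stride
        # pipeline-scale EM settings: the coordinate clouds inside a bin are
        # small and only a hard partition is consumed, so fewer restarts and
        # a looser likelihood tolerance than the standalone fit defaults
        self.gmm_kws = {"n_restarts": 2, "tol": 1e-3, "max_iter": 100}
        self.gmm_kws.update(gmm_kws or {})
        self.classifier = classifier or ClassifierSpec(probability=False)
        self.ranking_method = ranking_method
        self.cluster_map_: ClusterMap | None = None
        self.chosen_bins_: int | None = None

    def _reference(self, train_volumes, train_labels) -> Volume:
        if self.reference_volumes is not None:
            return mean_reference_image(self.reference_volumes)
        label = self.reference_label
        if label is None:
            present = sorted(set(train_labels), key=lambda l: IMPAIRMENT_ORDER.get(l, 99))
            label = present[0]
        refs = [v for v, lab in zip(train_volumes, train_labels) if lab == label]
        if not refs:
            raise EvaluationError(f"no training volume carries reference label {label!r}")
        return mean_reference_image(refs)

    def _discover(self, reference: Volume, n_bins: int, seed: int) -> ClusterMap:
        return discover_clusters(
            reference,
            self.mask,
            n_bins,
            criterion=self.criterion,
            seed=_seed_int(seed, n_bins),
            k_stride=self.k_stride,
            **self.gmm_kws,
        )

    def fit(self, train_volumes, train_labels, seed: int = 0) -> "GMMFeaturizer":
        train_labels = np.asarray(train_labels)
        reference = self._reference(train_volumes, train_labels)
        if len(self.bin_grid) == 1:
            self.chosen_bins_ = self.bin_grid[0]
            self.cluster_map_ = self._discover(reference, self.chosen_bins_, seed)
            return self
        chosen, maps, _ = inner_select_bins(
            train_volumes,
            train_labels,
            reference=reference,
            discover=lambda n_bins: self._discover(reference, n_bins, seed),
            bin_grid=self.bin_grid,
            top_m=self.top_m,
            classifier=self.classifier,
            ranking_method=self.ranking_method,
            seed=seed,
        )
        self.chosen_bins_ = chosen
        self.cluster_map_ = maps[chosen]
        return self

    def transform(self, volumes) -> np.ndarray:
        if self.cluster_map_ is None:
            raise EvaluationError("featurizer not fitted")
        return np.stack([extract_features(v, self.cluster_map_) for v in volumes])

    @property
    def feature_names(self) -> list[str]:
        return cluster_feature_names(self.cluster_map_)

    def select(self, train_values, train_labels, seed: int = 0):
        ranking = rank_features(train_values, train_labels, method=self.ranking_method)
        return select_top_m(ranking, min(self.top_m, len(ranking.order))), ranking

    def feature_unit(self, feature_index: int):
        """Cluster behind a feature index (means block, then SDs block)."""
        n = len(self.cluster_map_.clusters)
        return self.cluster_map_.clusters[feature_index % n]


class AtlasFeaturizer:
    """Anatomical baseline: mean/SD per atlas region, no selection."""

    def __init__(self, atlas: Atlas):
        self.atlas = atlas

    def fit(self, train_volumes, train_labels, seed: int = 0) -> "AtlasFeaturizer":
        return self

    def transform(self, volumes) -> np.ndarray:
        return np.stack([atlas_features(v, self.atlas)[0] for v in volumes])

    def select(self, train_values, train_labels, seed: int = 0):
        return None

    chosen_bins_ = None


class TTestFeaturizer:
    """Mass-univariate baseline: raw intensities of the top t-test voxels."""

    def __init__(self, mask: BrainMask, alpha: float = TTEST_ALPHA, top_m: int = TTEST_TOP_M):
        self.mask = mask
        self.alpha = alpha
        self.top_m = top_m
        self.coords_: np.ndarray | None = None

    def fit(self, train_volumes, train_labels, seed: int = 0) -> "TTestFeaturizer":
        train_labels = np.asarray(train_labels)
        classes = np.unique(train_labels)
        if len(classes) != 2:
            raise EvaluationError("t-test featurizer needs exactly two classes")
        a = [v for v, lab in zip(train_volumes, train_labels) if lab == classes[0]]
        b = [v for v, lab in zip(train_volumes, train_labels) if lab == classes[1]]
        coords, _ = ttest_voxel_selection(a, b, self.mask, alpha=self.alpha, top_m=self.top_m)
        if coords.shape[0] == 0:
            logger.warning("t-test selected no voxel below alpha=%g; using the global best", self.alpha)
            coords, _ = ttest_voxel_selection(a, b, self.mask, alpha=1.1, top_m=self.top_m)
        self.coords_ = coords
        return self

    def transform(self, volumes) -> np.ndarray:
        if self.coords_ is None:
            raise EvaluationError("featurizer not fitted")
        return np.stack([v.data[tuple(self.coords_.T)] for v in volumes])

    def select(self, train_values, train_labels, seed: int = 0):
        return None

    chosen_bins_ = None


# ---------------------------------------------------------------------------
# inner bin selection and per-fold training
# ---------------------------------------------------------------------------


def inner_select_bins(
    train_volumes,
    train_labels,
    *,
    reference: Volume,
    discover,
    bin_grid,
    top_m: int,
    classifier: ClassifierSpec,
    ranking_method: str = "abs_t",
    seed: int = 0,
) -> tuple[int, dict[int, ClusterMap], dict[int, float]]:
    """Pick the bin count with the best sub-test accuracy on training data.

    One stratified 80/20 sub-split of the training subjects (identical for
    every bin size) is used: features are extracted per candidate map,
    ranked on the sub-training rows, and a linear classifier is trained on
    sub-training and scored on sub-test.  Ties break toward fewer bins.
    """
    train_labels = np.asarray(train_labels)
    sub_plan = stratified_folds(train_labels, n_folds=5, n_repeats=1, seed=_seed_int(seed, 7))
    sub_test = sub_plan.assignment[0] == 0
    sub_train = ~sub_test
    maps: dict[int, ClusterMap] = {}
    accs: dict[int, float] = {}
    for n_bins in sorted(set(int(b) for b in bin_grid)):
        cmap = discover(n_bins)
        maps[n_bins] = cmap
        values = np.stack([extract_features(v, cmap) for v in train_volumes])
        ranking = rank_features(values[sub_train], train_labels[sub_train], method=ranking_method)
        idx = select_top_m(ranking, min(top_m, len(ranking.order)))
        _, _, acc, _, _ = _fit_linear_svm(
            values[sub_train][:, idx],
            train_labels[sub_train],
            values[sub_test][:, idx],
            train_labels[sub_test],
            classifier,
            positive_label=None,
            seed=_seed_int(seed, 11, n_bins),
        )
        accs[n_bins] = acc
    chosen = max(sorted(accs), key=lambda b: (accs[b], -b))
    logger.debug("inner_select_bins: accuracies %s -> %d bins", accs, chosen)
    return chosen, maps, accs


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _choose_c(X, y, classifier: ClassifierSpec, seed: int) -> float:
    """Grid-search C by stratified CV accuracy on the training rows alone."""
    if len(classifier.c_grid) == 1:
        return classifier.c_grid[0]
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    k = int(min(3, counts.min()))
    if k < 2:
        return sorted(classifier.c_grid)[len(classifier.c_grid) // 2]
    plan = stratified_folds(y, n_folds=k, n_repeats=1, seed=seed)
    best_c, best_acc = None, -1.0
    for c in sorted(classifier.c_grid):
        correct = 0
        for f in range(k):
            te = plan.assignment[0] == f
            tr = ~te
            Xtr, Xte = _standardize(X[tr], X[te])
            clf = SVC(kernel="linear", C=c)
            clf.fit(Xtr, y[tr])
            correct += int((clf.predict(Xte) == y[te]).sum())
        acc = correct / len(y)
        if acc > best_acc:
            best_c, best_acc = c, acc
    return best_c


def _fit_linear_svm(Xtr, ytr, Xte, yte, classifier: ClassifierSpec, positive_label, seed: int):
    """Standardize, grid-search C, fit and score; returns (pred, scores, acc)."""
    c = _choose_c(Xtr, ytr, classifier, seed)
    Xtr_s, Xte_s = _standardize(Xtr, Xte)
    import warnings

    with warnings.catch_warnings():
        # sklearn >=1.9 deprecates SVC(probability=True); Platt-scaled
        # probabilities are exactly what the pooled ROC consumes here
        warnings.simplefilter("ignore", FutureWarning)
        clf = SVC(
            kernel="linear",
            C=c,
            probability=classifier.probability,
            random_state=seed % (2**31),
        )
        clf.fit(Xtr_s, ytr)
    pred = clf.predict(Xte_s)
    if positive_label is None:
        scores = np.zeros(len(pred))
    elif classifier.probability:
        pos_col = int(np.flatnonzero(clf.classes_ == positive_label)[0])
        scores = clf.predict_proba(Xte_s)[:, pos_col]
    else:
        # decision values are rank-equivalent for the ROC; sign toward positive
        sign = 1.0 if clf.classes_[1] == positive_label else -1.0
        scores = sign * clf.decision_function(Xte_s)
        logger.debug("using signed decision values as ROC scores")
    acc = float((pred == np.asarray(yte)).mean()) if len(yte) else 0.0
    return pred, scores, acc, c, clf


def default_positive_label(labels) -> str:
    """The more-impaired class (AD > MCI > NC); lexicographic fallback."""
    present = sorted(set(np.asarray(labels).tolist()))
    return max(present, key=lambda l: (IMPAIRMENT_ORDER.get(l, -1), l))


def train_eval_fold(
    volumes,
    labels,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    featurizer,
    classifier: ClassifierSpec,
    seed: int,
    positive_label: str,
    repeat: int = 0,
    fold: int = 0,
) -> FoldResult:
    """Fit the featurizer and classifier on the training fold, score the test fold.

    Every data-dependent choice (reference image, bin count, feature
    ranking, penalty C, standardization) is computed from training rows
    only.
    """
    labels = np.asarray(labels)
    ytr = labels[train_idx]
    if len(np.unique(ytr)) < 2:
        raise EvaluationError("training fold contains a single class")
    train_volumes = [volumes[i] for i in train_idx]
    test_volumes = [volumes[i] for i in test_idx]
    featurizer.fit(train_volumes, ytr, seed=seed)
    Xtr = featurizer.transform(train_volumes)
    Xte = featurizer.transform(test_volumes)
    selection = featurizer.select(Xtr, ytr, seed=seed)
    top_units: list[tuple[bytes, np.ndarray, int]] = []
    if selection is not None:
        idx, ranking = selection
        top_units = _top_units_from_ranking(featurizer, ranking)
        Xtr, Xte = Xtr[:, idx], Xte[:, idx]
    pred, scores, _, chosen_c, _ = _fit_linear_svm(
        Xtr, ytr, Xte, labels[test_idx], classifier, positive_label, seed=_seed_int(seed, 13)
    )
    return FoldResult(
        repeat=repeat,
        fold=fold,
        test_indices=np.asarray(test_idx),
        y_true=labels[test_idx],
        y_pred=np.asarray(pred),
        scores=np.asarray(scores),
        chosen_bins=getattr(featurizer, "chosen_bins_", None),
        chosen_c=float(chosen_c),
        top_units=top_units,
    )


def _top_units_from_ranking(featurizer, ranking: FeatureRanking, top_n: int = 10):
    """Top clusters by ranking position of their best feature; scores 10..1."""
    if not hasattr(featurizer, "feature_unit"):
        return []
    units: list[tuple[bytes, np.ndarray, int]] = []
    seen: set[int] = set()
    for feat in ranking.order:
        unit = featurizer.feature_unit(int(feat))
        if unit.id in seen:
            continue
        seen.add(unit.id)
        coords = np.ascontiguousarray(unit.coords, dtype=np.int64)
        key = coords.tobytes()
        units.append((key, coords, top_n - len(units)))
        if len(units) == top_n:
            break
    return units


def cross_validate(
    volumes,
    labels,
    featurizer,
    classifier: ClassifierSpec | None = None,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    positive_label: str | None = None,
) -> EvalResult:
    """Repeated stratified k-fold evaluation of one featurization pipeline."""
    labels = np.asarray(labels)
    classifier = classifier or ClassifierSpec()
    positive_label = positive_label or default_positive_label(labels)
    plan = stratified_folds(labels, n_folds=n_folds, n_repeats=n_repeats, seed=seed)
    folds: list[FoldResult] = []
    for r in range(n_repeats):
        for f in range(n_folds):
            test_idx = np.flatnonzero(plan.assignment[r] == f)
            train_idx = np.flatnonzero(plan.assignment[r] != f)
            folds.append(
                train_eval_fold(
                    volumes,
                    labels,
                    train_idx,
                    test_idx,
                    featurizer,
                    classifier,
                    seed=_seed_int(seed, r, f),
                    positive_label=positive_label,
                    repeat=r,
                    fold=f,
                )
            )
    return EvalResult(summary=summarize(folds, positive_label), folds=folds, plan=plan)


def summarize(folds: list[FoldResult], positive_label: str) -> EvalSummary:
    """Aggregate fold results by instance within each repeat, then average.

    Sensitivity is the true-positive rate on ``positive_label``;
    specificity the true-negative rate on the other class.  The AUC is
    computed once on the pooled (score, truth) pairs of all repeats.
    """
    rows = []
    for r in sorted({f.repeat for f in folds}):
        y_true = np.concatenate([f.y_true for f in folds if f.repeat == r])
        y_pred = np.concatenate([f.y_pred for f in folds if f.repeat == r])
        pos = y_true == positive_label
        rows.append(
            {
                "repeat": r,
                "accuracy": float((y_true == y_pred).mean()),
                "sensitivity": float((y_pred[pos] == positive_label).mean()) if pos.any() else np.nan,
                "specificity": float((y_pred[~pos] != positive_label).mean()) if (~pos).any() else np.nan,
            }
        )
    per_repeat = pd.DataFrame(rows)
    truth = np.concatenate([f.y_true for f in folds]) == positive_label
    scores = np.concatenate([f.scores for f in folds])
    auc, _ = auc_pooled(truth, scores)
    return EvalSummary(
        accuracy=float(per_repeat["accuracy"].mean()),
        auc=auc,
        sensitivity=float(per_repeat["sensitivity"].mean()),
        specificity=float(per_repeat["specificity"].mean()),
        positive_label=positive_label,
        per_repeat=per_repeat,
        pooled_truth=truth,
        pooled_scores=scores,
    )


def auc_pooled(truth, scores) -> tuple[float, pd.DataFrame]:
    """AUC of pooled test predictions, as the Mann-Whitney rank statistic.

    Ties count one half.  Also returns the ROC points (FPR, TPR) obtained
    by sweeping the score threshold.  Raises when one class is absent.
    """
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC undefined: pooled scores contain a single class")
    ranks = stats.rankdata(scores)
    auc = (ranks[truth].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(truth[order])
    fps = np.cumsum(~truth[order])
    roc = pd.DataFrame({"fpr": fps / n_neg, "tpr": tps / n_pos})
    return float(auc), roc


def corrected_resampled_ttest(diffs, n_train: int, n_test: int) -> tuple[float, float]:
    """Corrected paired t-test for per-run accuracy differences.

    t = mean(d) / sqrt((1/R + n_test/n_train) · var(d)) with R runs and the
    sample variance, referred to Student's t with R-1 degrees of freedom;
    the n_test/n_train term corrects for the overlap of resampled training
    sets.  Returns (t, two-tailed p).
    """
    d = np.asarray(diffs, dtype=np.float64)
    R = len(d)
    if R < 2:
        raise ConfigurationError("need at least 2 runs")
    var = float(d.var(ddof=1))
    mean = float(d.mean())
    if var == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        logger.warning("corrected t-test: zero variance with nonzero mean; p -> 0")
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / np.sqrt((1.0 / R + n_test / n_train) * var)
    p = 2.0 * stats.t.sf(abs(t), df=R - 1)
    return float(t), float(p)


def dissimilarity_ratio(test_row, other_rows, target_rows, weights) -> RatioResult:
    """Relative dissimilarity of a test case to two groups, Eq-style.

    All rows are re-weighted elementwise by the classifier weight vector;
    D_group is the mean Euclidean distance from the weighted test row to
    the weighted rows of a group.  rho = (D_other - D_target) / D_target,
    so larger rho means the case sits closer to the target group (e.g.
    other=MCI, target=AD: large rho reads "more AD-like").
    """
    w = np.asarray(weights, dtype=np.float64)
    t = np.asarray(test_row, dtype=np.float64) * w
    other = np.atleast_2d(np.asarray(other_rows, dtype=np.float64)) * w
    target = np.atleast_2d(np.asarray(target_rows, dtype=np.float64)) * w
    d_other = float(np.linalg.norm(other - t, axis=1).mean())
    d_target = float(np.linalg.norm(target - t, axis=1).mean())
    if d_target == 0.0:
        raise EvaluationError("mean distance to the target group is zero")
    return RatioResult(d_other=d_other, d_target=d_target, rho=(d_other - d_target) / d_target)


def informative_regions_report(
    folds: list[FoldResult], atlas: Atlas, top_n: int = 10
) -> pd.DataFrame:
    """Attribute the overall top-scoring clusters to atlas regions.

    Per fold, the ten best-ranked clusters receive 10..1 points; points
    are summed over all repeats and folds (clusters re-identified by their
    voxel set).  The voxels of the overall top-``top_n`` clusters are then
    attributed to atlas regions, and regions are ranked by their voxel
    share of those clusters (percentages sum to at most 100).
    """
    tally: dict[bytes, list] = {}
    for fr in folds:
        for key, coords, score in fr.top_units:
            if key in tally:
                tally[key][0] += score
            else:
                tally[key] = [score, coords]
    if not tally:
        return pd.DataFrame(columns=["region_code", "region_name", "share_pct"])
    top = sorted(tally.items(), key=lambda kv: (-kv[1][0], kv[0]))[:top_n]
    coords = np.concatenate([entry[1] for _, entry in top])
    region_codes = atlas.labels[tuple(coords.T)]
    total = len(region_codes)
    rows = []
    for code in np.unique(region_codes):
        if code == 0:
            continue
        share = 100.0 * float((region_codes == code).sum()) / total
        rows.append({"region_code": int(code), "region_name": atlas.names[int(code)], "share_pct": share})
    out = pd.DataFrame(rows).sort_values("share_pct", ascending=False, kind="stable")
    return out.reset_index(drop=True)
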