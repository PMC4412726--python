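"""Self-contained simulation studies at phantom scale.

These functions bundle the package's headline experiments so they can be
re-run identically from tests, examples and the acceptance script: the
component-count recovery study for BIC/AIC, and the end-to-end phantom
classification study (repeated stratified CV of the cluster-feature
pipeline on a synthetic cohort with planted hypometabolism, plus its
label-permuted control).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import (
    ClassifierSpec,
    EvalResult,
    GMMFeaturizer,
    cross_validate,
    informative_regions_report,
)
from .gmm_core import select_k
from .phantom import PhantomSpec, gmm_point_cloud, separated_mixture, simulate_cohort

#: Conditions of the end-to-end phantom study: 12-region brain, two
#: affected regions at the AD effect size (-15%), 10% voxel noise,
#: 20 classified subjects per group plus a disjoint 20-scan NC reference
#: pool, and a {8, 16} bin grid appropriate to the ~1.8k-voxel mask.
STUDY_N_PER_GROUP = 20
STUDY_BIN_GRID = (8, 16)

#: EM settings for phantom-scale pipelines (small coordinate clouds, hard
#: partition consumed): fewer restarts, looser likelihood tolerance.
STUDY_GMM_KWS = dict(n_restarts=1, tol=1e-2, max_iter=50)
STUDY_K_STRIDE = 2


def k_recovery_study(
    seed: int = 0,
    n_runs: int = 20,
    k_true_values: tuple[int, ...] = (2, 3, 4, 5, 6),
    separation: float = 8.0,
    n_points: int = 2000,
    k_grid: range = range(1, 9),
) -> pd.DataFrame:
    """Component-count recovery of BIC and AIC on well-separated mixtures.

    Each run draws ``n_points`` 3D points from an equal-weight mixture of
    K* unit-covariance Gaussians whose means are ``separation`` standard
    deviations apart (K* cycling through ``k_true_values``), then selects
    K over ``k_grid`` with both criteria.  Returns one row per run with
    the true and selected counts.
    """
    rows = []
    for run in range(n_runs):
        k_true = k_true_values[run % len(k_true_values)]
        run_seed = int(np.random.SeedSequence([int(seed), run]).generate_state(1)[0] % (2**31))
        weights, means, covs = separated_mixture(k_true, separation=separation, seed=run_seed)
        X, _ = gmm_point_cloud(k_true, weights, means, covs, n_points, seed=run_seed)
        sel = select_k(X, k_grid, criterion="bic", seed=run_seed, n_restarts=2, tol=1e-5)
        k_bic = sel.chosen_k
        k_aic = min(sorted(sel.aic), key=lambda k: (sel.aic[k], k))
        rows.append({"run": run, "k_true": k_true, "k_bic": k_bic, "k_aic": k_aic})
    return pd.DataFrame(rows)


def study_cohort(seed: int = 0):
    """The phantom cohort of the end-to-end study.

    Returns (cohort, reference_pool, classified volumes, labels): 40 NC
    are simulated and split into a 20-scan reference pool (used only to
    form the mean reference image, mirroring the use of NC scans external
    to the classified pair) and 20 classified NC, plus 20 AD.
    """
    spec = PhantomSpec(seed=int(seed))
    n = STUDY_N_PER_GROUP
    cohort = simulate_cohort(spec, {"NC": 2 * n, "AD": n})
    nc = cohort.group("NC")
    reference_pool = nc[:n]
    volumes = nc[n:] + cohort.group("AD")
    labels = np.array(["NC"] * n + ["AD"] * n)
    return cohort, reference_pool, volumes, labels


def phantom_classification_study(
    seed: int = 0,
    n_repeats: int = 10,
    n_folds: int = 10,
    permute_labels: bool = False,
) -> tuple[EvalResult, pd.DataFrame, tuple[int, ...]]:
    """End-to-end pipeline on the phantom cohort under repeated 10-fold CV.

    Returns (evaluation result, informative-regions report, ground-truth
    affected region codes).  With ``permute_labels`` the subject labels
    are randomly permuted first (chance-level control).
    """
    cohort, reference_pool, volumes, labels = study_cohort(seed)
    if permute_labels:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 999]))
        labels = rng.permutation(labels)
    featurizer = GMMFeaturizer(
        cohort.mask,
        bin_grid=STUDY_BIN_GRID,
        criterion="bic",
        reference_volumes=reference_pool,
        k_stride=STUDY_K_STRIDE,
        gmm_kws=STUDY_GMM_KWS,
    )
    result = cross_validate(
        volumes,
        labels,
        featurizer,
        classifier=ClassifierSpec(),
        n_folds=n_folds,
        n_repeats=n_repeats,
        seed=int(seed),
        positive_label="AD",
    )
    report = informative_regions_report(result.folds, cohort.atlas)
    return result, report, cohort.affected_regions
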