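"""Seeded synthetic data: mixture point clouds and brain-like phantoms.

Two families of generators:

* :func:`gmm_point_cloud` draws labelled samples from a known Gaussian
  mixture, for exercising EM and model-selection recovery.
* :func:`make_atlas_phantom` / :func:`simulate_cohort` build an ellipsoidal
  "brain" partitioned into contiguous Voronoi regions with region-wise
  baseline uptake, then simulate NC/MCI/AD cohorts by planting a fractional
  intensity reduction (hypometabolism) in chosen regions plus i.i.d.
  Gaussian voxel noise and an optional Gaussian blur.

Everything is deterministic given the spec seed; distinct subjects get
distinct noise streams derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .volume_io import Atlas, BrainMask, Volume

#: Fractional uptake reduction in affected regions, by diagnostic group.
DEFAULT_EFFECTS = {"NC": 0.0, "MCI": 0.07, "AD": 0.15}

GROUPS = ("NC", "MCI", "AD")


def gmm_point_cloud(
    K: int,
    weights: np.ndarray,
    means: np.ndarray,
    covs: np.ndarray,
    N: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw N i.i.d. points from a K-component Gaussian mixture.

    Returns (points (N, D), true component labels (N,)).
    """
    weights = np.asarray(weights, dtype=np.float64)
    means = np.atleast_2d(np.asarray(means, dtype=np.float64))
    covs = np.asarray(covs, dtype=np.float64)
    if covs.ndim == 2:
        covs = np.repeat(covs[None], K, axis=0)
    if weights.shape != (K,) or abs(weights.sum() - 1) > 1e-9 or np.any(weights < 0):
        raise ConfigurationError("weights must be a length-K simplex vector")
    if means.shape[0] != K or covs.shape[0] != K:
        raise ConfigurationError("means/covs must have K rows")
    for c in covs:
        np.linalg.cholesky(c)  # raises LinAlgError on invalid covariance
    rng = np.random.default_rng(seed)
    labels = rng.choice(K, size=N, p=weights)
    D = means.shape[1]
    X = np.empty((N, D))
    for k in range(K):
        member = labels == k
        X[member] = rng.multivariate_normal(means[k], covs[k], size=int(member.sum()))
    return X, labels


def separated_mixture(
    K: int, separation: float = 8.0, D: int = 3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equal-weight unit-covariance mixture with means ≥ ``separation`` apart.

    Means are distinct sites of a lattice with spacing ``separation``, so
    neighbouring components are exactly ``separation`` standard deviations
    apart.  Returns (weights, means, covs).
    """
    rng = np.random.default_rng(seed)
    side = int(np.ceil(K ** (1 / D))) + 1
    lattice = np.array(np.meshgrid(*[np.arange(side)] * D)).reshape(D, -1).T * separation
    sites = lattice[rng.choice(len(lattice), size=K, replace=False)]
    weights = np.full(K, 1.0 / K)
    covs = np.repeat(np.eye(D)[None], K, axis=0)
    return weights, sites.astype(np.float64), covs


@dataclass
class PhantomSpec:
    """Conditions of a synthetic brain cohort.

    The defaults describe the phantom regime used throughout the test
    studies: a 16×20×16 ellipsoidal brain of 12 contiguous regions with
    region baselines uniform in [0.7, 1.3] (the span of normalized FDG
    uptake from white matter to metabolically active cortex), two affected
    regions with MCI -7% / AD -15% uptake, and voxel noise with SD equal
    to 10% of the local baseline.
    """

    shape: tuple[int, int, int] = (16, 20, 16)
    n_regions: int = 12
    n_affected: int = 2
    affected_regions: tuple[int, ...] | None = None  # region codes; None = seeded pick
    baseline_range: tuple[float, float] = (0.7, 1.3)
    effect_sizes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    noise_sd: float = 0.10  # fraction of the local baseline
    smoothing_sigma: float = 0.0  # voxels; 0 disables the blur
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 <= e < 1 for e in self.effect_sizes.values()):
            raise ConfigurationError("effect sizes must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise SD must be non-negative")
        if self.baseline_range[0] <= 0:
            raise ConfigurationError("baselines must be positive")


def make_atlas_phantom(spec: PhantomSpec) -> tuple[Atlas, BrainMask, Volume]:
    """Ellipsoidal brain mask, Voronoi region atlas and baseline volume.

    The mask is the interior of an axis-aligned ellipsoid filling ~92% of
    each half-dimension.  Regions are the Voronoi cells of ``n_regions``
    random interior sites (contiguous, size-varied, mimicking the
    irregularity of anatomical atlas regions).  The baseline volume is
    constant within each region.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    shape = np.asarray(spec.shape)
    center = (shape - 1) / 2.0
    semi = 0.92 * center
    grid = np.indices(spec.shape).reshape(3, -1).T
    inside = (((grid - center) / semi) ** 2).sum(axis=1) <= 1.0
    coords = grid[inside]
    if coords.shape[0] < spec.n_regions:
        raise ConfigurationError(
            f"{spec.n_regions} regions exceed the {coords.shape[0]}-voxel mask"
        )
    mask = BrainMask(coords, tuple(int(s) for s in shape))
    sites = mask.indices[rng.choice(len(mask), size=spec.n_regions, replace=False)]
    region_of = cKDTree(sites.astype(float)).query(mask.indices.astype(float))[1]
    labels = np.zeros(spec.shape, dtype=np.int64)
    labels[tuple(mask.indices.T)] = region_of + 1
    names = {code: f"region_{code:02d}" for code in range(1, spec.n_regions + 1)}
    atlas = Atlas(labels, names)
    baselines = rng.uniform(*spec.baseline_range, size=spec.n_regions)
    data = np.zeros(spec.shape)
    data[tuple(mask.indices.T)] = baselines[region_of]
    return atlas, mask, Volume(data)


def _affected_codes(spec: PhantomSpec) -> tuple[int, ...]:
    if spec.affected_regions is not None:
        if not set(spec.affected_regions) <= set(range(1, spec.n_regions + 1)):
            raise ConfigurationError("affected regions must be valid region codes")
        return tuple(int(c) for c in spec.affected_regions)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    picked = rng.choice(np.arange(1, spec.n_regions + 1), size=spec.n_affected, replace=False)
    return tuple(int(c) for c in sorted(picked))


def simulate_subject(
    spec: PhantomSpec,
    group: str,
    subject_seed: int | None = None,
    atlas: Atlas | None = None,
    baseline: Volume | None = None,
) -> Volume:
    """One subject volume: baseline, group effect in affected regions, noise.

    Affected-region voxels are scaled by (1 - effect) for the subject's
    group; i.i.d. Gaussian noise with SD = ``noise_sd`` × local baseline is
    added inside the brain, followed by the optional blur.  NC has effect 0.
    """
    if group not in spec.effect_sizes:
        raise ConfigurationError(f"unknown group {group!r}")
    if atlas is None or baseline is None:
        atlas, _, baseline = make_atlas_phantom(spec)
    data = baseline.data.copy()
    affected = np.isin(atlas.labels, _affected_codes(spec))
    data[affected] *= 1.0 - spec.effect_sizes[group]
    brain = atlas.labels != 0
    if spec.noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed), 2, 0 if subject_seed is None else int(subject_seed)])
        )
        noise = rng.normal(size=data.shape) * (spec.noise_sd * baseline.data)
        data = data + np.where(brain, noise, 0.0)
    if spec.smoothing_sigma > 0:
        data = gaussian_filter(data, spec.smoothing_sigma)
        data[~brain] = 0.0
    return Volume(data)


@dataclass
class Cohort:
    """Simulated subjects with labels and the generating ground truth."""

    volumes: list[Volume]
    labels: list[str]
    subjects: list[str]
    spec: PhantomSpec
    affected_regions: tuple[int, ...]
    atlas: Atlas
    mask: BrainMask
    baseline: Volume

    def group(self, label: str) -> list[Volume]:
        return [v for v, lab in zip(self.volumes, self.labels) if lab == label]


def simulate_cohort(spec: PhantomSpec, n_per_group: dict[str, int]) -> Cohort:
    """Independent subjects per group, NC first, group order NC/MCI/AD.

    Subject noise seeds are derived deterministically from ``spec.seed``.
    """
    for g, n in n_per_group.items():
        if g not in GROUPS:
            raise ConfigurationError(f"unknown group {g!r}")
        if n < 0:
            raise ConfigurationError("group sizes must be >= 0")
    atlas, mask, baseline = make_atlas_phantom(spec)
    volumes: list[Volume] = []
    labels: list[str] = []
    subjects: list[str] = []
    counter = 0
    for group in GROUPS:
        for i in range(n_per_group.get(group, 0)):
            volumes.append(
                simulate_subject(spec, group, subject_seed=counter, atlas=atlas, baseline=baseline)
            )
            labels.append(group)
            subjects.append(f"{group}_{i:03d}")
            counter += 1
    return Cohort(
        volumes=volumes,
        labels=labels,
        subjects=subjects,
        spec=spec,
        affected_regions=_affected_codes(spec),
        atlas=atlas,
        mask=mask,
        baseline=baseline,
    )
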