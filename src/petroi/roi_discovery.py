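"""Two-phase ROI discovery: intensity binning, then spatial GMM clustering.

Masked voxels of a reference image (typically the mean of the normal-control
scans) are first grouped into ``n_bins`` equal-width intensity bins, so
voxels in one bin have similar uptake.  Each bin is then clustered on its
(x, y, z) voxel coordinates alone with a GMM whose component count is chosen
by BIC or AIC, yielding clusters that are both intensity-homogeneous and
geometrically compact.  All clusters from all bins together partition the
brain mask and serve as data-driven ROIs.

The candidate component counts per bin come from the rule that a cluster
should hold between 30 and 1000 voxels: K is searched over
[ceil(n/1000), floor(n/30)] for a bin of n voxels (clamped to (1, 1) when
that interval is empty).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SelectionError
from .gmm_core import assign_labels, select_k
from .volume_io import BrainMask, Volume

logger = logging.getLogger(__name__)

#: Target cluster-size bounds behind the K search range.
MAX_CLUSTER_VOXELS = 1000
MIN_CLUSTER_VOXELS = 30

#: Default diagnostic grid of bin counts.
DEFAULT_BIN_GRID: tuple[int, ...] = tuple(range(50, 151, 10))


@dataclass
class IntensityBin:
    """Voxels of one equal-width intensity interval.

    Bins are half-open [lo, hi); the last bin is closed above so the
    maximum intensity belongs to it.  Empty bins are retained (with empty
    arrays) so bin indices stay stable across runs.
    """

    index: int  # 1-based
    lo: float
    hi: float
    coords: np.ndarray  # (M, 3) int voxel indices
    intensities: np.ndarray  # (M,)

    def __len__(self) -> int:
        return int(self.coords.shape[0])


@dataclass
class Cluster:
    """A set of voxels produced by one mixture component of one bin."""

    id: int
    bin_index: int
    component_index: int
    coords: np.ndarray  # (M, 3) int

    def __len__(self) -> int:
        return int(self.coords.shape[0])


@dataclass
class ClusterMap:
    """All clusters discovered on one reference image.

    The clusters are pairwise disjoint and their union is exactly the
    brain mask they were discovered on.
    """

    clusters: list[Cluster]
    n_bins: int
    criterion: str
    shape: tuple[int, int, int]
    seed: int
    source: str = ""
    chosen_k_per_bin: dict[int, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clusters)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            for x, y, z in c.coords:
                rows.append((c.id, c.bin_index, int(x), int(y), int(z)))
        return pd.DataFrame(rows, columns=["cluster_id", "bin_index", "x", "y", "z"])

    def to_label_volume(self) -> Volume:
        """Label image with cluster_id + 1 at each voxel (0 = background)."""
        data = np.zeros(self.shape)
        for c in self.clusters:
            data[tuple(c.coords.T)] = c.id + 1
        return Volume(data)

    def save(self, directory: str | Path) -> None:
        """Write voxel table (TSV) plus a JSON sidecar of run metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(directory / "clusters.tsv", sep="\t", index=False)
        meta = {
            "n_bins": self.n_bins,
            "criterion": self.criterion,
            "seed": self.seed,
            "shape": list(self.shape),
            "source": self.source,
            "n_clusters": len(self.clusters),
            "chosen_k_per_bin": {str(k): v for k, v in self.chosen_k_per_bin.items()},
        }
        (directory / "clusters.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "ClusterMap":
        directory = Path(directory)
        meta = json.loads((directory / "clusters.json").read_text())
        table = pd.read_csv(directory / "clusters.tsv", sep="\t")
        clusters = []
        for cid, grp in table.groupby("cluster_id", sort=True):
            clusters.append(
                Cluster(
                    id=int(cid),
                    bin_index=int(grp["bin_index"].iloc[0]),
                    component_index=0,
                    coords=grp[["x", "y", "z"]].to_numpy(dtype=np.int64),
                )
            )
        return cls(
            clusters=clusters,
            n_bins=int(meta["n_bins"]),
            criterion=str(meta["criterion"]),
            shape=tuple(meta["shape"]),
            seed=int(meta["seed"]),
            source=str(meta.get("source", "")),
            chosen_k_per_bin={int(k): v for k, v in meta.get("chosen_k_per_bin", {}).items()},
        )


def make_bins(reference: Volume, mask: BrainMask, n_bins: int) -> list[IntensityBin]:
    """Split masked voxels into ``n_bins`` equal-width intensity bins.

    A constant image yields a single bin holding all masked voxels.
    """
    if n_bins < 1:
        raise ConfigurationError("n_bins must be >= 1")
    values = mask.values(reference)
    coords = mask.indices
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return [IntensityBin(1, lo, hi, coords.copy(), values.copy())]
    width = (hi - lo) / n_bins
    idx = np.minimum(np.floor((values - lo) / width).astype(np.int64), n_bins - 1)
    edges = lo + width * np.arange(n_bins + 1)
    bins = []
    for b in range(n_bins):
        member = idx == b
        bins.append(
            IntensityBin(b + 1, float(edges[b]), float(edges[b + 1]), coords[member], values[member])
        )
    return bins


def k_range(n_voxels: int) -> tuple[int, int]:
    """Candidate component-count interval for a bin of ``n_voxels`` voxels.

    [max(1, ceil(n/1000)), max(1, floor(n/30))]; (1, 1) when empty.
    """
    if n_voxels < 1:
        raise ConfigurationError("n_voxels must be >= 1")
    k_min = max(1, math.ceil(n_voxels / MAX_CLUSTER_VOXELS))
    k_max = max(1, math.floor(n_voxels / MIN_CLUSTER_VOXELS))
    if k_max < k_min:
        return (1, 1)
    return (k_min, k_max)


def cluster_bin(
    bin_: IntensityBin,
    criterion: str = "bic",
    seed: int = 0,
    k_stride: int = 1,
    **fit_kwargs,
) -> list[Cluster]:
    """Cluster one bin's voxels on (x, y, z) coordinates with GMM + selection.

    Returns one cluster per non-empty mixture component.  When the K search
    range degenerates to (1, 1), or every candidate fit fails, the whole bin
    becomes a single cluster.
    """
    n = len(bin_)
    if n == 0:
        raise ConfigurationError(f"bin {bin_.index} is empty")
    k_min, k_max = k_range(n)
    if k_stride > 1:
        logger.info("cluster_bin: scanning K with stride %d", k_stride)
    ks = [k for k in range(k_min, k_max + 1, max(1, int(k_stride))) if k <= n]
    if ks == [1] or (k_min, k_max) == (1, 1):
        return [Cluster(0, bin_.index, 0, bin_.coords.copy())]
    X = bin_.coords.astype(np.float64)
    try:
        sel = select_k(X, ks, criterion=criterion, seed=seed, **fit_kwargs)
    except SelectionError:
        logger.warning("cluster_bin: all fits failed for bin %d; one cluster", bin_.index)
        return [Cluster(0, bin_.index, 0, bin_.coords.copy())]
    labels = assign_labels(X, sel.best_fit.params)
    clusters = []
    next_id = 0
    for comp in range(sel.chosen_k):
        member = labels == comp
        if not member.any():
            continue
        clusters.append(Cluster(next_id, bin_.index, comp, bin_.coords[member]))
        next_id += 1
    return clusters


def discover_clusters(
    reference: Volume,
    mask: BrainMask,
    n_bins: int,
    criterion: str = "bic",
    seed: int = 0,
    k_stride: int = 1,
    source: str = "",
    **fit_kwargs,
) -> ClusterMap:
    """Full two-phase discovery: bin the mask, cluster every non-empty bin.

    Cluster ids are sequential over bins; deterministic given ``seed``.
    """
    bins = make_bins(reference, mask, n_bins)
    all_clusters: list[Cluster] = []
    chosen_k: dict[int, int] = {}
    next_id = 0
    for b in bins:
        if len(b) == 0:
            logger.debug("discover_clusters: bin %d empty, skipped", b.index)
            continue
        bin_seed = int(np.random.SeedSequence([int(seed), b.index]).generate_state(1)[0] % (2**31))
        found = cluster_bin(b, criterion=criterion, seed=bin_seed, k_stride=k_stride, **fit_kwargs)
        chosen_k[b.index] = len(found)
        for c in found:
            all_clusters.append(Cluster(next_id, c.bin_index, c.component_index, c.coords))
            next_id += 1
    return ClusterMap(
        clusters=all_clusters,
        n_bins=n_bins,
        criterion=criterion,
        shape=mask.shape,
        seed=int(seed),
        source=source,
        chosen_k_per_bin=chosen_k,
    )


def cluster_count_curve(
    reference: Volume,
    mask: BrainMask,
    bin_grid: list[int] | tuple[int, ...] = DEFAULT_BIN_GRID,
    criterion: str = "bic",
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Diagnostic: number of discovered clusters as a function of bin count."""
    if not bin_grid:
        raise ConfigurationError("bin_grid is empty")
    rows = []
    for n_bins in bin_grid:
        cmap = discover_clusters(reference, mask, n_bins, criterion=criterion, seed=seed, **kwargs)
        rows.append((int(n_bins), len(cmap)))
    return pd.DataFrame(rows, columns=["n_bins", "n_clusters"])
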