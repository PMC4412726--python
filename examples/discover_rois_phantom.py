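"""Discover data-driven ROIs on a synthetic brain phantom.

Builds a 12-region phantom, forms a mean reference image from 10
simulated normal-control scans, grand-mean normalizes it, and runs the
two-phase discovery (equal-width intensity bins, then spatial GMM
clustering with BIC selection inside each bin).  Prints the per-bin
cluster counts and the cluster-count-vs-bin-count diagnostic.
"""

import numpy as np

from petroi.phantom import PhantomSpec, simulate_cohort
from petroi.roi_discovery import cluster_count_curve, discover_clusters
from petroi.volume_io import grand_mean_normalize, mean_reference_image

cohort = simulate_cohort(PhantomSpec(seed=5), {"NC": 10})
reference = mean_reference_image(cohort.volumes)
reference = grand_mean_normalize(reference, cohort.mask)

cmap = discover_clusters(
    reference, cohort.mask, n_bins=8, criterion="bic", seed=0,
    n_restarts=1, tol=1e-2, max_iter=50,
)
sizes = np.array([len(c) for c in cmap.clusters])
print(f"mask of {len(cohort.mask)} voxels -> {len(cmap)} clusters from 8 bins")
print(f"cluster sizes: min {sizes.min()}, median {int(np.median(sizes))}, max {sizes.max()}")
print("clusters per bin:", dict(cmap.chosen_k_per_bin))

curve = cluster_count_curve(
    reference, cohort.mask, bin_grid=(4, 8, 16, 32), seed=0,
    n_restarts=1, tol=1e-2, max_iter=50,
)
print("\ncluster count vs bin count:")
print(curve.to_string(index=False))
# Every masked voxel sits in exactly one cluster; clusters are compact in
# space and homogeneous in intensity (within one bin width).  On a small
# mask the count grows with the bin count because many bins fall below the
# 30-voxel cluster floor and stay whole; on large masks, where K is driven
# by BIC inside the [n/1000, n/30] range, the trend reverses.
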