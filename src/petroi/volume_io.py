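"""Volumes, atlases, brain masks and intensity normalization.

A PET scan is handled as a plain 3D grid of relative-uptake intensities
(unitless after intensity normalization).  Volumes are expected to be
spatially normalized upstream, so all coordinates here are 0-based voxel
indices in the file's native (i, j, k) axis order; no world-space transform
is applied.  Intensities are stored as 64-bit floats internally regardless
of the on-disk dtype to keep the downstream EM numerics stable.

Two intensity-normalization schemes are provided:

* grand-mean: divide every voxel by the mean intensity over all brain
  voxels (non-brain voxels excluded from the mean, but divided too);
* pSMC: divide by the mean over the primary sensorimotor cortex reference
  regions (pre- and postcentral gyri, left and right).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, NormalizationError

#: AAL names of the primary sensorimotor cortex reference regions.
PSMC_REGIONS: tuple[str, ...] = (
    "Precentral_L",
    "Precentral_R",
    "Postcentral_L",
    "Postcentral_R",
)


@dataclass
class Volume:
    """A 3D intensity grid.

    Parameters
    ----------
    data
        3D array of finite intensities; converted to float64.
    voxel_size_mm
        Voxel edge lengths in mm.  Metadata only; never used in computation.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass
class Atlas:
    """A label volume partitioning the brain into named regions.

    ``labels`` holds non-negative integer region codes, 0 meaning
    background / non-brain.  Every nonzero code present in ``labels``
    must have an entry in ``names``.
    """

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("atlas labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded, atol=1e-6):
                raise FormatError("atlas labels must be (near-)integer codes")
            self.labels = rounded.astype(np.int64)
        if self.labels.min() < 0:
            raise FormatError("atlas labels must be non-negative")
        present = {int(c) for c in np.unique(self.labels) if c != 0}
        missing = present - set(self.names)
        if missing:
            # auto-name codes the caller did not label
            for code in sorted(missing):
                self.names[code] = f"region_{code:03d}"

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    @property
    def codes(self) -> list[int]:
        """Sorted nonzero region codes present in the label volume."""
        return [int(c) for c in np.unique(self.labels) if c != 0]

    def code_for_name(self, name: str) -> int:
        for code, n in self.names.items():
            if n == name:
                return code
        raise ConfigurationError(f"unknown atlas region name: {name!r}")


class BrainMask:
    """A non-empty set of in-brain voxel coordinates.

    Stored both as an (N, 3) array of 0-based (x, y, z) indices and as a
    boolean volume for fast fancy indexing.
    """

    def __init__(self, indices: np.ndarray, shape: tuple[int, int, int]):
        indices = np.asarray(indices, dtype=np.int64)
        if indices.ndim != 2 or indices.shape[1] != 3:
            raise ConfigurationError("mask indices must be an (N, 3) array")
        if indices.shape[0] == 0:
            raise ConfigurationError("empty mask")
        if indices.min() < 0 or np.any(indices >= np.asarray(shape)):
            raise ConfigurationError("mask coordinates outside the volume shape")
        self.shape = tuple(int(s) for s in shape)
        # canonical ordering (lexicographic) so masks compare reproducibly
        order = np.lexsort((indices[:, 2], indices[:, 1], indices[:, 0]))
        self.indices = indices[order]

    @classmethod
    def from_boolean(cls, boolean: np.ndarray) -> "BrainMask":
        boolean = np.asarray(boolean, dtype=bool)
        return cls(np.argwhere(boolean), boolean.shape)

    def to_boolean(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        out[tuple(self.indices.T)] = True
        return out

    def values(self, volume: Volume) -> np.ndarray:
        """Intensities of ``volume`` at the mask's voxels, in mask order."""
        if volume.shape != self.shape:
            raise ConfigurationError(
                f"volume shape {volume.shape} != mask shape {self.shape}"
            )
        return volume.data[tuple(self.indices.T)]

    def __len__(self) -> int:
        return int(self.indices.shape[0])


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) file into a :class:`Volume`."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # nibabel raises a zoo of exceptions
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return Volume(data, voxel_size_mm=tuple(float(z) for z in zooms))


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a :class:`Volume` to NIfTI, as float32."""
    affine = np.diag(list(volume.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    nib.save(img, str(path))


def read_atlas(path: str | Path, names_path: str | Path | None = None) -> Atlas:
    """Read an atlas label volume, optionally with a code<TAB>name table."""
    vol = read_volume(path)
    names: dict[int, str] = {}
    if names_path is not None:
        table = pd.read_csv(names_path, sep="\t", header=None, names=["code", "name"])
        names = {int(r.code): str(r.name) for r in table.itertuples()}
    return Atlas(vol.data, names)


def write_atlas(atlas: Atlas, path: str | Path, names_path: str | Path | None = None) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), np.eye(4))
    nib.save(img, str(path))
    if names_path is not None:
        pd.DataFrame(
            sorted(atlas.names.items()), columns=["code", "name"]
        ).to_csv(names_path, sep="\t", header=False, index=False)


def mask_from_atlas(atlas: Atlas, codes: set[int] | str = "all nonzero") -> BrainMask:
    """Brain mask of the voxels whose atlas label is in ``codes``.

    ``codes="all nonzero"`` takes every labelled (nonzero) voxel.
    """
    if isinstance(codes, str):
        if codes != "all nonzero":
            raise ConfigurationError(f"unknown codes spec: {codes!r}")
        boolean = atlas.labels != 0
    else:
        boolean = np.isin(atlas.labels, sorted(int(c) for c in codes))
    if not boolean.any():
        raise ConfigurationError("empty mask: no voxel carries the requested codes")
    return BrainMask.from_boolean(boolean)


def grand_mean_normalize(volume: Volume, mask: BrainMask) -> Volume:
    """Divide every voxel by the mean intensity over the brain mask.

    After normalization the masked mean equals 1.  Voxels outside the mask
    are divided by the same constant (they are excluded from the mean only).
    """
    ref = float(mask.values(volume).mean())
    if not np.isfinite(ref) or ref <= 0:
        raise NormalizationError(f"masked mean is {ref}; cannot normalize")
    return Volume(volume.data / ref, volume.voxel_size_mm)


def psmc_normalize(
    volume: Volume,
    atlas: Atlas,
    region_names: list[str] | tuple[str, ...] = PSMC_REGIONS,
) -> Volume:
    """Divide every voxel by the mean over the named reference regions.

    Defaults to the four primary sensorimotor cortex regions (pre/postcentral
    gyri), a reference whose metabolism is relatively spared in dementia.
    """
    codes = {atlas.code_for_name(n) for n in region_names}
    ref_mask = mask_from_atlas(atlas, codes)
    ref = float(ref_mask.values(volume).mean())
    if not np.isfinite(ref) or ref <= 0:
        raise NormalizationError(f"reference-region mean is {ref}; cannot normalize")
    return Volume(volume.data / ref, volume.voxel_size_mm)


def mean_reference_image(volumes: list[Volume]) -> Volume:
    """Voxel-wise arithmetic mean of same-shape volumes."""
    if len(volumes) == 0:
        raise ConfigurationError("need at least one volume to average")
    shape = volumes[0].shape
    for v in volumes[1:]:
        if v.shape != shape:
            raise ConfigurationError(f"shape mismatch: {v.shape} != {shape}")
    stacked = np.stack([v.data for v in volumes])
    return Volume(stacked.mean(axis=0), volumes[0].voxel_size_mm)
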