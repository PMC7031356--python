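"""Mean time-series extraction from a 4-D image and an integer parcellation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import RegionTimeSeries


@dataclass
class Parcellation:
    """3-D integer label volume; 0 is background, region ids are sorted."""

    label_volume: np.ndarray
    region_names: dict[int, str] | None = None
    region_ids: list[int] = field(init=False)

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            raise ValueError("label volume must be an integer array")
        if np.any(self.label_volume < 0):
            raise ValueError("labels must be >= 0 (0 = background)")
        ids = np.unique(self.label_volume)
        self.region_ids = [int(i) for i in ids if i > 0]
        if not self.region_ids:
            raise ValueError("label volume contains no positive region labels")


def extract_mean_timeseries(
    image: np.ndarray,
    parcellation: Parcellation,
    subject_id: str = "",
) -> RegionTimeSeries:
    """Average voxel signals within each label, per timepoint.

    Column j is the unweighted mean over voxels labelled
    ``parcellation.region_ids[j]``; NaN voxels are excluded from the mean and
    a region with no usable voxels is rejected by name.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 4:
        raise ValueError("image must be 4-D (x, y, z, t)")
    if image.shape[:3] != parcellation.label_volume.shape:
        raise ValueError(
            f"spatial shape mismatch: image {image.shape[:3]} vs "
            f"labels {parcellation.label_volume.shape}"
        )
    n_t = image.shape[3]
    columns = np.empty((n_t, len(parcellation.region_ids)))
    for j, region_id in enumerate(parcellation.region_ids):
        mask = parcellation.label_volume == region_id
        if not mask.any():
            raise ValueError(f"region {region_id} has no voxels")
        voxels = image[mask]  # (n_voxels, T)
        valid = ~np.isnan(voxels)
        counts = valid.sum(axis=0)
        if np.any(counts == 0):
            raise ValueError(
                f"region {region_id} has no unmasked voxels at some timepoints"
            )
        columns[:, j] = np.where(valid, voxels, 0.0).sum(axis=0) / counts
    return RegionTimeSeries(
        subject_id=subject_id, data=columns, region_ids=list(parcellation.region_ids)
    )
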