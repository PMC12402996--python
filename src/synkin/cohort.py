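"""The multi-subject beta-volume container shared by all analysis stages.

Volumes live on one grid with one brain mask. Internally data are kept
masked — a (subjects, objects, in-mask voxels) array — because every
statistic here operates on in-mask voxels; 3-D views are materialized on
demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DimensionMismatchError(ValueError):
    """Inputs do not agree on grid, mask, or object inventory."""


def default_affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def ellipsoid_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Inscribed-ellipsoid brain mask leaving a 1-voxel border."""
    radii = [(g - 2) / 2.0 for g in grid_shape]
    centers = [(g - 1) / 2.0 for g in grid_shape]
    coords = np.indices(grid_shape).astype(float)
    d2 = sum(
        ((coords[i] - centers[i]) / max(radii[i], 0.5)) ** 2 for i in range(3)
    )
    return d2 <= 1.0


@dataclass
class BetaCohort:
    """Per-subject, per-object response-estimate volumes on a shared grid.

    Parameters
    ----------
    data : ndarray, shape (n_subjects, n_objects, n_voxels)
        In-mask values, voxel order = ``np.flatnonzero(mask)``.
    mask : ndarray of bool, 3-D
        Brain mask defining the voxel axis.
    affine : ndarray, shape (4, 4)
        Grid-to-world affine (records voxel size).
    """

    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    subject_ids: list[str]
    object_ids: list[str]
    voxel_size_mm: float = field(default=3.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise DimensionMismatchError("data must be (subjects, objects, voxels)")
        if self.data.shape[0] != len(self.subject_ids):
            raise DimensionMismatchError(
                f"{self.data.shape[0]} volumes rows vs {len(self.subject_ids)} subject ids"
            )
        if self.data.shape[1] != len(self.object_ids):
            raise DimensionMismatchError(
                f"{self.data.shape[1]} volume columns vs {len(self.object_ids)} object ids"
            )
        if self.data.shape[2] != int(self.mask.sum()):
            raise DimensionMismatchError(
                f"data has {self.data.shape[2]} voxels but mask has {int(self.mask.sum())}"
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_objects(self) -> int:
        return self.data.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[2]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def unmask(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Embed a (..., n_voxels) array into full (..., x, y, z) volumes."""
        values = np.asarray(values)
        out = np.full(values.shape[:-1] + self.mask.shape, fill, dtype=float)
        out[..., self.mask] = values
        return out

    def volume(self, subject: str, obj: str) -> np.ndarray:
        s = self.subject_ids.index(subject)
        o = self.object_ids.index(obj)
        return self.unmask(self.data[s, o])

    def subject_matrix(self, subject: str | int) -> np.ndarray:
        """(n_objects, n_voxels) matrix for one subject."""
        s = subject if isinstance(subject, int) else self.subject_ids.index(subject)
        return self.data[s]
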