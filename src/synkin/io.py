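"""Readers and writers: NIfTI cohorts with JSON manifests, CSV tables.

A cohort directory contains one NIfTI per (subject, object), a brain
mask volume, and ``manifest.json`` listing the inventory; missing files
are reported by name.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from synkin.cohort import BetaCohort, DimensionMismatchError, default_affine
from synkin.space import Dendrogram, RatingMatrix, SimilarityMatrix

MANIFEST_NAME = "manifest.json"
MASK_NAME = "mask.nii"


class InventoryError(FileNotFoundError):
    """A (subject, object) volume named in the manifest is missing."""


def _beta_filename(subject: str, obj: str) -> str:
    return f"{subject}_{obj}_beta.nii"


def write_cohort(cohort: BetaCohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(cohort.mask.astype(np.uint8), cohort.affine), out / MASK_NAME)
    for s, subject in enumerate(cohort.subject_ids):
        for o, obj in enumerate(cohort.object_ids):
            vol = cohort.unmask(cohort.data[s, o], fill=0.0)
            nib.save(nib.Nifti1Image(vol.astype(np.float64), cohort.affine),
                     out / _beta_filename(subject, obj))
    manifest = {
        "subject_ids": cohort.subject_ids,
        "object_ids": cohort.object_ids,
        "voxel_size_mm": cohort.voxel_size_mm,
        "grid_shape": list(cohort.grid_shape),
        "mask": MASK_NAME,
        "files": {
            subject: {obj: _beta_filename(subject, obj) for obj in cohort.object_ids}
            for subject in cohort.subject_ids
        },
    }
    (out / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))
    return out


def read_cohort(in_dir: str | Path) -> BetaCohort:
    """Load a cohort directory, validating the shared grid and inventory."""
    src = Path(in_dir)
    manifest = json.loads((src / MANIFEST_NAME).read_text())
    mask_img = nib.load(src / manifest["mask"])
    mask = np.asarray(mask_img.dataobj).astype(bool)
    affine = mask_img.affine
    subject_ids = list(manifest["subject_ids"])
    object_ids = list(manifest["object_ids"])
    n_vox = int(mask.sum())
    data = np.empty((len(subject_ids), len(object_ids), n_vox))
    for s, subject in enumerate(subject_ids):
        for o, obj in enumerate(object_ids):
            fname = manifest["files"][subject][obj]
            path = src / fname
            if not path.exists():
                raise InventoryError(f"missing volume for ({subject}, {obj}): {fname}")
            img = nib.load(path)
            vol = np.asarray(img.dataobj, dtype=float)
            if vol.shape != mask.shape:
                raise DimensionMismatchError(
                    f"volume {fname} grid {vol.shape} does not match mask {mask.shape}"
                )
            data[s, o] = vol[mask]
    return BetaCohort(
        data=data,
        mask=mask,
        affine=affine,
        subject_ids=subject_ids,
        object_ids=object_ids,
        voxel_size_mm=float(manifest.get("voxel_size_mm", abs(affine[0, 0]))),
    )


def write_volume(values: np.ndarray, mask: np.ndarray, path: str | Path,
                 voxel_size_mm: float = 3.0, affine: np.ndarray | None = None) -> None:
    """Write a masked vector or full volume as NIfTI (NaN-filled outside)."""
    if values.ndim == 1:
        vol = np.full(mask.shape, np.nan)
        vol[np.asarray(mask, dtype=bool)] = values
    else:
        vol = values
    aff = affine if affine is not None else default_affine(voxel_size_mm)
    nib.save(nib.Nifti1Image(vol.astype(np.float64), aff), str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


# ---------------------------------------------------------------------------
# Delimited text tables


def write_ratings_csv(ratings: RatingMatrix, path: str | Path) -> None:
    df = pd.DataFrame(ratings.loadings, index=ratings.synergy_ids, columns=ratings.object_ids)
    df.to_csv(path, index_label="synergy_id")


def read_ratings_csv(path: str | Path) -> RatingMatrix:
    df = pd.read_csv(path, index_col=0)
    return RatingMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns])


def write_scores_csv(object_ids: list[str], values: np.ndarray, path: str | Path,
                     value_name: str = "value") -> None:
    pd.DataFrame({"object_id": object_ids, value_name: values}).to_csv(path, index=False)


def read_scores_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    return [str(o) for o in df.iloc[:, 0]], df.iloc[:, 1].to_numpy(dtype=float)


def write_similarity_csv(sim: SimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(sim.values, index=sim.object_ids, columns=sim.object_ids)
    df.to_csv(path, index_label=sim.mode)


def read_similarity_csv(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    mode = str(df.index.name) if df.index.name in ("similarity", "dissimilarity") else None
    values = df.to_numpy(dtype=float)
    if mode is None:
        mode = "similarity" if np.allclose(np.diag(values), 1.0) else "dissimilarity"
    return SimilarityMatrix(values, mode, [str(c) for c in df.columns])


def write_newick(tree: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
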