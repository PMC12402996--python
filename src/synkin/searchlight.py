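"""Multivoxel searchlight RSA against a model similarity matrix.

At every in-mask sphere center the local neural RSM (Pearson similarity
of object patterns over the sphere's voxels) is compared with a model
RSM on the strictly-lower triangle, by Spearman rank correlation by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from synkin.cohort import BetaCohort
from synkin.space import InvalidInputError, SimilarityMatrix


class UndefinedComparisonError(ValueError):
    """Model RSM has no off-diagonal variance; nothing to correlate."""


@dataclass
class SearchlightSpec:
    radius: float = 3.0  # voxel units
    min_voxels: int = 10
    comparison: str = "spearman"  # or "pearson"

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise InvalidInputError("searchlight radius must be >= 1 voxel")
        if self.min_voxels < 3:
            raise InvalidInputError("min_voxels must be >= 3")
        if self.comparison not in ("spearman", "pearson"):
            raise InvalidInputError(f"unknown comparison {self.comparison!r}")


def neural_rsm(patterns: np.ndarray, object_ids: list[str] | None = None) -> SimilarityMatrix:
    """Pearson similarity between object pattern vectors.

    Entries involving a zero-variance object pattern are NaN (flagged,
    not silently zeroed).
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[0] < 3:
        raise InvalidInputError("patterns must be (>=3 objects, voxels)")
    if patterns.shape[1] < 2:
        raise InvalidInputError("need >= 2 voxels per pattern")
    ids = object_ids or [f"obj{i:03d}" for i in range(patterns.shape[0])]
    sd = patterns.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(patterns)
    bad = sd == 0
    if bad.any():
        r[bad, :] = np.nan
        r[:, bad] = np.nan
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix(r, "similarity", ids)


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer offsets within Euclidean ``radius`` voxels (center included)."""
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def build_searchlight_indices(
    mask: np.ndarray, spec: SearchlightSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Per-center neighbor lists into the masked voxel axis.

    Returns
    -------
    neighbors : int ndarray, (n_centers, n_offsets); -1 marks out-of-sphere
    counts : int ndarray, (n_centers,) of valid neighbors
    """
    offs = sphere_offsets(spec.radius)
    idx_vol = np.full(mask.shape, -1, dtype=np.int64)
    idx_vol[mask] = np.arange(int(mask.sum()))
    centers = np.argwhere(mask)
    nbr = centers[:, None, :] + offs[None, :, :]
    inb = ((nbr >= 0) & (nbr < np.asarray(mask.shape)[None, None, :])).all(axis=2)
    flat = np.full((centers.shape[0], offs.shape[0]), -1, dtype=np.int64)
    ii = np.nonzero(inb)
    flat[ii] = idx_vol[nbr[ii][:, 0], nbr[ii][:, 1], nbr[ii][:, 2]]
    counts = (flat >= 0).sum(axis=1)
    return flat, counts


def _triangle(values: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(values.shape[0], k=-1)
    return values[i, j]


def _fast_ranks(x: np.ndarray) -> np.ndarray:
    """Ordinal ranks along the last axis (ties broken by order; with
    continuous data, tied values have measure zero)."""
    order = np.argsort(x, axis=-1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(x.shape[-1])[(None,) * (x.ndim - 1)], axis=-1)
    return ranks.astype(float)


def _searchlight_batch(
    data: np.ndarray,
    mask: np.ndarray,
    model_rsm: SimilarityMatrix,
    spec: SearchlightSpec,
    precomputed: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Searchlight maps for a (subjects, objects, voxels) stack.

    One pass over centers serves every subject: per sphere the neural
    RSM triangles for all subjects come from a single batched matmul.
    """
    model = model_rsm.to_rsm()
    n_sub, n_obj, n_vox = data.shape
    if n_obj != model.n_objects:
        raise InvalidInputError("data objects do not match model RSM")
    model_tri = _triangle(model.values)
    if np.nanstd(model_tri) == 0:
        raise UndefinedComparisonError("model RSM off-diagonal is constant")
    model_cmp = rankdata(model_tri) if spec.comparison == "spearman" else model_tri
    mc = model_cmp - model_cmp.mean()
    mc_norm = np.sqrt((mc**2).sum())

    neighbors, counts = (
        precomputed if precomputed is not None else build_searchlight_indices(mask, spec)
    )
    tri_i, tri_j = np.tril_indices(n_obj, k=-1)
    out = np.full((n_sub, n_vox), np.nan)
    for c in range(n_vox):
        if counts[c] < spec.min_voxels:
            continue
        idx = neighbors[c]
        idx = idx[idx >= 0]
        P = data[:, :, idx]  # (S, O, k)
        Pc = P - P.mean(axis=2, keepdims=True)
        norms = np.sqrt(np.einsum("sok,sok->so", Pc, Pc))
        if (norms == 0).any():
            continue  # zero-variance pattern: comparison flagged invalid
        C = (Pc @ Pc.transpose(0, 2, 1)) / (norms[:, :, None] * norms[:, None, :])
        neural = C[:, tri_i, tri_j]  # (S, n_pairs)
        nc = _fast_ranks(neural) if spec.comparison == "spearman" else neural
        nc = nc - nc.mean(axis=1, keepdims=True)
        denom = np.sqrt((nc**2).sum(axis=1)) * mc_norm
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, c] = (nc @ mc) / denom
    return out


def searchlight_map(
    subject_data: np.ndarray,
    mask: np.ndarray,
    model_rsm: SimilarityMatrix,
    spec: SearchlightSpec | None = None,
    precomputed: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Whole-brain searchlight r for one subject.

    Parameters
    ----------
    subject_data : ndarray, (n_objects, n_voxels)
        Masked object betas, object order matching ``model_rsm``.
    precomputed : optional output of :func:`build_searchlight_indices`.

    Returns
    -------
    ndarray, (n_voxels,) of r values; NaN where the sphere has fewer than
    ``min_voxels`` in-mask voxels or the comparison is undefined.
    """
    spec = spec or SearchlightSpec()
    return _searchlight_batch(subject_data[None], mask, model_rsm, spec, precomputed)[0]


def searchlight_cohort(
    cohort: BetaCohort, model_rsm: SimilarityMatrix, spec: SearchlightSpec | None = None
) -> np.ndarray:
    """Per-subject searchlight maps, shape (n_subjects, n_voxels)."""
    spec = spec or SearchlightSpec()
    if list(model_rsm.object_ids) != list(cohort.object_ids):
        raise InvalidInputError("model RSM objects do not match cohort")
    pre = build_searchlight_indices(cohort.mask, spec)
    return _searchlight_batch(cohort.data, cohort.mask, model_rsm, spec, precomputed=pre)
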