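"""Group-level inference over per-subject voxel maps.

Pipeline order: r -> Fisher z -> smooth -> one-sample t -> TFCE ->
sign-flip permutation correction. Cluster-based alternatives (FDR over
clusters at a fixed height threshold, and a Monte-Carlo cluster-extent
threshold) share the same sign-flip null machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from synkin.config import InvalidConfigError
from synkin.space import InvalidInputError

FISHER_CLIP = 1.0 - 1e-7
_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # face connectivity


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh of r clipped to +-(1 - 1e-7); NaN (invalid) propagates."""
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmax(np.abs(r)) > 1 + 1e-12:
            raise InvalidInputError("r values outside [-1, 1]")
    return np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))


def smooth_volumes(
    values: np.ndarray,
    mask: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float,
) -> np.ndarray:
    """Gaussian-smooth masked maps with edge renormalization.

    ``values`` is (..., n_voxels) over the masked voxel axis. The kernel
    SD is ``fwhm / (2 sqrt(2 ln 2))`` per axis; smoothing is computed as
    smooth(data * w) / smooth(w) with w the per-map validity weights, so
    in-mask constants are preserved and NaNs do not bleed.
    """
    if fwhm_mm < 0:
        raise InvalidConfigError("fwhm must be nonnegative")
    values = np.asarray(values, dtype=float)
    if fwhm_mm == 0:
        return values.copy()
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    flat = values.reshape(-1, values.shape[-1])
    out = np.empty_like(flat)
    for k in range(flat.shape[0]):
        vol = np.zeros(mask.shape)
        w = np.zeros(mask.shape)
        valid = np.isfinite(flat[k])
        vox = np.flatnonzero(mask.ravel())
        vol.ravel()[vox[valid]] = flat[k][valid]
        w.ravel()[vox[valid]] = 1.0
        sv = ndimage.gaussian_filter(vol, sigma=sigma)
        sw = ndimage.gaussian_filter(w, sigma=sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = sv / sw
        res = np.full(flat.shape[1], np.nan)
        res[valid] = sm.ravel()[vox[valid]]
        out[k] = res
    return out.reshape(values.shape)


def group_ttest(
    z: np.ndarray, min_valid_frac: float = 0.8
) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t against zero at each voxel, over subjects present there.

    Voxels valid in fewer than ``min_valid_frac`` of subjects, with fewer
    than 2 valid subjects, or with zero variance are flagged NaN rather
    than forced toward zero.

    Returns
    -------
    t : ndarray (n_voxels,)
    n_valid : int ndarray (n_voxels,)
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2:
        raise InvalidInputError("z must be (n_subjects, n_voxels)")
    valid = np.isfinite(z)
    n_valid = valid.sum(axis=0)
    n_sub = z.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_valid > 0, np.nansum(np.where(valid, z, 0.0), axis=0) / n_valid, np.nan)
        ss = np.nansum(np.where(valid, (z - mean[None, :]) ** 2, 0.0), axis=0)
        var = ss / np.maximum(n_valid - 1, 1)
        t = mean / np.sqrt(var / n_valid)
    bad = (n_valid < 2) | (n_valid < min_valid_frac * n_sub) | (var == 0)
    t = np.where(bad, np.nan, t)
    return t, n_valid


# ---------------------------------------------------------------------------
# TFCE


def _tfce_one_sided_reference(vol: np.ndarray, H: float, E: float, n_steps: int) -> np.ndarray:
    """Step-wise relabeling route; kept as the slow reference implementation."""
    out = np.zeros_like(vol)
    vmax = float(vol.max(initial=0.0))
    if vmax <= 0:
        return out
    dh = vmax / n_steps
    for j in range(n_steps):
        h = (j + 0.5) * dh  # midpoint rule
        supra = vol > h
        if not supra.any():
            break
        labels, n = ndimage.label(supra, structure=_STRUCT6)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        out += np.where(supra, sizes[labels] ** E * (h**H) * dh, 0.0)
    return out


try:  # compiled incremental route: union-find over descending thresholds
    import numba

    @numba.njit(cache=True)
    def _tfce_kernel(vol, nx, ny, nz, H, E, n_steps):  # pragma: no cover - jit
        n = vol.size
        out = np.zeros(n)
        vmax = 0.0
        for i in range(n):
            if vol[i] > vmax:
                vmax = vol[i]
        if vmax <= 0.0:
            return out
        dh = vmax / n_steps
        order = np.argsort(-vol)
        parent = np.full(n, -1, dtype=np.int64)
        size = np.zeros(n, dtype=np.int64)

        def find(parent, v):
            root = v
            while parent[root] != root:
                root = parent[root]
            while parent[v] != root:  # path compression
                nxt = parent[v]
                parent[v] = root
                v = nxt
            return root

        sy = nz
        sx = ny * nz
        ptr = 0
        for j in range(n_steps - 1, -1, -1):
            h = (j + 0.5) * dh
            while ptr < n and vol[order[ptr]] > h:
                v = order[ptr]
                parent[v] = v
                size[v] = 1
                x = v // sx
                rem = v - x * sx
                y = rem // sy
                z = rem - y * sy
                for d in range(6):
                    if d == 0:
                        ok = x > 0
                        w = v - sx
                    elif d == 1:
                        ok = x < nx - 1
                        w = v + sx
                    elif d == 2:
                        ok = y > 0
                        w = v - sy
                    elif d == 3:
                        ok = y < ny - 1
                        w = v + sy
                    elif d == 4:
                        ok = z > 0
                        w = v - 1
                    else:
                        ok = z < nz - 1
                        w = v + 1
                    if ok and parent[w] >= 0:
                        ra = find(parent, v)
                        rb = find(parent, w)
                        if ra != rb:
                            if size[ra] < size[rb]:
                                ra, rb = rb, ra
                            parent[rb] = ra
                            size[ra] += size[rb]
                ptr += 1
            inc = (h**H) * dh
            for k in range(ptr):
                v = order[k]
                out[v] += size[find(parent, v)] ** E * inc
        return out

    def _tfce_one_sided(vol: np.ndarray, H: float, E: float, n_steps: int) -> np.ndarray:
        nx, ny, nz = vol.shape
        flat = np.ascontiguousarray(vol, dtype=np.float64).ravel()
        return _tfce_kernel(flat, nx, ny, nz, float(H), float(E), int(n_steps)).reshape(vol.shape)

except ImportError:  # pragma: no cover
    _tfce_one_sided = _tfce_one_sided_reference


def tfce(
    t_map: np.ndarray,
    mask: np.ndarray | None = None,
    H: float = 2.0,
    E: float = 0.5,
    n_steps: int = 100,
) -> np.ndarray:
    """Threshold-free cluster enhancement, both tails, 6-connectivity.

    Accepts either a 3-D volume or a masked vector (then ``mask`` is
    required). Per voxel the statistic is ``sum_h e(h)^E h^H dh`` over a
    midpoint Riemann grid of ``n_steps`` thresholds from 0 to the map
    maximum, where ``e(h)`` is the extent of the voxel's suprathreshold
    component. The negative tail is enhanced identically on ``-t`` and
    returned with negative sign. NaNs are treated as zero (no support).
    """
    if H <= 0 or E <= 0:
        raise InvalidConfigError("TFCE H and E must be positive")
    t_map = np.asarray(t_map, dtype=float)
    vector_in = t_map.ndim == 1
    if vector_in:
        if mask is None:
            raise InvalidInputError("mask required for masked-vector input")
        vol = np.zeros(mask.shape)
        vol[mask] = np.nan_to_num(t_map)
    else:
        vol = np.nan_to_num(t_map)
    pos = _tfce_one_sided(np.clip(vol, 0, None), H, E, n_steps)
    neg = _tfce_one_sided(np.clip(-vol, 0, None), H, E, n_steps)
    enh = pos - neg
    if vector_in:
        return enh[mask]
    return enh


# ---------------------------------------------------------------------------
# Sign-flip permutation machinery


def _perm_tstats(z: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """t maps for a batch of sign-flip assignments, NaN-aware.

    z is (n_subjects, n_voxels); flips is (n_perm, n_subjects) of +-1.
    Sign flips leave per-voxel validity and sums of squares unchanged,
    so the whole batch reduces to one matmul.
    """
    valid = np.isfinite(z)
    zf = np.where(valid, z, 0.0)
    n_valid = valid.sum(axis=0).astype(float)
    sumsq = (zf**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (flips @ zf) / n_valid[None, :]
        var = (sumsq[None, :] - n_valid[None, :] * mean**2) / np.maximum(n_valid - 1, 1)[None, :]
        t = mean / np.sqrt(var / n_valid[None, :])
    return t


def _sign_flips(n_perm: int, n_sub: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice([-1.0, 1.0], size=(n_perm, n_sub))


@dataclass
class StatMap:
    """Group statistic volumes with provenance.

    All volumes are full-grid with NaN outside the valid in-mask voxels.
    """

    t_volume: np.ndarray
    tfce_volume: np.ndarray | None
    p_corrected: np.ndarray | None
    method: str
    n_subjects: int
    n_permutations: int
    seed: int | None
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.method not in ("tfce_permutation", "fdr_cluster", "cluster_extent_mc"):
            raise InvalidInputError(f"unknown method tag {self.method!r}")
        if self.p_corrected is not None:
            p = self.p_corrected[np.isfinite(self.p_corrected)]
            if p.size and ((p < 0).any() or (p > 1).any()):
                raise InvalidInputError("corrected p outside [0, 1]")

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        if self.p_corrected is None:
            raise InvalidInputError("no corrected p map attached")
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.p_corrected, nan=1.0) <= alpha


def permutation_correct(
    z: np.ndarray,
    mask: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    H: float = 2.0,
    E: float = 0.5,
    n_steps: int = 100,
    min_valid_frac: float = 0.8,
) -> StatMap:
    """TFCE + sign-flip max-statistic familywise correction.

    The null per permutation is the in-mask maximum of |TFCE| over both
    tails; ``p(v) = (1 + #{null >= |tfce(v)|}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise InvalidConfigError("n_perm must be >= 1")
    z = np.asarray(z, dtype=float)
    n_sub = z.shape[0]
    t, _ = group_ttest(z, min_valid_frac=min_valid_frac)
    valid = np.isfinite(t)
    obs_tfce = tfce(t, mask, H=H, E=E, n_steps=n_steps)
    obs_abs = np.abs(obs_tfce)

    rng = np.random.default_rng(seed)
    flips = _sign_flips(n_perm, n_sub, rng)
    t_null = _perm_tstats(z, flips)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        tp = np.where(valid, t_null[p], np.nan)
        enh = tfce(tp, mask, H=H, E=E, n_steps=n_steps)
        null_max[p] = np.max(np.abs(enh)) if enh.size else 0.0
    null_sorted = np.sort(null_max)
    # tiny tolerance so an identity flip reproducing the observed map counts
    # as >= despite float noise between the two t routes
    tol = 1e-9 * max(float(np.nanmax(obs_abs, initial=0.0)), 1.0)
    ge = n_perm - np.searchsorted(null_sorted, obs_abs - tol, side="left")
    p_vox = (1.0 + ge) / (n_perm + 1.0)
    p_vox = np.where(valid, p_vox, np.nan)

    mk = np.asarray(mask, dtype=bool)
    t_vol = np.full(mk.shape, np.nan)
    t_vol[mk] = t
    tf_vol = np.full(mk.shape, np.nan)
    tf_vol[mk] = np.where(valid, obs_tfce, np.nan)
    p_vol = np.full(mk.shape, np.nan)
    p_vol[mk] = p_vox
    return StatMap(
        t_volume=t_vol,
        tfce_volume=tf_vol,
        p_corrected=p_vol,
        method="tfce_permutation",
        n_subjects=n_sub,
        n_permutations=n_perm,
        seed=seed,
        mask=mk,
    )


# ---------------------------------------------------------------------------
# Cluster-based corrections


def _suprathreshold_clusters(
    t: np.ndarray, valid: np.ndarray, mask: np.ndarray, t_crit: float
) -> tuple[np.ndarray, list[dict]]:
    """Label two-tailed suprathreshold clusters; returns label volume + rows."""
    mk = np.asarray(mask, dtype=bool)
    t_vol = np.zeros(mk.shape)
    t_vol[mk] = np.where(valid, t, 0.0)
    label_vol = np.zeros(mk.shape, dtype=int)
    rows: list[dict] = []
    next_label = 1
    for sign in (1.0, -1.0):
        supra = sign * t_vol > t_crit
        labels, n = ndimage.label(supra, structure=_STRUCT6)
        for k in range(1, n + 1):
            sel = labels == k
            size = int(sel.sum())
            peak_flat = np.argmax(np.abs(t_vol) * sel)
            peak = np.unravel_index(peak_flat, mk.shape)
            rows.append(
                {
                    "label": next_label,
                    "sign": int(sign),
                    "size": size,
                    "peak_t": float(t_vol[peak]),
                    "peak_x": int(peak[0]),
                    "peak_y": int(peak[1]),
                    "peak_z": int(peak[2]),
                }
            )
            label_vol[sel] = next_label
            next_label += 1
    return label_vol, rows


def _max_cluster_null(
    z: np.ndarray, valid: np.ndarray, mask: np.ndarray, t_crit: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Sign-flip null of the maximum two-tailed cluster extent."""
    mk = np.asarray(mask, dtype=bool)
    flips = _sign_flips(n_perm, z.shape[0], rng)
    t_null = _perm_tstats(z, flips)
    out = np.empty(n_perm)
    for p in range(n_perm):
        t_vol = np.zeros(mk.shape)
        t_vol[mk] = np.where(valid, t_null[p], 0.0)
        best = 0
        for sign in (1.0, -1.0):
            labels, n = ndimage.label(sign * t_vol > t_crit, structure=_STRUCT6)
            if n:
                best = max(best, int(np.bincount(labels.ravel())[1:].max()))
        out[p] = best
    return out


def _height_tcrit(height_p: float, df: int) -> float:
    return float(stats.t.isf(height_p / 2.0, df))


def fdr_cluster_correct(
    z: np.ndarray,
    mask: np.ndarray,
    height_p: float = 0.001,
    q: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    min_valid_frac: float = 0.8,
) -> tuple[pd.DataFrame, StatMap]:
    """Cluster inference: fixed height threshold, permutation extent p, BH.

    Clusters are formed where two-tailed voxel p < ``height_p``; each
    cluster's p-value comes from the sign-flip null of the maximum
    cluster extent; Benjamini-Hochberg is applied across clusters at
    level ``q``.
    """
    z = np.asarray(z, dtype=float)
    n_sub = z.shape[0]
    t, _ = group_ttest(z, min_valid_frac=min_valid_frac)
    valid = np.isfinite(t)
    t_crit = _height_tcrit(height_p, n_sub - 1)
    label_vol, rows = _suprathreshold_clusters(t, valid, mask, t_crit)
    table = pd.DataFrame(rows, columns=["label", "sign", "size", "peak_t", "peak_x", "peak_y", "peak_z"])
    if len(table):
        rng = np.random.default_rng(seed)
        null = _max_cluster_null(z, valid, mask, t_crit, n_perm, rng)
        p_cluster = np.array(
            [(1.0 + np.sum(null >= s)) / (n_perm + 1.0) for s in table["size"]]
        )
        table["p_cluster"] = p_cluster
        table["p_fdr"] = _bh_adjust(p_cluster)
        table["significant"] = table["p_fdr"] <= q
    else:
        table["p_cluster"] = pd.Series(dtype=float)
        table["p_fdr"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)

    mk = np.asarray(mask, dtype=bool)
    t_vol = np.full(mk.shape, np.nan)
    t_vol[mk] = t
    p_vol = np.full(mk.shape, np.nan)
    p_vol[mk] = 1.0
    for _, row in table.iterrows():
        p_vol[label_vol == row["label"]] = row["p_fdr"]
    stat = StatMap(
        t_volume=t_vol,
        tfce_volume=None,
        p_corrected=p_vol,
        method="fdr_cluster",
        n_subjects=n_sub,
        n_permutations=n_perm,
        seed=seed,
        mask=mk,
    )
    return table, stat


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adj[idx] = running
    return adj


def cluster_extent_mc(
    z: np.ndarray,
    mask: np.ndarray,
    height_p: float = 0.001,
    n_sim: int = 1000,
    seed: int = 0,
    percentile: float = 95.0,
    min_valid_frac: float = 0.8,
) -> tuple[int, pd.DataFrame, StatMap]:
    """Monte-Carlo cluster-extent threshold at a fixed height threshold.

    The extent threshold is the ``percentile`` of the sign-flip null of
    the maximum cluster size; observed clusters at least that large
    survive.
    """
    z = np.asarray(z, dtype=float)
    n_sub = z.shape[0]
    t, _ = group_ttest(z, min_valid_frac=min_valid_frac)
    valid = np.isfinite(t)
    t_crit = _height_tcrit(height_p, n_sub - 1)
    rng = np.random.default_rng(seed)
    null = _max_cluster_null(z, valid, mask, t_crit, n_sim, rng)
    extent = int(np.quantile(null, percentile / 100.0, method="higher")) if n_sim > 1 else int(null[0])
    label_vol, rows = _suprathreshold_clusters(t, valid, mask, t_crit)
    table = pd.DataFrame(rows, columns=["label", "sign", "size", "peak_t", "peak_x", "peak_y", "peak_z"])
    table["significant"] = table["size"] >= max(extent, 1) if len(table) else pd.Series(dtype=bool)

    mk = np.asarray(mask, dtype=bool)
    t_vol = np.full(mk.shape, np.nan)
    t_vol[mk] = t
    p_vol = np.full(mk.shape, np.nan)
    p_vol[mk] = 1.0
    for _, row in table.iterrows():
        if row["significant"]:
            p_vol[label_vol == row["label"]] = 0.0
    stat = StatMap(
        t_volume=t_vol,
        tfce_volume=None,
        p_corrected=p_vol,
        method="cluster_extent_mc",
        n_subjects=n_sub,
        n_permutations=n_sim,
        seed=seed,
        mask=mk,
    )
    return extent, table, stat
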