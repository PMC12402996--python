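"""Synthetic rating tables, feature matrices, and beta-volume cohorts.

Everything downstream is validated against cohorts generated here: the
generator plants known linear structure (synergy-driven patterns, a
visual-feature region, a centrality-modulated region) inside disjoint
regions of a shared brain mask, so parameter recovery is testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from synkin.cohort import BetaCohort, DimensionMismatchError, default_affine, ellipsoid_mask
from synkin.config import InvalidConfigError, SynthConfig
from synkin.space import ObjectSet, RatingMatrix, aggregate_ratings

# independent substreams per generator, derived from cfg.seed
_STREAM_RATINGS = 11
_STREAM_OBJECTS = 23
_STREAM_FEATURES = 37
_STREAM_COHORT = 53


def _rng(cfg_seed: int, stream: int, seed: int | None = None) -> np.random.Generator:
    base = cfg_seed if seed is None else seed
    return np.random.default_rng([int(base), stream])


@dataclass
class GroundTruth:
    """Planted generative structure of one synthetic cohort.

    region_masks maps "kinematic"/"visual"/"centrality"/"buffer"/"null" to
    boolean volumes; all regions are pairwise disjoint, inside the brain
    mask, and together partition it. "buffer" is the pure-noise guard
    ring around planted regions (within smoothing reach of real signal);
    "null" is pure noise beyond it. synergy_patterns are zero outside the
    kinematic region.
    """

    region_masks: dict[str, np.ndarray]
    synergy_patterns: np.ndarray  # (n_synergies, x, y, z)
    visual_weights: np.ndarray  # (n_features, n_visual_voxels)
    centrality_scores: np.ndarray  # z-scored, per object
    familiarity_scores: np.ndarray  # z-scored, per object (not planted)
    effect_scale: float
    noise_sd: float

    def region_voxel_indices(self, name: str, mask: np.ndarray) -> np.ndarray:
        """Indices of a region's voxels within the masked voxel axis."""
        flat_region = self.region_masks[name][mask]
        return np.flatnonzero(flat_region)

    def expected_centrality_r(self) -> float:
        """Generative voxelwise r between beta and centrality score.

        In the centrality region beta = effect_scale * c_z + noise, so the
        population correlation is a / sqrt(a^2 + noise_sd^2).
        """
        a = self.effect_scale
        return a / np.sqrt(a**2 + self.noise_sd**2) if a > 0 else 0.0


def _synergy_cluster_prefs(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Latent object clusters and each synergy's preferred cluster."""
    obj_cluster = np.arange(cfg.n_objects) % cfg.n_rating_clusters
    syn_pref = np.arange(cfg.n_synergies) % cfg.n_rating_clusters
    return obj_cluster, syn_pref


def generate_ratings(
    cfg: SynthConfig,
    seed: int | None = None,
    n_objects: int | None = None,
) -> tuple[np.ndarray, RatingMatrix]:
    """Draw per-rater binary votes and their group-average RatingMatrix.

    Each (synergy, object) vote probability is an independent uniform
    draw tilted toward the synergy's preferred latent cluster by
    ``cfg.cluster_strength``; the mix keeps per-object loading profiles
    distinctive (strongly block-structured ratings make leave-one-out
    predictions within a cluster nearly identical, which induces a
    spurious anticorrelation with held-out noise). For each synergy two
    objects of the preferred cluster and two others are re-sampled (up
    to 1000 attempts) until their group loading clears 0.75 / 0.25, so
    high and low sets stay non-empty even with any single object held
    out.

    Returns
    -------
    votes : ndarray of uint8, (n_synergies, n_objects, n_raters)
    ratings : RatingMatrix
    """
    if cfg.n_raters < 1:
        raise InvalidConfigError("n_raters must be >= 1")
    n_obj = cfg.n_objects if n_objects is None else int(n_objects)
    rng = _rng(cfg.seed, _STREAM_RATINGS, seed)
    obj_cluster = np.arange(n_obj) % cfg.n_rating_clusters
    _, syn_pref = _synergy_cluster_prefs(cfg)

    # mid-concentrated base probabilities: extreme loadings come mostly from
    # the forced pairs below, which keeps leave-one-out fold weights
    # idiosyncratic across objects (strong block structure would make
    # predictions within a cluster near-identical and anticorrelated with
    # held-out noise)
    base = rng.beta(2.0, 2.0, size=(cfg.n_synergies, n_obj))
    tilt = np.where(obj_cluster[None, :] == syn_pref[:, None], 0.5, -0.5) * cfg.cluster_strength
    p = np.clip(base + tilt, 0.02, 0.98)
    votes = (rng.random((cfg.n_synergies, n_obj, cfg.n_raters)) < p[:, :, None]).astype(np.uint8)

    # forced separation: >=2 loadings above 0.75 and >=2 below 0.25 per synergy
    for s in range(cfg.n_synergies):
        pref = syn_pref[s]
        in_pref = np.flatnonzero(obj_cluster == pref)
        out_pref = np.flatnonzero(obj_cluster != pref)
        if len(out_pref) == 0:  # single-cluster config: split arbitrarily
            out_pref = in_pref[len(in_pref) // 2:]
            in_pref = in_pref[: len(in_pref) // 2]
        # rotate the forced objects so no object becomes extreme everywhere
        for o in rng.choice(in_pref, size=min(2, len(in_pref)), replace=False):
            _force_loading(votes[s, o], rng, low=False)
        for o in rng.choice(out_pref, size=min(2, len(out_pref)), replace=False):
            _force_loading(votes[s, o], rng, low=True)

    synergy_ids = [f"syn{s:02d}" for s in range(cfg.n_synergies)]
    object_ids = [f"obj{o:02d}" for o in range(n_obj)]
    ratings = aggregate_ratings(votes, synergy_ids, object_ids)
    return votes, ratings


def _force_loading(col: np.ndarray, rng: np.random.Generator, low: bool, max_attempts: int = 1000) -> None:
    """Resample one object's rater votes until its loading clears threshold."""
    p = 0.1 if low else 0.9
    for _ in range(max_attempts):
        m = col.mean()
        if (low and m < 0.25) or (not low and m > 0.75):
            return
        col[:] = (rng.random(col.shape) < p).astype(np.uint8)
    raise RuntimeError("failed to force loading separation within attempt cap")


def generate_object_set(
    cfg: SynthConfig,
    n_objects: int | None = None,
    seed: int | None = None,
) -> ObjectSet:
    """Centrality and familiarity scores drawn uniform on the 1-5 scale."""
    n_obj = cfg.n_objects if n_objects is None else int(n_objects)
    rng = _rng(cfg.seed, _STREAM_OBJECTS, seed)
    centrality = rng.uniform(1.0, 5.0, n_obj)
    familiarity = rng.uniform(1.0, 5.0, n_obj)
    return ObjectSet(
        object_ids=[f"obj{o:02d}" for o in range(n_obj)],
        centrality=centrality,
        familiarity=familiarity,
    )


def generate_visual_features(
    cfg: SynthConfig,
    ratings: RatingMatrix | None = None,
    seed: int | None = None,
    rsm_correlation: float = 0.0,
    decorrelation_tol: float = 0.1,
    max_attempts: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Objects x features matrix standing in for image-model activations.

    With ``rsm_correlation=0`` (default) features are redrawn until the
    off-diagonal correlation between the visual RSM and the kinematic RSM
    (from ``ratings``) is below ``decorrelation_tol``. A nonzero target
    blends the kinematic similarity structure into the feature Gram
    matrix (approximate, monotone in the target).

    Returns
    -------
    features : ndarray, (n_objects, n_features)
    rsm : ndarray, (n_objects, n_objects) Pearson similarity of rows
    """
    rng = _rng(cfg.seed, _STREAM_FEATURES, seed)
    n_obj = ratings.n_objects if ratings is not None else cfg.n_objects
    nf = cfg.n_visual_features

    kin_off = None
    if ratings is not None and (ratings.loadings.std(axis=0) > 0).all():
        with np.errstate(invalid="ignore", divide="ignore"):
            kin_rsm = np.corrcoef(ratings.loadings, rowvar=False)
        i, j = np.tril_indices(n_obj, k=-1)
        kin_off = kin_rsm[i, j]

    if rsm_correlation != 0.0 and kin_off is not None:
        w = float(np.clip(rsm_correlation, 0.0, 1.0))
        base = rng.standard_normal((n_obj, nf))
        rand_rsm = np.corrcoef(base)
        target = w * kin_rsm + (1.0 - w) * rand_rsm
        evals, evecs = np.linalg.eigh(target)
        evals = np.clip(evals, 0.0, None)
        features = evecs @ np.diag(np.sqrt(evals))
        rsm = np.corrcoef(features)
        return features, rsm

    for _ in range(max_attempts):
        features = rng.standard_normal((n_obj, nf))
        rsm = np.corrcoef(features)
        if kin_off is None:
            return features, rsm
        i, j = np.tril_indices(n_obj, k=-1)
        r = np.corrcoef(rsm[i, j], kin_off)[0, 1]
        if abs(r) < decorrelation_tol:
            return features, rsm
    raise RuntimeError("could not decorrelate visual features from kinematic RSM")


def _place_regions(cfg: SynthConfig, mask: np.ndarray) -> dict[str, np.ndarray]:
    """Carve disjoint near-spherical regions out of the brain mask.

    Regions are grown as the nearest unassigned in-mask voxels around
    well-separated anchor points (deterministic).
    """
    n_in = int(mask.sum())
    coords = np.argwhere(mask).astype(float)
    center = (np.asarray(mask.shape) - 1) / 2.0
    radii = (np.asarray(mask.shape) - 2) / 2.0
    anchors = {
        "kinematic": center + radii * np.array([0.45, 0.45, 0.0]),
        "visual": center + radii * np.array([-0.45, -0.45, 0.0]),
        "centrality": center + radii * np.array([-0.45, 0.45, 0.0]),
    }
    taken = np.zeros(n_in, dtype=bool)
    masks: dict[str, np.ndarray] = {}
    for name, frac in cfg.region_fractions.items():
        n_req = int(round(frac * n_in))
        anchor = anchors.get(name)
        if anchor is None:  # extra user-defined region: park at remaining corner
            anchor = center + radii * np.array([0.45, -0.45, 0.0])
        d = np.linalg.norm(coords - anchor[None, :], axis=1)
        d[taken] = np.inf
        order = np.argsort(d, kind="stable")[:n_req]
        sel = np.zeros(n_in, dtype=bool)
        sel[order] = True
        taken |= sel
        vol = np.zeros(mask.shape, dtype=bool)
        vol[mask] = sel
        masks[name] = vol
    # guard ring of pure-noise voxels around planted regions: at the default
    # smoothing level real signal bleeds a couple of voxels past region
    # borders, so "null" is reserved for voxels the smoothing kernel cannot
    # reach from any planted region
    planted = np.zeros(mask.shape, dtype=bool)
    for m in masks.values():
        planted |= m
    if cfg.buffer_vox > 0:
        ring = binary_dilation(planted, iterations=cfg.buffer_vox) & mask & ~planted
    else:
        ring = np.zeros(mask.shape, dtype=bool)
    masks["buffer"] = ring
    null_vol = np.zeros(mask.shape, dtype=bool)
    null_vol[mask] = ~taken
    null_vol &= ~ring
    masks["null"] = null_vol
    return masks


def _synergy_patterns(
    cfg: SynthConfig, kin_mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Smoothed Gaussian random fields, mean-centered across synergies.

    Each pattern is restricted to the kinematic region and scaled to unit
    SD over the region's voxels; centering across synergies guarantees
    high-vs-low contrasts are informative.
    """
    fields = rng.standard_normal((cfg.n_synergies,) + tuple(cfg.grid_shape))
    for s in range(cfg.n_synergies):
        fields[s] = gaussian_filter(fields[s], sigma=1.2)
    fields -= fields.mean(axis=0, keepdims=True)
    patterns = np.zeros_like(fields)
    region = kin_mask
    for s in range(cfg.n_synergies):
        vals = fields[s][region]
        sd = vals.std()
        patterns[s][region] = vals / sd if sd > 0 else vals
    return patterns


def generate_cohort(
    cfg: SynthConfig,
    ratings: RatingMatrix,
    visual_features: np.ndarray | None = None,
    object_set: ObjectSet | None = None,
    seed: int | None = None,
) -> tuple[BetaCohort, GroundTruth]:
    """Simulate per-subject, per-object beta volumes with planted signal.

    Noiseless signal per object o at voxel v:

    - kinematic region: ``effect_scale * sum_i pattern_i(v) * loading(i, o)``
    - visual region:    ``effect_scale * features(o) . W(v)``
    - centrality region: ``effect_scale * centrality_z(o)``
    - null region: zero.

    Each subject's signal is scaled by ``1 +- subject_jitter`` and buried
    in independent Gaussian noise of SD ``noise_sd``. Same (cfg, seed)
    gives bit-identical output.
    """
    if ratings.n_objects != cfg.n_objects:
        raise DimensionMismatchError(
            f"ratings have {ratings.n_objects} objects but cfg.n_objects={cfg.n_objects}"
        )
    rng = _rng(cfg.seed, _STREAM_COHORT, seed)
    mask = ellipsoid_mask(cfg.grid_shape)
    region_masks = _place_regions(cfg, mask)

    if visual_features is None:
        visual_features, _ = generate_visual_features(cfg, ratings, seed=seed)
    visual_features = np.asarray(visual_features, dtype=float)
    if visual_features.shape[0] != cfg.n_objects:
        raise DimensionMismatchError(
            f"visual features have {visual_features.shape[0]} rows, expected {cfg.n_objects}"
        )

    if object_set is not None:
        if len(object_set.object_ids) != cfg.n_objects:
            raise DimensionMismatchError("object_set size does not match cfg.n_objects")
        centrality_raw = object_set.centrality
        familiarity_raw = object_set.familiarity
    else:
        centrality_raw = rng.uniform(1.0, 5.0, cfg.n_objects)
        familiarity_raw = rng.uniform(1.0, 5.0, cfg.n_objects)
    c_z = _zscore(centrality_raw)
    # familiarity is planted as NOT modulating any region; residualize it
    # against centrality so chance correlation at small n cannot leak the
    # centrality signal into familiarity maps
    f_res = familiarity_raw - np.polyval(np.polyfit(c_z, familiarity_raw, 1), c_z)
    f_z = _zscore(f_res)

    patterns = _synergy_patterns(cfg, region_masks["kinematic"], rng)

    n_vox = int(mask.sum())
    base = np.zeros((cfg.n_objects, n_vox))

    kin_idx = np.flatnonzero(region_masks["kinematic"][mask])
    if kin_idx.size:
        pat_flat = patterns[:, region_masks["kinematic"]]  # (n_syn, n_kin_vox)
        base[:, kin_idx] = cfg.effect_scale * (ratings.loadings.T @ pat_flat)

    vis_idx = np.flatnonzero(region_masks["visual"][mask])
    n_feat = visual_features.shape[1]
    visual_weights = rng.standard_normal((n_feat, vis_idx.size)) / np.sqrt(n_feat)
    if vis_idx.size:
        base[:, vis_idx] = cfg.effect_scale * (visual_features @ visual_weights)

    cen_idx = np.flatnonzero(region_masks["centrality"][mask])
    if cen_idx.size:
        base[:, cen_idx] = cfg.effect_scale * c_z[:, None]

    jitter = 1.0 + cfg.subject_jitter * rng.uniform(-1.0, 1.0, cfg.n_subjects)
    data = np.empty((cfg.n_subjects, cfg.n_objects, n_vox))
    norm = _smooth_noise_norm(cfg.noise_smooth_vox, cfg.grid_shape)
    for s in range(cfg.n_subjects):
        noise = _smooth_noise(cfg, rng, norm, mask)
        data[s] = jitter[s] * base + noise

    cohort = BetaCohort(
        data=data,
        mask=mask,
        affine=default_affine(cfg.voxel_size_mm),
        subject_ids=[f"sub{s:02d}" for s in range(cfg.n_subjects)],
        object_ids=list(ratings.object_ids),
        voxel_size_mm=cfg.voxel_size_mm,
    )
    truth = GroundTruth(
        region_masks=region_masks,
        synergy_patterns=patterns,
        visual_weights=visual_weights,
        centrality_scores=c_z,
        familiarity_scores=f_z,
        effect_scale=cfg.effect_scale,
        noise_sd=cfg.noise_sd,
    )
    return cohort, truth


def _smooth_noise_norm(sigma: float, grid_shape: tuple[int, int, int]) -> float:
    """SD shrinkage factor of Gaussian-filtered white noise (interior voxels)."""
    if sigma == 0:
        return 1.0
    delta = np.zeros(grid_shape)
    delta[tuple(g // 2 for g in grid_shape)] = 1.0
    kernel = gaussian_filter(delta, sigma=sigma)
    return float(np.sqrt((kernel**2).sum()))


def _smooth_noise(
    cfg: SynthConfig, rng: np.random.Generator, norm: float, mask: np.ndarray
) -> np.ndarray:
    """Spatially smooth Gaussian noise with per-voxel SD ``noise_sd``.

    Real response estimates carry spatially correlated noise; generating
    white noise instead would let group-level smoothing shrink the
    between-subject error far below anything realistic.
    """
    white = rng.standard_normal((cfg.n_objects,) + tuple(cfg.grid_shape))
    if cfg.noise_smooth_vox == 0:
        return cfg.noise_sd * white[:, mask]
    out = np.empty((cfg.n_objects, int(mask.sum())))
    for o in range(cfg.n_objects):
        out[o] = gaussian_filter(white[o], sigma=cfg.noise_smooth_vox)[mask] / norm
    return cfg.noise_sd * out


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()
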