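"""Leave-one-object-out synergy encoding model and its univariate scoring.

For each fold (left-out object t) and each synergy, a whole-brain
contrast map is built from objects rated high (> 0.75) versus low
(< 0.25) on that synergy, excluding t throughout. The held-out object's
activity is then predicted voxelwise as the ratings-weighted linear sum
of those maps, and predictions are scored per voxel by correlating
predicted with observed values across objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from synkin.cohort import BetaCohort
from synkin.space import InvalidInputError, RatingMatrix

HIGH_THRESHOLD = 0.75
LOW_THRESHOLD = 0.25
FISHER_CLIP = 1.0 - 1e-7


class EmptyModelError(ValueError):
    """Every synergy map for a fold is absent; no prediction possible."""


def high_low_sets(
    ratings: RatingMatrix,
    synergy_id: str,
    left_out: str,
    high_threshold: float = HIGH_THRESHOLD,
    low_threshold: float = LOW_THRESHOLD,
) -> tuple[list[str], list[str]]:
    """Objects rated strictly above/below threshold, never including t."""
    s = ratings.synergy_ids.index(synergy_id)
    high, low = [], []
    for j, obj in enumerate(ratings.object_ids):
        if obj == left_out:
            continue
        v = ratings.loadings[s, j]
        if v > high_threshold:
            high.append(obj)
        elif v < low_threshold:
            low.append(obj)
    return high, low


def build_synergy_map(
    volumes: np.ndarray,
    ratings: RatingMatrix,
    synergy_id: str,
    left_out: str,
    method: str = "mean",
) -> np.ndarray | None:
    """One synergy's contrast map for one subject, with t held out.

    ``method="pairwise"`` subtracts each low object's volume from each
    high object's volume and averages the resulting difference maps —
    the procedure stated literally. ``method="mean"`` computes the
    algebraically identical ``mean(high) - mean(low)``. Returns None
    (absent map) when either set is empty.

    Parameters
    ----------
    volumes : ndarray, (n_objects, n_voxels)
        One subject's beta matrix, rows ordered as ``ratings.object_ids``.
    """
    high, low = high_low_sets(ratings, synergy_id, left_out)
    if not high or not low:
        return None
    hi = [ratings.object_ids.index(o) for o in high]
    lo = [ratings.object_ids.index(o) for o in low]
    if method == "pairwise":
        acc = np.zeros(volumes.shape[1])
        for h in hi:
            for l in lo:
                acc += volumes[h] - volumes[l]
        return acc / (len(hi) * len(lo))
    if method == "mean":
        return volumes[hi].mean(axis=0) - volumes[lo].mean(axis=0)
    raise InvalidInputError(f"unknown method {method!r}")


@dataclass
class SynergyMapSet:
    """All synergy maps for one fold, with the high/low provenance lists."""

    fold_id: str
    maps: dict[str, np.ndarray | None]
    provenance: dict[str, tuple[list[str], list[str]]]

    def __post_init__(self) -> None:
        for sid, (high, low) in self.provenance.items():
            if self.fold_id in high or self.fold_id in low:
                raise InvalidInputError(
                    f"left-out object {self.fold_id} appears in synergy {sid} sets"
                )
            absent = self.maps.get(sid) is None
            if absent != (not high or not low):
                raise InvalidInputError(
                    f"synergy {sid}: absence must coincide with an empty high/low set"
                )

    @property
    def skipped(self) -> list[str]:
        return [sid for sid, m in self.maps.items() if m is None]


def build_fold_maps(
    volumes: np.ndarray, ratings: RatingMatrix, left_out: str, method: str = "mean"
) -> SynergyMapSet:
    maps: dict[str, np.ndarray | None] = {}
    prov: dict[str, tuple[list[str], list[str]]] = {}
    for sid in ratings.synergy_ids:
        prov[sid] = high_low_sets(ratings, sid, left_out)
        maps[sid] = build_synergy_map(volumes, ratings, sid, left_out, method=method)
    return SynergyMapSet(left_out, maps, prov)


def predict_object(maps: SynergyMapSet, weights: np.ndarray, synergy_ids: list[str]) -> np.ndarray:
    """Weighted linear sum of synergy maps; absent maps contribute zero.

    ``weights[i]`` is the rating of ``synergy_ids[i]`` for the held-out
    object. Weights are applied exactly as given (no renormalization).
    """
    if len(weights) != len(synergy_ids):
        raise InvalidInputError("weights must align with synergy_ids")
    present = [sid for sid in synergy_ids if maps.maps.get(sid) is not None]
    if not present:
        raise EmptyModelError(f"all synergy maps absent for fold {maps.fold_id}")
    y = None
    for w, sid in zip(weights, synergy_ids):
        m = maps.maps.get(sid)
        if m is None:
            continue
        y = w * m if y is None else y + w * m
    return y


@dataclass
class PredictionResult:
    """Leave-one-out predictions for every (subject, object)."""

    predicted: np.ndarray  # (n_subjects, n_objects, n_voxels)
    subject_ids: list[str]
    object_ids: list[str]
    skipped_synergies: dict[str, list[str]] = field(default_factory=dict)  # fold -> synergies
    invalid_folds: list[str] = field(default_factory=list)

    @property
    def n_invalid(self) -> int:
        return len(self.invalid_folds)


def _fold_object_weights(
    ratings: RatingMatrix, left_out: str, normalize_weights: bool
) -> tuple[np.ndarray, list[str], bool]:
    """Collapse fold t's two model steps into one object-weight vector.

    The prediction ``y = sum_i k_i * (mean(high_i) - mean(low_i))`` is
    linear in the object volumes, so per fold it reduces to a single
    weight per training object — the fast path used by
    :func:`run_encoding_model`. Tests verify equality with the explicit
    map-then-sum route.
    """
    n_obj = ratings.n_objects
    t_idx = ratings.object_ids.index(left_out)
    k = ratings.loadings[:, t_idx].copy()
    contrib = np.zeros((ratings.n_synergies, n_obj))
    skipped = []
    for s, sid in enumerate(ratings.synergy_ids):
        high, low = high_low_sets(ratings, sid, left_out)
        if not high or not low:
            skipped.append(sid)
            continue
        hi = [ratings.object_ids.index(o) for o in high]
        lo = [ratings.object_ids.index(o) for o in low]
        contrib[s, hi] = 1.0 / len(hi)
        contrib[s, lo] = -1.0 / len(lo)
    active = np.flatnonzero(contrib.any(axis=1))
    empty_model = active.size == 0
    if normalize_weights and not empty_model:
        total = k[active].sum()
        if total > 0:
            k = k / total
    w = k @ contrib
    w[t_idx] = 0.0  # structurally zero already; assert the exclusion contract
    return w, skipped, empty_model


def run_encoding_model(
    cohort: BetaCohort, ratings: RatingMatrix, normalize_weights: bool = False
) -> PredictionResult:
    """Run all leave-one-out folds for every subject.

    Folds whose every synergy map is absent are recorded as invalid
    (prediction all-zero) and the run continues.
    """
    if list(cohort.object_ids) != list(ratings.object_ids):
        raise InvalidInputError("cohort and ratings must list the same objects in order")
    if cohort.n_objects < 3:
        raise InvalidInputError("need >= 3 objects for leave-one-out contrasts")

    n_obj = cohort.n_objects
    fold_w = np.zeros((n_obj, n_obj))  # rows: fold t; cols: training-object weights
    skipped: dict[str, list[str]] = {}
    invalid: list[str] = []
    for t, obj in enumerate(cohort.object_ids):
        w, sk, empty = _fold_object_weights(ratings, obj, normalize_weights)
        fold_w[t] = w
        if sk:
            skipped[obj] = sk
        if empty:
            invalid.append(obj)

    # predicted[s, t, v] = sum_o fold_w[t, o] * data[s, o, v]
    predicted = np.einsum("to,sov->stv", fold_w, cohort.data)
    return PredictionResult(
        predicted=predicted,
        subject_ids=list(cohort.subject_ids),
        object_ids=list(cohort.object_ids),
        skipped_synergies=skipped,
        invalid_folds=invalid,
    )


@dataclass
class ScoreMap:
    """Per-subject voxelwise prediction accuracy (r across objects)."""

    r: np.ndarray  # (n_subjects, n_voxels), NaN where invalid
    z: np.ndarray  # Fisher z of clipped r
    valid: np.ndarray  # boolean (n_subjects, n_voxels)
    subject_ids: list[str]

    def __post_init__(self) -> None:
        ok = self.r[self.valid]
        if ok.size and (np.abs(ok) > 1 + 1e-12).any():
            raise InvalidInputError("r out of [-1, 1]")
        if not np.isfinite(self.z[self.valid]).all():
            raise InvalidInputError("Fisher z must be finite at valid voxels")


def univariate_rsa_score(cohort: BetaCohort, preds: PredictionResult) -> ScoreMap:
    """Correlate predicted with observed activity across objects, per voxel.

    Voxels where either vector has zero variance across objects — and all
    voxels of subjects with fewer than 3 valid folds — are flagged
    invalid (NaN), never silently zeroed.
    """
    if list(preds.object_ids) != list(cohort.object_ids):
        raise InvalidInputError("prediction and cohort object sets differ")
    obs = cohort.data
    pred = preds.predicted
    oc = obs - obs.mean(axis=1, keepdims=True)
    pc = pred - pred.mean(axis=1, keepdims=True)
    o_ss = np.einsum("sov,sov->sv", oc, oc)
    p_ss = np.einsum("sov,sov->sv", pc, pc)
    cov = np.einsum("sov,sov->sv", oc, pc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(o_ss * p_ss)
    valid = (o_ss > 0) & (p_ss > 0)
    n_valid_folds = cohort.n_objects - len(preds.invalid_folds)
    if n_valid_folds < 3:
        valid[:] = False
    r = np.where(valid, np.clip(r, -1.0, 1.0), np.nan)
    z = np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
    return ScoreMap(r=r, z=z, valid=valid, subject_ids=list(cohort.subject_ids))
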