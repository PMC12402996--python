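"""ROI-level model comparison: performance contrasts and permutation ANOVA.

Model score maps (voxelwise r for each candidate model) are squared and
averaged within ROIs, contrasted pairwise as (M1 - M2)/(M1 + M2), tested
per ROI with Bonferroni-adjusted one-sample t tests, and jointly with a
permutation test of the ROI x Model interaction in a repeated-measures
two-factor decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from synkin.space import InvalidInputError, SimilarityMatrix


class UndefinedContrastError(ValueError):
    """Both model scores are zero; the contrast is undefined."""


@dataclass
class ROISet:
    """Labeled boolean masks on the shared grid."""

    masks: dict[str, np.ndarray]
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        bm = np.asarray(self.brain_mask, dtype=bool)
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != bm.shape:
                raise InvalidInputError(f"ROI {name!r} not on the shared grid")
            if not m.any():
                raise InvalidInputError(f"ROI {name!r} is empty")
            if (m & ~bm).any():
                raise InvalidInputError(f"ROI {name!r} extends outside the brain mask")
            self.masks[name] = m
        self.brain_mask = bm

    @property
    def labels(self) -> list[str]:
        return list(self.masks.keys())

    def voxel_indices(self, label: str) -> np.ndarray:
        """Indices into the masked voxel axis."""
        return np.flatnonzero(self.masks[label][self.brain_mask])


@dataclass
class ModelScores:
    """Mean r^2 per subject x model x ROI (NaN = missing)."""

    values: np.ndarray  # (n_subjects, n_models, n_rois)
    subject_ids: list[str]
    model_names: list[str]
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.subject_ids), len(self.model_names), len(self.roi_labels))
        if self.values.shape != expected:
            raise InvalidInputError(f"scores shape {self.values.shape} != {expected}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and ((finite < 0).any() or (finite > 1 + 1e-9).any()):
            raise InvalidInputError("r^2 scores must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for si, s in enumerate(self.subject_ids):
            for mi, m in enumerate(self.model_names):
                for ri, r in enumerate(self.roi_labels):
                    recs.append({"subject": s, "model": m, "roi": r, "r2": self.values[si, mi, ri]})
        return pd.DataFrame(recs)


def roi_scores(
    score_maps: dict[str, np.ndarray],
    rois: ROISet,
    subject_ids: list[str] | None = None,
) -> ModelScores:
    """Average each model's squared voxel score within each ROI.

    ``score_maps[model]`` is (n_subjects, n_voxels) of r values on the
    masked voxel axis (NaN = invalid voxel). An ROI with no valid voxels
    for a subject yields a missing entry and a warning.
    """
    models = list(score_maps.keys())
    n_sub = next(iter(score_maps.values())).shape[0]
    ids = subject_ids or [f"sub{s:02d}" for s in range(n_sub)]
    out = np.full((n_sub, len(models), len(rois.labels)), np.nan)
    for mi, model in enumerate(models):
        maps = np.asarray(score_maps[model], dtype=float)
        if maps.shape[0] != n_sub:
            raise InvalidInputError("score maps disagree on subject count")
        for ri, label in enumerate(rois.labels):
            idx = rois.voxel_indices(label)
            vals = maps[:, idx] ** 2
            n_valid = np.isfinite(vals).sum(axis=1)
            if (n_valid == 0).any():
                warnings.warn(f"ROI {label!r} has no valid voxels for some subjects", stacklevel=2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[:, mi, ri] = np.nanmean(vals, axis=1)
    return ModelScores(np.clip(out, 0.0, 1.0), ids, models, rois.labels)


def performance_contrast(m1, m2):
    """(M1 - M2) / (M1 + M2), in [-1, 1]; antisymmetric in its arguments."""
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if (m1 < 0).any() or (m2 < 0).any():
        raise InvalidInputError("scores must be nonnegative")
    denom = m1 + m2
    if np.isscalar(denom) or denom.ndim == 0:
        if denom == 0:
            raise UndefinedContrastError("both scores are zero")
        return float((m1 - m2) / denom)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (m1 - m2) / denom, np.nan)
    return out


def contrast_tests(
    scores: ModelScores, model_1: str, model_2: str
) -> pd.DataFrame:
    """Per-ROI one-sample t of the performance contrast, Bonferroni-adjusted.

    Returns one row per ROI: mean contrast, t, df, raw and adjusted p,
    and Cohen's d over subjects.
    """
    i1 = scores.model_names.index(model_1)
    i2 = scores.model_names.index(model_2)
    rows = []
    n_rois = len(scores.roi_labels)
    for ri, label in enumerate(scores.roi_labels):
        c = performance_contrast(scores.values[:, i1, ri], scores.values[:, i2, ri])
        c = c[np.isfinite(c)]
        if len(c) < 2:
            rows.append({"roi": label, "n": len(c), "mean_contrast": np.nan, "t": np.nan,
                         "df": np.nan, "p": np.nan, "p_bonferroni": np.nan, "cohens_d": np.nan})
            continue
        t, p = stats.ttest_1samp(c, 0.0)
        d = c.mean() / c.std(ddof=1) if c.std(ddof=1) > 0 else np.inf * np.sign(c.mean())
        rows.append(
            {
                "roi": label,
                "n": len(c),
                "mean_contrast": float(c.mean()),
                "t": float(t),
                "df": len(c) - 1,
                "p": float(p),
                "p_bonferroni": float(min(1.0, p * n_rois)),
                "cohens_d": float(d),
            }
        )
    return pd.DataFrame(rows)


def _interaction_f(y: np.ndarray) -> float:
    """ROI x Model interaction F from a repeated-measures decomposition.

    y is (subjects, models, rois), complete. The error term is the
    subject x model x roi residual, df = (p-1)(q-1)(n-1).
    """
    n, p, q = y.shape
    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    model = y.mean(axis=(0, 2))
    roi = y.mean(axis=(0, 1))
    cell = y.mean(axis=0)  # (p, q)
    sm = y.mean(axis=2)  # (n, p)
    sr = y.mean(axis=1)  # (n, q)

    ss_int = n * np.sum((cell - model[:, None] - roi[None, :] + grand) ** 2)
    resid = (
        y
        - sm[:, :, None]
        - sr[:, None, :]
        - cell[None, :, :]
        + subj[:, None, None]
        + model[None, :, None]
        + roi[None, None, :]
        - grand
    )
    ss_err = np.sum(resid**2)
    df_int = (p - 1) * (q - 1)
    df_err = (p - 1) * (q - 1) * (n - 1)
    if ss_err <= 0 or df_err <= 0:
        return 0.0 if ss_int <= 1e-24 else np.inf
    return float((ss_int / df_int) / (ss_err / df_err))


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_interaction: int
    df_error: int
    null: np.ndarray


def permutation_anova(scores: ModelScores, n_perm: int = 1000, seed: int = 0) -> AnovaResult:
    """Permutation test of the ROI x Model interaction.

    Model labels are shuffled within subject (whole model slabs, ROIs
    kept fixed), preserving subject and ROI marginals. Subjects with any
    missing entry are dropped listwise.
    """
    y = scores.values
    keep = np.isfinite(y).all(axis=(1, 2))
    y = y[keep]
    if y.shape[0] < 2:
        raise InvalidInputError("need >= 2 complete subjects for the ANOVA")
    n, p, q = y.shape
    f_obs = _interaction_f(y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        yp = np.empty_like(y)
        for s in range(n):
            yp[s] = y[s, rng.permutation(p), :]
        null[k] = _interaction_f(yp)
    p_value = (1.0 + float(np.sum(null >= f_obs))) / (n_perm + 1.0)
    return AnovaResult(
        f_statistic=f_obs,
        p_value=p_value,
        df_interaction=(p - 1) * (q - 1),
        df_error=(p - 1) * (q - 1) * (n - 1),
        null=null,
    )


def visual_model_rsm(
    features: np.ndarray | SimilarityMatrix,
    object_ids: list[str] | None = None,
) -> SimilarityMatrix:
    """Object similarity from a feature matrix (or pass an RDM through).

    A (objects x features) array yields the pairwise Pearson similarity
    of its rows. A SimilarityMatrix input is converted to similarity mode
    unchanged — behavioral RDMs pass straight through.
    """
    if isinstance(features, SimilarityMatrix):
        return features.to_rsm()
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise InvalidInputError("features must be (>=2 objects, features)")
    sd = features.std(axis=1)
    if (sd == 0).any():
        raise InvalidInputError("zero-variance feature rows cannot be correlated")
    ids = object_ids or [f"obj{i:03d}" for i in range(features.shape[0])]
    r = np.corrcoef(features)
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix(r, "similarity", ids)
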