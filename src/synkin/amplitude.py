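"""Voxelwise correlation between response amplitude and behavioral scores.

Per subject, correlates each voxel's betas with a per-object score
vector (centrality of manipulation, familiarity) across objects. The
resulting r maps feed the same group-inference stages as the encoding
model scores.
"""

from __future__ import annotations

import numpy as np

from synkin.cohort import BetaCohort
from synkin.space import InvalidInputError


class ConstantScoresError(ValueError):
    """Scores have zero variance; the correlation is undefined."""


def amplitude_correlation_map(
    cohort: BetaCohort,
    scores: dict[str, float] | np.ndarray,
    zscore: bool = True,
) -> np.ndarray:
    """Per-subject voxelwise Pearson r between betas and object scores.

    Parameters
    ----------
    scores : mapping object_id -> value, or array aligned with
        ``cohort.object_ids``. Scores are z-scored by default (the r is
        invariant to affine rescaling either way).

    Returns
    -------
    ndarray, (n_subjects, n_voxels); NaN where the betas have zero
    variance across objects.
    """
    if isinstance(scores, dict):
        missing = [o for o in cohort.object_ids if o not in scores]
        if missing:
            raise InvalidInputError(f"scores missing for objects: {missing}")
        s = np.array([scores[o] for o in cohort.object_ids], dtype=float)
    else:
        s = np.asarray(scores, dtype=float)
        if s.shape != (cohort.n_objects,):
            raise InvalidInputError("need exactly one score per cohort object")
    if s.std() == 0:
        raise ConstantScoresError("constant scores: correlation undefined")
    if zscore:
        s = (s - s.mean()) / s.std()
    sc = s - s.mean()
    data = cohort.data
    dc = data - data.mean(axis=1, keepdims=True)
    cov = np.einsum("o,sov->sv", sc, dc)
    d_ss = np.einsum("sov,sov->sv", dc, dc)
    s_ss = float(sc @ sc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(d_ss * s_ss)
    r = np.where(d_ss > 0, np.clip(r, -1.0, 1.0), np.nan)
    return r
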