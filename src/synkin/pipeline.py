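"""End-to-end workflow: simulate -> space -> encode -> searchlight ->
group -> compare -> amplitude, as toggled by a RunConfig.

Each stage logs structured progress and drops its artifacts under the
run's output directory; a provenance record (config, seeds, versions)
and a JSON summary make reruns comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np

import synkin
from synkin import io as skio
from synkin.amplitude import amplitude_correlation_map
from synkin.comparison import (
    ROISet,
    contrast_tests,
    permutation_anova,
    roi_scores,
    visual_model_rsm,
)
from synkin.config import RunConfig
from synkin.encoding import run_encoding_model, univariate_rsa_score
from synkin.inference import fisher_z, permutation_correct, smooth_volumes
from synkin.searchlight import SearchlightSpec, searchlight_cohort
from synkin.space import build_dendrogram, compute_rdm, entanglement_permutation_test
from synkin.synthetic import generate_cohort, generate_ratings, generate_visual_features

log = logging.getLogger("synkin.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the toggled stages; returns the summary report dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "versions": {"synkin": synkin.__version__, "numpy": np.__version__},
        "stages": {},
        "skipped": [],
    }
    synth = cfg.synth
    state: dict[str, Any] = {}

    def stage(name: str, fn) -> None:
        if not cfg.stages.get(name, False):
            report["skipped"].append(name)
            log.info("stage=%s skipped", name)
            return
        t0 = time.perf_counter()
        try:
            report["stages"][name] = fn() or {}
        except Exception as exc:  # noqa: BLE001 - halt with stage tag
            raise StageError(name, exc) from exc
        elapsed = time.perf_counter() - t0
        report["stages"][name]["elapsed_s"] = round(elapsed, 3)
        log.info("stage=%s seed=%s elapsed=%.2fs", name, cfg.seed, elapsed)

    def do_simulate() -> dict[str, Any]:
        votes, ratings = generate_ratings(synth, seed=cfg.seed)
        features, vis_rsm = generate_visual_features(synth, ratings, seed=cfg.seed)
        cohort, truth = generate_cohort(synth, ratings, visual_features=features, seed=cfg.seed)
        state.update(ratings=ratings, features=features, cohort=cohort, truth=truth)
        skio.write_ratings_csv(ratings, out / "ratings.csv")
        skio.write_cohort(cohort, out / "cohort")
        return {"n_subjects": cohort.n_subjects, "n_objects": cohort.n_objects,
                "n_voxels": cohort.n_voxels}

    def do_space() -> dict[str, Any]:
        ratings = state["ratings"]
        rdm = compute_rdm(ratings)
        tree = build_dendrogram(rdm)
        skio.write_similarity_csv(rdm, out / "kinematic_rdm.csv")
        skio.write_newick(tree, out / "kinematic_tree.nwk")
        # stability probe: tree vs tree from an independent rater sample
        _, ratings2 = generate_ratings(synth, seed=cfg.seed + 1)
        tree2 = build_dendrogram(compute_rdm(ratings2))
        res = entanglement_permutation_test(tree, tree2, n_perm=999, seed=cfg.seed,
                                            untangle=True)
        state.update(rdm=rdm, tree=tree)
        return {"entanglement": res.observed, "entanglement_p": res.p_value}

    def do_encode() -> dict[str, Any]:
        cohort, ratings = state["cohort"], state["ratings"]
        preds = run_encoding_model(cohort, ratings)
        score = univariate_rsa_score(cohort, preds)
        state.update(preds=preds, score=score)
        return {"n_invalid_folds": preds.n_invalid}

    def do_searchlight() -> dict[str, Any]:
        cohort, rdm = state["cohort"], state["rdm"]
        spec = SearchlightSpec(cfg.searchlight.radius, cfg.searchlight.min_voxels,
                               cfg.searchlight.comparison)
        kin_maps = searchlight_cohort(cohort, rdm.to_rsm(), spec)
        vis_rsm = visual_model_rsm(state["features"], list(cohort.object_ids))
        vis_maps = searchlight_cohort(cohort, vis_rsm, spec)
        state.update(kin_searchlight=kin_maps, vis_searchlight=vis_maps)
        return {"n_centers": int(np.isfinite(kin_maps[0]).sum())}

    def do_group() -> dict[str, Any]:
        cohort, score = state["cohort"], state["score"]
        inf = cfg.inference
        z = smooth_volumes(fisher_z(score.r), cohort.mask, inf.fwhm_mm, cohort.voxel_size_mm)
        stat = permutation_correct(z, cohort.mask, n_perm=inf.n_perm, seed=cfg.seed,
                                   alpha=inf.alpha, H=inf.tfce_h, E=inf.tfce_e,
                                   n_steps=inf.tfce_steps)
        state["group_stat"] = stat
        skio.write_volume(stat.t_volume, cohort.mask, out / "group_t.nii",
                          cohort.voxel_size_mm, cohort.affine)
        skio.write_volume(stat.p_corrected, cohort.mask, out / "group_p_tfce.nii",
                          cohort.voxel_size_mm, cohort.affine)
        n_sig = int(stat.significant(inf.alpha).sum())
        return {"n_significant_voxels": n_sig}

    def do_compare() -> dict[str, Any]:
        cohort, truth = state["cohort"], state["truth"]
        rois = ROISet(
            {"kinematic": truth.region_masks["kinematic"], "visual": truth.region_masks["visual"]},
            cohort.mask,
        )
        scores = roi_scores(
            {"kinematic": state["score"].r, "visual": state["vis_searchlight"]},
            rois, list(cohort.subject_ids),
        )
        table = contrast_tests(scores, "kinematic", "visual")
        anova = permutation_anova(scores, n_perm=cfg.inference.n_perm, seed=cfg.seed)
        table.to_csv(out / "model_contrasts.csv", index=False)
        return {
            "anova_f": anova.f_statistic,
            "anova_p": anova.p_value,
            "contrasts": {r["roi"]: r["mean_contrast"] for _, r in table.iterrows()},
        }

    def do_amplitude() -> dict[str, Any]:
        cohort, truth = state["cohort"], state["truth"]
        r_cen = amplitude_correlation_map(cohort, truth.centrality_scores)
        r_fam = amplitude_correlation_map(cohort, truth.familiarity_scores)
        cen_idx = truth.region_voxel_indices("centrality", cohort.mask)
        return {
            "centrality_region_mean_r": float(np.nanmean(r_cen[:, cen_idx])),
            "familiarity_region_mean_r": float(np.nanmean(r_fam[:, cen_idx])),
            "expected_centrality_r": truth.expected_centrality_r(),
        }

    stage("simulate", do_simulate)
    stage("space", do_space)
    stage("encode", do_encode)
    stage("searchlight", do_searchlight)
    stage("group", do_group)
    stage("compare", do_compare)
    stage("amplitude", do_amplitude)

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
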