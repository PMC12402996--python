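import numpy as np
import pytest

from synkin.encoding import (
    EmptyModelError,
    SynergyMapSet,
    build_fold_maps,
    build_synergy_map,
    high_low_sets,
    predict_object,
    run_encoding_model,
    univariate_rsa_score,
)
from synkin.space import InvalidInputError, RatingMatrix

from conftest import small_config
from synkin.synthetic import generate_cohort, generate_ratings, generate_visual_features


def _toy_ratings(loadings, n_obj=None):
    loadings = np.asarray(loadings, dtype=float)
    syn = [f"s{i}" for i in range(loadings.shape[0])]
    obj = [f"o{i}" for i in range(loadings.shape[1])]
    return RatingMatrix(loadings, syn, obj)


class TestHighLowSets:
    def test_strict_inequalities(self):
        rm = _toy_ratings([[0.75, 0.25, 0.8, 0.2, 0.5]])
        high, low = high_low_sets(rm, "s0", left_out="o4")
        assert high == ["o2"]  # 0.75 itself excluded: strictly greater
        assert low == ["o3"]  # 0.25 itself excluded: strictly less

    def test_left_out_never_included(self):
        rm = _toy_ratings([[0.9, 0.9, 0.1, 0.1]])
        high, low = high_low_sets(rm, "s0", left_out="o0")
        assert "o0" not in high + low


class TestBuildSynergyMap:
    def test_pairwise_enumeration_oracle(self, rng):
        """mean over all (h, l) pairs of (vol_h - vol_l), enumerated
        explicitly, equals both computation routes."""
        vols = rng.standard_normal((5, 7))
        rm = _toy_ratings([[0.9, 0.8, 0.1, 0.05, 0.5]])
        high, low = high_low_sets(rm, "s0", left_out="o4")
        acc = np.zeros(7)
        npairs = 0
        for h in high:
            for l in low:
                acc += vols[int(h[1])] - vols[int(l[1])]
                npairs += 1
        oracle = acc / npairs
        got_pair = build_synergy_map(vols, rm, "s0", "o4", method="pairwise")
        got_mean = build_synergy_map(vols, rm, "s0", "o4", method="mean")
        assert np.allclose(got_pair, oracle, rtol=1e-12)
        assert np.allclose(got_mean, oracle, rtol=1e-12)

    def test_single_high_two_low(self, rng):
        # high={A}, low={B,C}: map = A - (B + C)/2
        vols = rng.standard_normal((4, 6))
        rm = _toy_ratings([[0.9, 0.1, 0.2, 0.5]])
        got = build_synergy_map(vols, rm, "s0", "o3")
        assert np.allclose(got, vols[0] - (vols[1] + vols[2]) / 2)

    def test_absent_when_no_high(self, rng):
        vols = rng.standard_normal((3, 4))
        rm = _toy_ratings([[0.1, 0.2, 0.15]])
        assert build_synergy_map(vols, rm, "s0", "o2") is None

    def test_pairwise_equals_mean_random_instances(self, rng):
        """Algebraic identity on 100 random instances at tight tolerance."""
        for _ in range(100):
            n_obj = rng.integers(4, 10)
            vols = rng.standard_normal((n_obj, 11))
            load = rng.random((1, n_obj))
            rm = _toy_ratings(load)
            t = f"o{rng.integers(n_obj)}"
            a = build_synergy_map(vols, rm, "s0", t, method="pairwise")
            b = build_synergy_map(vols, rm, "s0", t, method="mean")
            if a is None:
                assert b is None
                continue
            assert np.allclose(a, b, rtol=1e-10, atol=1e-12)


class TestPredictObject:
    def test_single_synergy_identity(self, rng):
        m = rng.standard_normal(5)
        maps = SynergyMapSet("t", {"s0": m}, {"s0": (["a"], ["b"])})
        y = predict_object(maps, np.array([1.0]), ["s0"])
        assert np.array_equal(y, m)

    def test_zero_weights_zero_prediction(self, rng):
        m = rng.standard_normal(5)
        maps = SynergyMapSet("t", {"s0": m}, {"s0": (["a"], ["b"])})
        y = predict_object(maps, np.array([0.0]), ["s0"])
        assert np.all(y == 0)

    def test_hand_summed_weighted_combination(self):
        # 3 synergies on a 2-voxel grid, k = (0.8, 0.9, 0.0)
        m0, m1, m2 = np.array([1.0, 2.0]), np.array([-1.0, 0.5]), np.array([3.0, 3.0])
        maps = SynergyMapSet(
            "t",
            {"s0": m0, "s1": m1, "s2": m2},
            {k: (["a"], ["b"]) for k in ("s0", "s1", "s2")},
        )
        y = predict_object(maps, np.array([0.8, 0.9, 0.0]), ["s0", "s1", "s2"])
        expected = np.array([0.8 * 1.0 + 0.9 * -1.0, 0.8 * 2.0 + 0.9 * 0.5])
        assert np.allclose(y, expected)

    def test_all_absent_raises(self):
        maps = SynergyMapSet("t", {"s0": None}, {"s0": ([], ["b"])})
        with pytest.raises(EmptyModelError):
            predict_object(maps, np.array([0.5]), ["s0"])


class TestSynergyMapSetInvariants:
    def test_left_out_in_sets_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            SynergyMapSet("t", {"s0": rng.standard_normal(3)}, {"s0": (["t"], ["b"])})

    def test_absence_must_match_empty_set(self, rng):
        with pytest.raises(InvalidInputError):
            SynergyMapSet("t", {"s0": None}, {"s0": (["a"], ["b"])})


class TestRunEncodingModel:
    def test_fold_count_equals_objects(self, cohort_small, ratings_small):
        cohort, _ = cohort_small
        preds = run_encoding_model(cohort, ratings_small)
        assert preds.predicted.shape == (cohort.n_subjects, cohort.n_objects, cohort.n_voxels)

    def test_no_leakage_bit_identical(self, cohort_small, ratings_small, rng):
        """Replacing an object's observed volumes with noise leaves that
        object's prediction bit-identical."""
        cohort, _ = cohort_small
        preds = run_encoding_model(cohort, ratings_small)
        t = 4
        corrupted = cohort.data.copy()
        corrupted[:, t, :] = rng.standard_normal(corrupted[:, t, :].shape)
        from synkin.cohort import BetaCohort

        cohort2 = BetaCohort(corrupted, cohort.mask, cohort.affine,
                             cohort.subject_ids, cohort.object_ids, cohort.voxel_size_mm)
        preds2 = run_encoding_model(cohort2, ratings_small)
        assert np.array_equal(preds.predicted[:, t, :], preds2.predicted[:, t, :])

    def test_fast_path_matches_explicit_maps(self, cohort_small, ratings_small):
        """The collapsed object-weight route equals building synergy maps
        then summing them, per fold and subject."""
        cohort, _ = cohort_small
        preds = run_encoding_model(cohort, ratings_small)
        s = 1
        for t_idx in (0, 3, 7):
            t = cohort.object_ids[t_idx]
            maps = build_fold_maps(cohort.data[s], ratings_small, t)
            y = predict_object(maps, ratings_small.column(t), ratings_small.synergy_ids)
            assert np.allclose(preds.predicted[s, t_idx], y, rtol=1e-10, atol=1e-10)

    def test_too_few_objects_rejected(self, ratings_small, cohort_small):
        cohort, _ = cohort_small
        with pytest.raises(InvalidInputError):
            run_encoding_model(cohort, ratings_small.subset(ratings_small.object_ids[:2]))

    def test_noiseless_recovery(self):
        """Planted cohort at zero noise: mean in-region prediction r > 0.9.

        Uses strongly clustered ratings; with unstructured ratings the
        contrast maps carry cross-synergy talk and fidelity is lower even
        without noise.
        """
        cfg = small_config(noise_sd=0.0, subject_jitter=0.0,
                           cluster_strength=1.0, n_rating_clusters=3)
        _, ratings = generate_ratings(cfg)
        features, _ = generate_visual_features(cfg, ratings)
        cohort, truth = generate_cohort(cfg, ratings, visual_features=features)
        preds = run_encoding_model(cohort, ratings)
        score = univariate_rsa_score(cohort, preds)
        kin = truth.region_voxel_indices("kinematic", cohort.mask)
        assert np.nanmean(score.r[:, kin]) > 0.9

    def test_permutation_destruction(self):
        """Object-label shuffling of the ratings collapses in-region scores.

        A single shuffle leaves a common (subject-independent) residual
        alignment, so the check is against the intact model's effect and
        over several shuffles rather than against the between-subject SE.
        """
        cfg = small_config(n_subjects=8, seed=77, n_objects=33)
        _, ratings = generate_ratings(cfg)
        features, _ = generate_visual_features(cfg, ratings)
        cohort, truth = generate_cohort(cfg, ratings, visual_features=features)
        kin = truth.region_voxel_indices("kinematic", cohort.mask)

        def region_z(rm):
            preds = run_encoding_model(cohort, rm)
            score = univariate_rsa_score(cohort, preds)
            return float(np.nanmean(score.z[:, kin]))

        observed = region_z(ratings)
        rng = np.random.default_rng(0)
        shuffled_z = []
        for _ in range(5):
            perm = rng.permutation(ratings.n_objects)
            shuffled_z.append(region_z(RatingMatrix(
                ratings.loadings[:, perm], ratings.synergy_ids, ratings.object_ids)))
        assert observed > 0.2
        assert abs(np.mean(shuffled_z)) < observed / 4
        assert max(np.abs(shuffled_z)) < observed / 2

    def test_monotone_noise_degradation(self):
        """Mean planted-region r decreases as noise grows (3-point grid,
        averaged over replicates)."""
        means = []
        for noise in (0.5, 1.5, 4.0):
            vals = []
            for rep in range(3):
                cfg = small_config(noise_sd=noise, seed=500 + rep)
                _, ratings = generate_ratings(cfg)
                features, _ = generate_visual_features(cfg, ratings)
                cohort, truth = generate_cohort(cfg, ratings, visual_features=features)
                preds = run_encoding_model(cohort, ratings)
                score = univariate_rsa_score(cohort, preds)
                kin = truth.region_voxel_indices("kinematic", cohort.mask)
                vals.append(np.nanmean(score.r[:, kin]))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestUnivariateRsaScore:
    def test_perfect_prediction_r_one(self, cohort_small, ratings_small):
        cohort, _ = cohort_small
        preds = run_encoding_model(cohort, ratings_small)
        preds.predicted = cohort.data.copy()
        score = univariate_rsa_score(cohort, preds)
        assert np.allclose(score.r[score.valid], 1.0)

    def test_negated_prediction_r_minus_one(self, cohort_small, ratings_small):
        cohort, _ = cohort_small
        preds = run_encoding_model(cohort, ratings_small)
        preds.predicted = -cohort.data.copy()
        score = univariate_rsa_score(cohort, preds)
        assert np.allclose(score.r[score.valid], -1.0)

    def test_zero_variance_voxels_flagged_not_zeroed(self, cohort_small, ratings_small):
        cohort, _ = cohort_small
        preds = run_encoding_model(cohort, ratings_small)
        preds.predicted[:, :, 0] = 5.0  # constant across objects
        score = univariate_rsa_score(cohort, preds)
        assert not score.valid[:, 0].any()
        assert np.isnan(score.r[:, 0]).all()
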