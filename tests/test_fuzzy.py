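"""Triangular MFs, level models, possibility aggregation, classification."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from headlag import (
    HeadlagError,
    TriangularMF,
    classify,
    classify_batch,
    fit_level_model,
    fit_mf,
    load_models,
    mf_value,
    possibility,
    save_models,
)
from headlag.skeleton import KEYPOINTS_13, CanonicalSequence

from conftest import random_canonical


def brute_force_fp(coords, model):
    """Independent final-possibility oracle: direct triple loop, scalar MFs."""
    n, k, _ = coords.shape
    frame_sum = 0.0
    for f in range(n):
        kp_sum = 0.0
        for j in range(k):
            mx = mf_value(model.mf(f, j, "x"), coords[f, j, 0])
            my = mf_value(model.mf(f, j, "y"), coords[f, j, 1])
            kp_sum += math.sqrt(mx * my)
        frame_sum += kp_sum / k
    return frame_sum / n


class TestFitMF:
    def test_three_sigma_bounds(self):
        # Avg 0.5, population Sd 0.1 -> LB 0.2, UB 0.8
        values = 0.5 + 0.1 * np.array([-1.0, 1.0, -1.0, 1.0])
        mf = fit_mf(values)
        assert mf.avg == pytest.approx(0.5)
        assert mf.lb == pytest.approx(0.2)
        assert mf.ub == pytest.approx(0.8)

    def test_population_sd_of_zero_one(self):
        mf = fit_mf([0.0, 1.0])
        assert mf.avg == 0.5 and mf.sd == 0.5
        assert mf.lb == -1.0 and mf.ub == 2.0

    def test_single_value_degenerate(self):
        mf = fit_mf([0.7])
        assert mf.lb == mf.avg == mf.ub == 0.7 and mf.sd == 0.0

    def test_empty_rejected(self):
        with pytest.raises(HeadlagError):
            fit_mf([])


class TestMFValue:
    mf = TriangularMF(lb=0.2, avg=0.5, ub=0.8, sd=0.1)

    def test_apex_is_one(self):
        assert mf_value(self.mf, 0.5) == 1.0

    @pytest.mark.parametrize("x", [0.2, 0.8, 0.0, 1.0, -5.0, 5.0])
    def test_feet_and_outside_are_zero(self, x):
        assert mf_value(self.mf, x) == 0.0

    def test_linear_rise(self):
        # (0.35 - 0.2) / (0.5 - 0.2) = 0.5
        assert mf_value(self.mf, 0.35) == pytest.approx(0.5)

    def test_degenerate_mf_is_point_mass(self):
        mf = TriangularMF(lb=0.4, avg=0.4, ub=0.4, sd=0.0)
        assert mf_value(mf, 0.4) == 1.0
        assert mf_value(mf, 0.4 + 5e-10) == 1.0
        assert mf_value(mf, 0.41) == 0.0

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        values=st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=20
        ),
        x=st.floats(-1e6, 1e6, allow_nan=False),
    )
    def test_fitted_mf_bounded_with_maximal_apex(self, values, x):
        mf = fit_mf(values)
        assert 0.0 <= mf_value(mf, x) <= 1.0
        assert mf_value(mf, mf.avg) == 1.0


class TestFitLevelModel:
    def test_bank_dimensions(self, rng):
        seqs = [random_canonical(rng, n_frames=2, label=1) for _ in range(4)]
        model = fit_level_model(seqs)
        assert model.level == 1
        assert model.avg.shape == (2, 13, 2)  # N x k x 2 MFs

    def test_identical_training_gives_degenerate_bank(self, rng):
        seq = random_canonical(rng, label=3)
        model = fit_level_model([seq, seq, seq])
        np.testing.assert_allclose(model.sd, 0.0, atol=1e-15)
        np.testing.assert_allclose(model.avg, seq.coords, atol=1e-15)

    def test_mf_fitted_across_sequences(self, rng):
        seqs = [random_canonical(rng, n_frames=3, label=0) for _ in range(30)]
        model = fit_level_model(seqs)
        values = np.array([s.coords[1, 4, 0] for s in seqs])
        expected = fit_mf(values)
        got = model.mf(1, 4, "x")
        assert got.avg == pytest.approx(expected.avg)
        assert got.lb == pytest.approx(expected.lb)

    def test_mismatched_shapes_rejected(self, rng):
        a = random_canonical(rng, n_frames=3, label=0)
        b = random_canonical(rng, n_frames=4, label=0)
        with pytest.raises(HeadlagError):
            fit_level_model([a, b])


class TestPossibility:
    def test_geometric_mean_of_quarter_and_one(self):
        # poss = sqrt(0.25 * 1.0) = 0.5 at a single frame/keypoint
        coords = np.full((1, 13, 2), 0.5)
        seqs = [
            CanonicalSequence("a", coords - 0.01, KEYPOINTS_13, label=0),
            CanonicalSequence("b", coords + 0.01, KEYPOINTS_13, label=0),
        ]
        model = fit_level_model(seqs)
        mf = model.mf(0, 0, "x")
        x_quarter = mf.lb + 0.25 * (mf.avg - mf.lb)
        test_coords = coords.copy()
        test_coords[0, 0, 0] = x_quarter  # MF_X = 0.25, MF_Y = 1
        rep = possibility(
            CanonicalSequence("t", test_coords, KEYPOINTS_13), model
        )
        assert rep.per_keypoint[0][0, 0] == pytest.approx(0.5)

    def test_fp_one_at_model_average(self, rng):
        seqs = [random_canonical(rng, label=1) for _ in range(5)]
        model = fit_level_model(seqs)
        at_avg = CanonicalSequence(
            "avg", np.clip(model.avg, 0, 1), KEYPOINTS_13
        )
        assert possibility(at_avg, model).fp[1] == pytest.approx(1.0)

    def test_zero_membership_drags_fp_below_one(self, rng):
        # tight cluster around 0.3 -> every UB well below 1
        base = np.full((3, 13, 2), 0.3)
        seqs = [
            CanonicalSequence(f"s{i}", base + rng.normal(0, 0.01, base.shape),
                              KEYPOINTS_13, label=1)
            for i in range(5)
        ]
        model = fit_level_model(seqs)
        assert model.ub.max() < 1.0
        coords = np.clip(model.avg, 0, 1).copy()
        coords[0, 0, 0] = 1.0  # far outside that keypoint's MF support
        rep = possibility(CanonicalSequence("t", coords, KEYPOINTS_13), model)
        assert rep.per_keypoint[1][0, 0] == 0.0
        assert rep.fp[1] < 1.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            seqs = [random_canonical(rng, n_frames=3, label=0) for _ in range(4)]
            model = fit_level_model(seqs)
            test = random_canonical(rng, n_frames=3)
            fp = possibility(test, model).fp[0]
            assert fp == pytest.approx(brute_force_fp(test.coords, model), abs=1e-12)
            assert 0.0 <= fp <= 1.0

    def test_monotone_in_distance_from_apex(self, rng):
        seqs = [random_canonical(rng, n_frames=2, label=0) for _ in range(6)]
        model = fit_level_model(seqs)
        coords = np.clip(model.avg, 0, 1).copy()
        fps = []
        for x in np.linspace(model.avg[0, 0, 0], min(model.ub[0, 0, 0] + 0.1, 1.0), 8):
            c = coords.copy()
            c[0, 0, 0] = x
            fps.append(possibility(CanonicalSequence("t", c, KEYPOINTS_13), model).fp[0])
        assert all(a >= b - 1e-12 for a, b in zip(fps, fps[1:]))

    def test_shape_mismatch_rejected(self, rng):
        model = fit_level_model([random_canonical(rng, n_frames=3, label=0)])
        with pytest.raises(HeadlagError):
            possibility(random_canonical(rng, n_frames=4), model)


def separated_models_and_data(rng, n_per_level=8, gap=0.3, sd=0.005):
    """Three well-separated clusters of canonical sequences, one per level."""
    data = {}
    for i, lvl in enumerate((0, 1, 3)):
        center = np.full((4, 13, 2), 0.15 + i * gap)
        data[lvl] = [
            CanonicalSequence(
                f"L{lvl}_{j}",
                np.clip(center + rng.normal(0, sd, center.shape), 0, 1),
                KEYPOINTS_13,
                label=lvl,
            )
            for j in range(n_per_level)
        ]
    return data


class TestClassify:
    def test_argmax_over_levels(self, rng):
        data = separated_models_and_data(rng)
        models = {lvl: fit_level_model(v) for lvl, v in data.items()}
        rep = classify(data[0][0], models)
        assert rep.predicted == 0
        assert rep.fp[0] > rep.fp[1] >= 0 and rep.fp[0] > rep.fp[3] >= 0

    def test_leave_one_out_recovery_on_separated_clusters(self, rng):
        data = separated_models_and_data(rng)
        correct = total = 0
        for lvl, seqs in data.items():
            for i, held_out in enumerate(seqs):
                models = {
                    m: fit_level_model([s for j, s in enumerate(ss) if m != lvl or j != i],
                                       level=m)
                    for m, ss in data.items()
                }
                rep = classify(held_out, models)
                correct += rep.predicted == lvl
                total += 1
        assert correct == total  # 100% on well-separated clusters

    def test_all_zero_tie_predicts_lowest_with_warning(self, rng):
        data = separated_models_and_data(rng, sd=0.0)
        models = {lvl: fit_level_model(v) for lvl, v in data.items()}
        far = CanonicalSequence("far", np.ones((4, 13, 2)), KEYPOINTS_13)
        with pytest.warns(UserWarning, match="tied"):
            rep = classify(far, models)
        assert rep.predicted == 0
        assert rep.degenerate and all(v == 0.0 for v in rep.fp.values())

    def test_missing_level_model_rejected(self, rng):
        data = separated_models_and_data(rng)
        models = {lvl: fit_level_model(v) for lvl, v in data.items()}
        del models[1]
        with pytest.raises(HeadlagError, match="missing level"):
            classify(data[0][0], models)

    def test_batch_agrees_with_scalar_classify(self, rng):
        data = separated_models_and_data(rng)
        models = {lvl: fit_level_model(v) for lvl, v in data.items()}
        all_seqs = [s for seqs in data.values() for s in seqs]
        coords = np.stack([s.coords for s in all_seqs])
        predicted, fps = classify_batch(coords, models)
        for i, seq in enumerate(all_seqs):
            rep = classify(seq, models)
            assert predicted[i] == rep.predicted
            np.testing.assert_allclose(fps[i], [rep.fp[0], rep.fp[1], rep.fp[3]],
                                       atol=1e-14)


class TestModelPersistence:
    def test_round_trip_exact(self, tmp_path, rng):
        data = separated_models_and_data(rng, n_per_level=3)
        models = {lvl: fit_level_model(v) for lvl, v in data.items()}
        path = tmp_path / "models.yaml"
        save_models(models, path)
        back = load_models(path)
        assert set(back) == {0, 1, 3}
        for lvl in (0, 1, 3):
            np.testing.assert_array_equal(back[lvl].avg, models[lvl].avg)
            np.testing.assert_array_equal(back[lvl].sd, models[lvl].sd)
            assert back[lvl].keypoints == models[lvl].keypoints

    def test_retrain_writes_identical_file(self, tmp_path, rng):
        data = separated_models_and_data(rng, n_per_level=3)
        models = {lvl: fit_level_model(v) for lvl, v in data.items()}
        p1, p2 = tmp_path / "m1.yaml", tmp_path / "m2.yaml"
        save_models(models, p1)
        save_models({lvl: fit_level_model(v) for lvl, v in data.items()}, p2)
        assert p1.read_bytes() == p2.read_bytes()
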