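"""Synthetic-data generator: schedules, feature processes, the forward
model and cohort structure."""

import numpy as np
import pytest

from emoenc.data import BinnedHFB
from emoenc.features import EmotionFeatureSet, default_feature_set
from emoenc.simulate import (
    CohortSpec,
    GroundTruth,
    ParticipantSpec,
    default_cohort_spec,
    generate_block_schedule,
    generate_cohort,
    generate_feature_timecourses,
    synthesize_binned_hfb,
    synthesize_raw_signal,
)


class TestFeatureSet:
    def test_default_vocabulary(self, feature_set):
        assert feature_set.n_features == 48
        assert len(set(feature_set.names)) == 48
        for name in ("guilt", "embarrassment", "pride", "envy", "interest",
                     "joy", "sadness", "fear", "anger", "disgust", "surprise"):
            assert name in feature_set.names
        assert not (feature_set.complex_set & feature_set.basic_set)

    def test_five_complex_variant_adds_interest(self):
        fset = default_feature_set(five_complex=True)
        assert "interest" in fset.complex_set

    def test_rejects_wrong_count(self):
        with pytest.raises(ValueError):
            EmotionFeatureSet(names=("a", "b"))


class TestBlockSchedule:
    def test_movie_layout_13_blocks(self):
        s = generate_block_schedule(13, 30.0, seed=1)
        assert s.n_blocks == 13
        conds = list(s.condition)
        assert conds.count("music") == 7 and conds.count("speech") == 6
        # alternating
        assert all(a != b for a, b in zip(conds, conds[1:]))
        # exactly the fifth music block is feature-absent
        absent = s.block_index[~s.features_present]
        music_blocks = [i for i, c in enumerate(conds) if c == "music"]
        assert list(absent) == [music_blocks[4]]
        assert np.all(np.diff(s.onset) > 0)
        assert np.all(s.onset[1:] >= s.onset[:-1] + s.duration[:-1])

    def test_below_movie_layout_has_no_flag(self):
        s = generate_block_schedule(2, 30.0, seed=0)
        assert s.n_blocks == 2
        assert s.condition[0] != s.condition[1]
        assert s.features_present.all()

    def test_seeded_determinism(self):
        a = generate_block_schedule(13, 30.0, seed=1)
        b = generate_block_schedule(13, 30.0, seed=1)
        assert np.array_equal(a.onset, b.onset)
        assert a.condition == b.condition
        assert np.array_equal(a.features_present, b.features_present)

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            generate_block_schedule(13, -1.0, seed=0)


class TestFeatureTimecourses:
    def test_movie_yields_12_blocks_of_48x60(self, movie_schedule):
        f = generate_feature_timecourses(movie_schedule, 2.0, 2.0, seed=7)
        assert len(f.blocks) == 12
        for arr in f.blocks.values():
            assert arr.shape == (48, 60)
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_flagged_block_has_no_features(self, movie_schedule):
        f = generate_feature_timecourses(movie_schedule, 2.0, 2.0, seed=7)
        absent = int(movie_schedule.block_index[~movie_schedule.features_present][0])
        assert absent not in f.blocks

    def test_zero_smoothness_still_bounded(self, movie_schedule):
        f = generate_feature_timecourses(movie_schedule, 2.0, 0.0, seed=3)
        for arr in f.blocks.values():
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_smoothness_raises_lag1_autocorrelation(self, movie_schedule):
        """Across 200 traces, lag-1 autocorrelation under 2 s smoothing
        exceeds the value under near-white (0.1 s) smoothing."""
        def mean_lag1(smoothness, seed):
            acs = []
            f = generate_feature_timecourses(movie_schedule, 2.0, smoothness, seed=seed)
            for arr in f.blocks.values():
                for row in arr[:17]:   # ~200 traces over 12 blocks
                    a = row - row.mean()
                    denom = np.dot(a, a)
                    if denom > 0:
                        acs.append(np.dot(a[:-1], a[1:]) / denom)
            return np.mean(acs)

        assert mean_lag1(2.0, seed=11) > mean_lag1(0.1, seed=11)


class TestForwardModel:
    def test_identity_single_feature_single_lag(self, movie_schedule):
        f = generate_feature_timecourses(movie_schedule, 2.0, 2.0, seed=5)
        w = np.zeros((48, 1))
        w[7, 0] = 1.0
        truth = GroundTruth(w, noise_sd=0.0)
        out = synthesize_binned_hfb(f, truth, lags=(0.0,))
        for pos, b in enumerate(out.block_indices):
            np.testing.assert_allclose(out.values[0, pos], f.blocks[b][7])

    def test_zero_weights_zero_output(self, movie_features):
        truth = GroundTruth(np.zeros((48, 3)), noise_sd=0.0)
        out = synthesize_binned_hfb(movie_features, truth)
        assert np.all(out.values == 0)

    def test_matches_loop_convolution_oracle(self, movie_features):
        """Noiseless forward model equals an independent double loop over
        features and lags with explicit zero-padding at block starts."""
        rng = np.random.default_rng(8)
        w = rng.standard_normal((48, 3))
        truth = GroundTruth(w, noise_sd=0.0)
        lags = (0.0, 0.5, 1.0)
        out = synthesize_binned_hfb(movie_features, truth, lags=lags)
        for pos, b in enumerate(out.block_indices):
            x = movie_features.blocks[b]
            n = x.shape[1]
            expected = np.zeros(n)
            for t in range(n):
                for fi in range(48):
                    for li, lag in enumerate(lags):
                        shift = int(lag * 2)
                        if t - shift >= 0:
                            expected[t] += w[fi, li] * x[fi, t - shift]
            np.testing.assert_allclose(out.values[0, pos], expected, atol=1e-10)

    def test_linearity_in_weights(self, movie_features):
        rng = np.random.default_rng(9)
        w = rng.standard_normal((48, 3))
        one = synthesize_binned_hfb(movie_features, GroundTruth(w, 0.0))
        three = synthesize_binned_hfb(movie_features, GroundTruth(3.0 * w, 0.0))
        np.testing.assert_allclose(three.values, 3.0 * one.values, atol=1e-10)

    def test_shape_mismatch_rejected(self, movie_features):
        truth = GroundTruth(np.zeros((48, 2)), noise_sd=0.0)
        with pytest.raises(ValueError):
            synthesize_binned_hfb(movie_features, truth, lags=(0.0, 0.5, 1.0))


class TestRawSynthesis:
    def test_nyquist_violation_rejected(self, movie_schedule):
        b = BinnedHFB(np.zeros((1, 1, 60)), [0])
        with pytest.raises(ValueError):
            synthesize_raw_signal(b, movie_schedule, fs_raw=200.0)

    def test_zero_envelope_stays_at_baseline(self):
        """A zero target leaves the HFB amplitude flat at the baseline
        level: the extracted sqrt-envelope mean inside blocks matches the
        pre-block baseline mean closely."""
        from emoenc.preprocess import extract_hfb_amplitude

        sched = generate_block_schedule(2, 30.0, seed=0)
        b = BinnedHFB(np.zeros((2, 2, 60)), [0, 1])
        ses = synthesize_raw_signal(b, sched, seed=4, pink_sd=0.0, line_amp=0.0)
        amp = extract_hfb_amplitude(ses)
        fs = ses.fs
        i0, i1 = int(sched.onset[0] * fs), int((sched.onset[0] + 30) * fs)
        inside = amp.signal[0, i0:i1].mean()
        before = amp.signal[0, int(0.5 * fs) : i0].mean()
        assert abs(inside - before) / before < 0.1


class TestCohort:
    def test_default_cohort_counts(self):
        spec = default_cohort_spec(seed=0)
        groups = [p.group for p in spec.participants]
        assert groups.count("childhood") == 11
        assert groups.count("post_childhood") == 31
        n_dlpfc_child = sum(
            1 for p in spec.participants
            if p.group == "childhood" and "DLPFC" in p.areas
        )
        n_pstc_post = sum(
            1 for p in spec.participants
            if p.group == "post_childhood" and "pSTC" in p.areas
        )
        assert n_dlpfc_child == 8 and n_pstc_post == 25

    def test_metadata_rows(self, small_truth):
        cohort = generate_cohort(default_cohort_spec(seed=0), small_truth, seed=0)
        md = cohort.metadata()
        assert len(md) == 42
        assert (md["group"] == "childhood").sum() == 11

    def test_complex_weights_increase_with_age(self, small_truth, feature_set):
        spec = CohortSpec(
            participants=tuple(
                ParticipantSpec(f"P{i}", age=float(a), group="post_childhood",
                                areas={"pSTC": 4})
                for i, a in enumerate(np.linspace(13, 55, 12))
            ),
            complex_age_slope=0.01,
        )
        cohort = generate_cohort(spec, small_truth, seed=2)
        cx = feature_set.indices(feature_set.complex_set)
        means = [p.true_weights["pSTC"][cx].mean() for p in cohort.participants]
        assert np.all(np.diff(means) > 0)

    def test_childhood_dlpfc_weights_zeroed(self, small_truth):
        cohort = generate_cohort(default_cohort_spec(seed=1), small_truth, seed=1)
        for p in cohort.participants:
            if p.group == "childhood" and "DLPFC" in p.true_weights:
                assert np.all(p.true_weights["DLPFC"] == 0)
            if p.group == "post_childhood" and "DLPFC" in p.true_weights:
                assert np.any(p.true_weights["DLPFC"] != 0)

    def test_seeded_reproducibility(self, small_truth):
        a = generate_cohort(default_cohort_spec(seed=3), small_truth, seed=3)
        b = generate_cohort(default_cohort_spec(seed=3), small_truth, seed=3)
        for pa, pb in zip(a.participants, b.participants):
            for area in pa.binned:
                np.testing.assert_array_equal(
                    pa.binned[area].values, pb.binned[area].values
                )

    def test_age_range_validation(self):
        with pytest.raises(ValueError):
            CohortSpec(
                participants=(
                    ParticipantSpec("X", age=11.5, group="childhood",
                                    areas={"pSTC": 4}),
                ),
            )

    def test_contact_minimum_enforced(self):
        with pytest.raises(ValueError):
            CohortSpec(
                participants=(
                    ParticipantSpec("X", age=8, group="childhood",
                                    areas={"pSTC": 3}),
                ),
            )

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(participants=())
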