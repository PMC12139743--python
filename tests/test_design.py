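"""Design construction: face-table aggregation, 2 Hz resampling,
lagging, response binning and contact concatenation."""

import numpy as np
import pandas as pd
import pytest

from emoenc.data import BinnedHFB, BlockSchedule, FeatureTimecourses, HFBEpochs
from emoenc.design import (
    bin_response,
    build_lagged_design,
    concatenate_contacts,
    max_over_faces,
    resample_to_2hz,
)
from emoenc.encoding import ridge_fit
from emoenc.errors import SchemaError

NAMES = ("joy", "fear", "anger")


def _face_row(t, face, **scores):
    row = {"time_s": t, "face_id": face}
    row.update({n: scores.get(n, 0.0) for n in NAMES})
    return row


class TestMaxOverFaces:
    def test_two_faces_takes_max(self):
        df = pd.DataFrame([
            _face_row(0.0, 0, joy=0.2),
            _face_row(0.0, 1, joy=0.7),
        ])
        out = max_over_faces(df, NAMES)
        assert out.loc[0.0, "joy"] == 0.7

    def test_single_face_passthrough(self):
        df = pd.DataFrame([_face_row(0.0, 0, joy=0.3, fear=0.9)])
        out = max_over_faces(df, NAMES)
        assert out.loc[0.0, "joy"] == 0.3 and out.loc[0.0, "fear"] == 0.9

    def test_matches_per_frame_loop_oracle(self):
        rng = np.random.default_rng(10)
        rows = []
        for k in range(100):
            for face in range(rng.integers(1, 4)):
                rows.append(_face_row(
                    k * 0.04, face,
                    **{n: rng.uniform() for n in NAMES},
                ))
        df = pd.DataFrame(rows)
        out = max_over_faces(df, NAMES)
        for t, frame in df.groupby("time_s"):
            for n in NAMES:
                assert out.loc[t, n] == frame[n].max()

    def test_out_of_range_scores_rejected(self):
        df = pd.DataFrame([_face_row(0.0, 0, joy=1.2)])
        with pytest.raises(ValueError):
            max_over_faces(df, NAMES)

    def test_missing_column_named_in_error(self):
        df = pd.DataFrame([{"time_s": 0.0, "face_id": 0, "joy": 0.1}])
        with pytest.raises(SchemaError, match="fear"):
            max_over_faces(df, NAMES)

    def test_no_face_frame_scores_zero(self):
        df = pd.DataFrame([
            _face_row(0.0, 0, joy=0.5),
            {"time_s": 0.04, "face_id": np.nan,
             **{n: np.nan for n in NAMES}},
        ])
        out = max_over_faces(df, NAMES)
        assert (out.loc[0.04] == 0.0).all()


class TestResample:
    def test_constant_input_constant_output(self):
        t = np.arange(0, 30, 0.04)
        df = pd.DataFrame({"joy": np.full(len(t), 0.5)}, index=t)
        out = resample_to_2hz(df, block_dur=30.0)
        assert out.shape == (1, 60)
        np.testing.assert_allclose(out, 0.5)

    def test_30s_block_gives_60_samples(self):
        t = np.arange(0, 30, 0.04)
        df = pd.DataFrame({"joy": np.zeros(len(t))}, index=t)
        assert resample_to_2hz(df, block_dur=30.0).shape[1] == 60

    def test_linear_ramp_bin_means(self):
        """Bin averages of a 0->1 ramp at 25 fps match the analytic bin
        midpoints to 0.02."""
        t = np.arange(0, 30, 0.04)
        df = pd.DataFrame({"joy": t / 30.0}, index=t)
        out = resample_to_2hz(df, block_dur=30.0)[0]
        midpoints = (np.arange(60) * 0.5 + 0.25) / 30.0
        assert np.abs(out - midpoints).max() < 0.02

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            resample_to_2hz(pd.DataFrame({"joy": []}, index=[]), block_dur=30.0)


class TestLaggedDesign:
    def test_zero_lag_is_identity(self, movie_features):
        d = build_lagged_design(movie_features, lags=(0.0,))
        stacked = np.vstack(
            [movie_features.blocks[b].T for b in movie_features.block_indices]
        )
        np.testing.assert_array_equal(d.X, stacked)

    def test_movie_dimensions(self, movie_features):
        d = build_lagged_design(movie_features)
        assert d.X.shape == (720, 144)
        assert len(d.column_labels) == 144

    def test_impulse_shift_semantics(self):
        x = np.zeros((1, 10))
        x[0, 4] = 1.0
        f = FeatureTimecourses(("joy",), 2.0, {0: x})
        d = build_lagged_design(f, lags=(0.0, 0.5, 1.0))
        np.testing.assert_array_equal(np.nonzero(d.X[:, 0])[0], [4])
        np.testing.assert_array_equal(np.nonzero(d.X[:, 1])[0], [5])
        np.testing.assert_array_equal(np.nonzero(d.X[:, 2])[0], [6])

    def test_zero_padding_at_block_starts(self, movie_features):
        d = build_lagged_design(movie_features)
        block_starts = np.flatnonzero(np.diff(d.block_of_row, prepend=-1))
        # the 1 s lag columns are zero in the first two bins of each block
        lag2 = d.X[:, 96:]
        for s in block_starts:
            assert np.all(lag2[s] == 0) and np.all(lag2[s + 1] == 0)

    def test_non_grid_lag_rejected(self, movie_features):
        with pytest.raises(ValueError):
            build_lagged_design(movie_features, lags=(0.3,))


def _epochs(values, fs=400.0):
    n_blocks = values.shape[1]
    sched = BlockSchedule(
        onset=2.0 + np.arange(n_blocks) * 32.0,
        duration=np.full(n_blocks, values.shape[2] / fs),
        condition=tuple(
            "speech" if i % 2 == 0 else "music" for i in range(n_blocks)
        ),
        block_index=np.arange(n_blocks),
        features_present=np.ones(n_blocks, bool),
    )
    return HFBEpochs(values, fs, sched, ["c0"], ["pSTC"])


class TestBinResponse:
    def test_constant_epoch(self):
        ep = _epochs(np.ones((1, 2, 12000)))
        out = bin_response(ep)
        assert out.values.shape == (1, 2, 60)
        np.testing.assert_allclose(out.values, 1.0)

    def test_alternating_signs_cancel(self):
        v = np.tile(np.array([1.0, -1.0]), 6000)[None, None, :]
        out = bin_response(_epochs(v))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(11)
        v = rng.standard_normal((2, 3, 12000))
        out = bin_response(_epochs(v))
        for c in range(2):
            for b in range(3):
                for k in range(60):
                    expected = v[c, b, k * 200 : (k + 1) * 200].mean()
                    assert abs(out.values[c, b, k] - expected) < 1e-12

    def test_misaligned_length_rejected(self):
        with pytest.raises(ValueError):
            bin_response(_epochs(np.ones((1, 1, 12001))))


class TestConcatenateContacts:
    def test_single_contact_unchanged(self, movie_features, movie_design):
        b = BinnedHFB(
            np.random.default_rng(12).standard_normal((1, 12, 60)),
            movie_features.block_indices,
        )
        X, y, blocks, contacts = concatenate_contacts(b, movie_design)
        np.testing.assert_array_equal(X, movie_design.X)
        np.testing.assert_array_equal(y, b.values[0].ravel())

    def test_replication_arithmetic(self, movie_features, movie_design):
        b = BinnedHFB(
            np.random.default_rng(13).standard_normal((4, 12, 60)),
            movie_features.block_indices,
        )
        X, y, blocks, contacts = concatenate_contacts(b, movie_design)
        assert X.shape == (2880, 144) and y.shape == (2880,)
        assert len(blocks) == 2880 and len(contacts) == 2880

    def test_row_alignment_per_contact(self, movie_features, movie_design):
        b = BinnedHFB(
            np.random.default_rng(14).standard_normal((3, 12, 60)),
            movie_features.block_indices,
        )
        X, y, blocks, contacts = concatenate_contacts(b, movie_design)
        n = movie_design.n_rows
        for c in range(3):
            np.testing.assert_array_equal(y[c * n : (c + 1) * n],
                                          b.values[c].ravel())
            np.testing.assert_array_equal(X[c * n : (c + 1) * n], movie_design.X)

    def test_identical_contacts_match_single_fit_with_scaled_lambda(
        self, movie_features, movie_design
    ):
        """Duplicating every row k times while scaling lambda by k leaves
        the ridge solution unchanged, so identical contacts fit like one."""
        rng = np.random.default_rng(15)
        one = rng.standard_normal((1, 12, 60))
        b1 = BinnedHFB(one, movie_features.block_indices)
        b4 = BinnedHFB(np.tile(one, (4, 1, 1)), movie_features.block_indices)
        X1, y1, _, _ = concatenate_contacts(b1, movie_design)
        X4, y4, _, _ = concatenate_contacts(b4, movie_design)
        w1 = ridge_fit(X1, y1, 100.0)
        w4 = ridge_fit(X4, y4, 400.0)
        np.testing.assert_allclose(w4, w1, atol=1e-8)

    def test_condition_split_partitions_rows(self, movie_schedule, movie_features):
        speech = movie_schedule.blocks_for("speech")
        music = movie_schedule.blocks_for("music")
        assert set(speech) | set(music) == set(movie_features.block_indices)
        assert not set(speech) & set(music)
        # the feature-absent block contributes to neither
        absent = movie_schedule.block_index[~movie_schedule.features_present][0]
        assert absent not in set(speech) | set(music)
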