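"""Sliding-window SVR decoding: grids, CV machinery, nulls, group tests."""

import numpy as np
import pandas as pd
import pytest

import erpdecode as ed
from erpdecode.decoding import (FIRST_HALF_MS, SECOND_HALF_MS, Window,
                                temporal_samples, union_extent)
from erpdecode.errors import ValidationError
from erpdecode.validation import _labeled, _simulated_participant

from conftest import make_epochs


def small_cfg(**kw):
    defaults = dict(folds=5, repetitions=2)
    defaults.update(kw)
    return ed.PipelineConfig(**defaults)


class TestFisherZ:
    def test_reference_values(self):
        assert ed.fisher_z(0.0) == 0.0
        assert ed.fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        assert ed.fisher_z(np.tanh(1.0)) == pytest.approx(1.0)

    def test_inverse_pair(self, rng):
        r = rng.uniform(-0.99, 0.99, 50)
        assert np.allclose(ed.inverse_fisher_z(ed.fisher_z(r)), r, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            ed.fisher_z(1.5)

    def test_extreme_r_stays_finite(self):
        assert np.isfinite(ed.fisher_z(1.0)) and np.isfinite(ed.fisher_z(-1.0))


class TestWindowGrid:
    def test_forty_ms_window_holds_twenty_samples_at_512hz(self):
        grid = ed.make_window_grid(512.0)
        assert all(w.n_samples == 20 for w in grid.windows)

    def test_default_span_centers(self):
        grid = ed.make_window_grid(512.0, span_ms=(0, 400))
        assert np.array_equal(grid.centers_ms, np.arange(20, 381, 20))
        grid440 = ed.make_window_grid(512.0)
        assert grid440.centers_ms[-1] == 420.0

    def test_consecutive_centers_step(self):
        grid = ed.make_window_grid(512.0)
        assert np.allclose(np.diff(grid.centers_ms), 20.0)

    def test_step_equals_length_non_overlapping(self):
        grid = ed.make_window_grid(512.0, step_ms=40.0, span_ms=(0, 400))
        assert np.allclose(np.diff(grid.centers_ms), 40.0)
        starts = [w.start_sample for w in grid.windows]
        assert all(b - a >= 20 for a, b in zip(starts, starts[1:]))

    def test_span_shorter_than_window_rejected(self):
        with pytest.raises(ValidationError):
            ed.make_window_grid(512.0, span_ms=(0, 30))

    def test_half_periods_cover_ten_windows_each(self):
        grid = ed.make_window_grid(512.0)  # default 0-440 span
        centers = grid.centers_ms
        first = (centers >= FIRST_HALF_MS[0]) & (centers <= FIRST_HALF_MS[1])
        second = (centers >= SECOND_HALF_MS[0]) & (centers <= SECOND_HALF_MS[1])
        assert first.sum() == 10 and second.sum() == 10


class TestVectorize:
    def test_default_feature_count(self, rng):
        epochs = make_epochs(rng.standard_normal((5, 64, 410)))
        grid = ed.make_window_grid(512.0)
        x = ed.vectorize_window(epochs, grid.windows[0])
        assert x.shape == (5, 64 * 20)

    def test_exact_flattening_against_hand_oracle(self):
        data = np.arange(2 * 2 * 6, dtype=float).reshape(2, 2, 6)
        epochs = make_epochs(data, labels=("Cz", "Pz"), t_start=0.0, fs=1000.0)
        w = Window(1.0, 4.0, 1, 3)
        x = ed.vectorize_window(epochs, w)
        # channel-major: trial 0 = [ch0 s1..s3, ch1 s1..s3]
        assert np.array_equal(x[0], [1, 2, 3, 7, 8, 9])
        assert np.array_equal(x[1], [13, 14, 15, 19, 20, 21])

    def test_constant_trial_constant_features(self):
        data = np.full((1, 3, 20), 4.2)
        epochs = make_epochs(data, labels=("Cz", "Pz", "Oz"), t_start=0.0)
        x = ed.vectorize_window(epochs, Window(0, 20, 0, 10))
        assert np.all(x == 4.2)


class TestRunSvrCv:
    def test_default_config_runs_100_analyses(self, rng):
        x = rng.standard_normal((30, 8))
        y = np.repeat([1, 2, 3], 10)
        rs, _ = ed.run_svr_cv(x, y, ed.PipelineConfig(), rng)
        assert len(rs) == 100

    def test_perfect_feature_decodes_perfectly(self, rng):
        y = np.repeat([1.0, 2.0, 3.0], 10)
        x = y[:, None] + 1e-4 * rng.standard_normal((30, 1))
        _, z = ed.run_svr_cv(x, y, small_cfg(), rng)
        assert z > 2.0

    def test_shuffled_labels_center_on_zero(self, rng):
        zs = []
        for _ in range(40):
            x = rng.standard_normal((60, 10))
            y = rng.permutation(np.repeat([1, 2, 3], 20))
            _, z = ed.run_svr_cv(x, y, small_cfg(), rng)
            zs.append(z)
        assert abs(np.mean(zs)) < 0.1

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValidationError):
            ed.run_svr_cv(np.zeros((4, 3)), np.array([1, 2, 3, 1]),
                          ed.PipelineConfig(folds=10), rng)

    def test_constant_features_give_zero_r(self, rng):
        x = np.ones((30, 5))
        y = np.repeat([1, 2, 3], 10)
        rs, z = ed.run_svr_cv(x, y, small_cfg(), rng)
        assert z == 0.0 and all(r == 0.0 for r in rs)


class TestSlidingWindow:
    def _participant(self, rng, slope=3.0):
        labels = np.repeat([1, 2, 3], 10)
        rng.shuffle(labels)
        epochs = _simulated_participant(rng, labels, 8, 80, 256.0, slope,
                                        (120.0, 160.0), (0, 1))
        return epochs, _labeled(labels)

    def test_effect_localized_at_planted_window(self, rng):
        grid = ed.make_window_grid(256.0, span_ms=(0.0, 240.0), t_start_ms=0.0)
        gaps = np.zeros(len(grid.windows))
        for _ in range(4):
            epochs, lab = self._participant(rng)
            res = ed.sliding_window_decode(epochs, lab, grid, small_cfg(),
                                           seed=int(rng.integers(2 ** 31)))
            gaps += np.array([w.z_empirical - w.z_null for w in res.windows])
        best = grid.centers_ms[int(np.argmax(gaps))]
        assert abs(best - 140.0) <= 20.0  # within one window step

    def test_same_seed_bit_identical(self, rng):
        epochs, lab = self._participant(rng)
        grid = ed.make_window_grid(256.0, span_ms=(0.0, 160.0), t_start_ms=0.0)
        a = ed.sliding_window_decode(epochs, lab, grid, small_cfg(), seed=5)
        b = ed.sliding_window_decode(epochs, lab, grid, small_cfg(), seed=5)
        assert all(x.z_empirical == y.z_empirical and x.z_null == y.z_null
                   and x.r_empirical == y.r_empirical
                   for x, y in zip(a.windows, b.windows))

    def test_monotone_in_slope(self, rng):
        grid = ed.make_window_grid(256.0, span_ms=(100.0, 180.0),
                                   t_start_ms=0.0)
        means = []
        for slope in (0.0, 1.5, 4.0):
            zs = []
            for p in range(3):
                rng_p = np.random.default_rng(900 + p)
                labels = np.repeat([1, 2, 3], 10)
                rng_p.shuffle(labels)
                epochs = _simulated_participant(rng_p, labels, 8, 80, 256.0,
                                                slope, (120.0, 160.0), (0, 1))
                res = ed.sliding_window_decode(epochs, _labeled(labels), grid,
                                               small_cfg(), seed=p)
                zs += [w.z_empirical for w in res.windows]
            means.append(np.mean(zs))
        assert means[0] < means[1] < means[2]


class TestGroupStats:
    def _results(self, offsets, noise=0.05, n_windows=6, seed=0):
        rng = np.random.default_rng(seed)
        grid = ed.make_window_grid(256.0, span_ms=(0.0, 40 + (n_windows - 1) * 20),
                                   t_start_ms=0.0)
        out = []
        for p, off in enumerate(offsets):
            windows = []
            for c in grid.centers_ms:
                e = off + noise * rng.standard_normal()
                nl = noise * rng.standard_normal()
                windows.append(ed.decoding.WindowResult(f"P{p}", c, e, nl))
            out.append(ed.ParticipantDecoding(f"P{p}", "arousal", grid, windows))
        return out

    def test_constant_offset_all_windows_significant(self):
        res = self._results([0.3] * 16)
        stats = ed.group_stats(res)
        assert (stats.windows["p"] < 0.05).all()
        assert (stats.periods["p"] < 0.05).all()
        assert (stats.windows["df"] == 15).all()

    def test_mismatched_grids_rejected(self):
        res = self._results([0.1] * 4)
        other = self._results([0.1] * 1, n_windows=4)
        with pytest.raises(ValidationError):
            ed.group_stats(res + other)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValidationError):
            ed.group_stats(self._results([0.1, 0.1]))

    def test_model_front_end_matches_function(self):
        res = self._results([0.2] * 8)
        a = ed.GroupDecoding(res).fit()
        b = ed.group_stats(res)
        pd.testing.assert_frame_equal(a.windows, b.windows)


class TestChannelTemporalDecoding:
    def test_union_of_centers_100_120_has_31_samples(self, rng):
        epochs = make_epochs(rng.standard_normal((3, 64, 410)))
        grid = ed.make_window_grid(512.0)
        extent = union_extent(grid, [100.0, 120.0])
        assert extent == (80.0, 140.0)
        sl = temporal_samples(epochs, extent)
        assert sl.stop - sl.start == 31

    def test_effect_peaks_at_planted_channel(self, rng):
        labels = np.repeat([1, 2, 3], 10)
        results = []
        for p in range(3):
            rng_p = np.random.default_rng(70 + p)
            lab = labels.copy()
            rng_p.shuffle(lab)
            epochs = _simulated_participant(rng_p, lab, 8, 80, 256.0, 3.0,
                                            (120.0, 160.0), (4,))
            epochs.participant_id = f"P{p}"
            results.append(ed.channel_temporal_decode(
                epochs, _labeled(lab), (120.0, 160.0), small_cfg(), seed=p))
        table = ed.channel_group_stats(results)
        gap = table["mean_z_empirical"] - table["mean_z_null"]
        assert int(gap.idxmax()) == 4

    def test_empty_union_rejected(self, rng):
        epochs = make_epochs(rng.standard_normal((3, 8, 80)),
                             labels=ed.CHANNELS_64[:8])
        grid = ed.make_window_grid(512.0, span_ms=(0.0, 80.0))
        with pytest.raises(ValidationError):
            union_extent(grid, [999.0])
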