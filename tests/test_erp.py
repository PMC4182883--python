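"""ERP component quantification and repeated-measures ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import erpdecode as ed
from erpdecode.erp_analysis import anova_frame, mauchly_test
from erpdecode.errors import ValidationError

from conftest import make_epochs


class TestAveraging:
    def test_single_trial_condition_equals_trial(self, rng):
        data = rng.standard_normal((3, 4, 16))
        epochs = make_epochs(data, labels=ed.CHANNELS_64[:4])
        avg = ed.average_by_condition(epochs, np.array([1, 2, 3]))
        for cond in (1, 2, 3):
            assert np.array_equal(avg[cond], data[cond - 1])

    def test_identical_trial_sets_identical_averages(self, rng):
        data = np.concatenate([rng.standard_normal((5, 4, 16))] * 2)
        epochs = make_epochs(data, labels=ed.CHANNELS_64[:4])
        avg = ed.average_by_condition(epochs, np.repeat([1, 2], 5))
        assert np.allclose(avg[1], avg[2])

    def test_empty_condition_raises_naming_it(self, rng):
        epochs = make_epochs(rng.standard_normal((2, 4, 16)),
                             labels=ed.CHANNELS_64[:4])
        with pytest.raises(ValidationError, match="3"):
            ed.average_by_condition(epochs, np.array([1, 2]), conditions=[1, 2, 3])

    def test_mean_converges_to_template(self, rng):
        # planted template + zero-mean noise: the average must sit within
        # 3 SEM of the template at every sample (CLT bound)
        template = np.sin(np.linspace(0, 4 * np.pi, 64))
        sigma, n = 1.0, 500
        data = template[None, None, :] + sigma * rng.standard_normal((n, 1, 64))
        epochs = make_epochs(data, labels=("Cz",))
        avg = ed.average_by_condition(epochs, np.ones(n, dtype=int))[1]
        sem = sigma / np.sqrt(n)
        assert np.abs(avg[0] - template).max() < 3.5 * sem * np.sqrt(2)


class TestDetectPeak:
    def test_parabola_peak_latency(self):
        times = np.arange(0, 200, 2.0)
        v = -((times - 100.0) ** 2) + 7.0
        amp, lat = ed.detect_peak(v, times, (50, 150), "pos")
        assert lat == 100.0 and amp == 7.0

    def test_monotone_trace_peaks_at_window_edge(self):
        times = np.arange(0, 200, 2.0)
        v = -times
        amp, lat = ed.detect_peak(v, times, (50, 150), "neg")
        assert lat == 150.0

    def test_matches_exhaustive_scan(self, rng):
        times = -100 + np.arange(410) / 512 * 1000
        for _ in range(20):
            v = rng.standard_normal(410)
            for polarity, fn in (("neg", np.argmin), ("pos", np.argmax)):
                amp, lat = ed.detect_peak(v, times, (50, 150), polarity)
                i0 = np.argmin(np.abs(times - 50))
                i1 = np.argmin(np.abs(times - 150))
                k = fn(v[i0:i1 + 1])
                assert amp == v[i0 + k] and lat == times[i0 + k]

    def test_invariant_to_samples_outside_window(self, rng):
        times = np.arange(0, 200, 2.0)
        v = rng.standard_normal(len(times))
        ref = ed.detect_peak(v, times, (50, 150), "neg")
        v2 = v.copy()
        v2[times < 50] += 100
        v2[times > 150] -= 100
        assert ed.detect_peak(v2, times, (50, 150), "neg") == ref

    def test_nan_rejected(self):
        times = np.arange(0, 200, 2.0)
        v = np.zeros(len(times))
        v[40] = np.nan
        with pytest.raises(ValidationError):
            ed.detect_peak(v, times, (50, 150), "neg")


class TestEpnMean:
    def _epochs(self, data):
        return make_epochs(data)

    def test_constant_across_electrodes(self):
        times = -100 + np.arange(410) / 512 * 1000
        wf = np.full((64, 410), 2.5)
        out = ed.epn_mean({1: wf}, ed.CHANNELS_64, times)
        assert np.allclose(out["amplitude"], 2.5)

    def test_hemisphere_separation(self):
        times = -100 + np.arange(410) / 512 * 1000
        wf = np.zeros((64, 410))
        for ch in ("O1", "P9", "PO7"):
            wf[ed.CHANNELS_64.index(ch)] = 1.0
        for ch in ("O2", "PO8", "P10"):
            wf[ed.CHANNELS_64.index(ch)] = 2.0
        out = ed.epn_mean({1: wf}, ed.CHANNELS_64, times).set_index("hemisphere")
        assert out.loc["left", "amplitude"] == 1.0
        assert out.loc["right", "amplitude"] == 2.0

    def test_matches_brute_force_loop(self, rng):
        times = -100 + np.arange(410) / 512 * 1000
        wf = rng.standard_normal((64, 410))
        out = ed.epn_mean({1: wf}, ed.CHANNELS_64, times).set_index("hemisphere")
        i0 = int(np.argmin(np.abs(times - 280)))
        i1 = int(np.argmin(np.abs(times - 320)))
        for hemi, chans in (("left", ("O1", "P9", "PO7")),
                            ("right", ("O2", "PO8", "P10"))):
            total, count = 0.0, 0
            for ch in chans:
                for s in range(i0, i1 + 1):
                    total += wf[ed.CHANNELS_64.index(ch), s]
                    count += 1
            assert abs(out.loc[hemi, "amplitude"] - total / count) < 1e-12


class TestGgEpsilon:
    def test_compound_symmetry_gives_one(self):
        s = 0.3 * np.ones((4, 4)) + 0.7 * np.eye(4)
        assert ed.gg_epsilon(s) == pytest.approx(1.0)

    def test_rank_one_hits_lower_bound(self, rng):
        v = rng.standard_normal(3)
        v = v - v.mean()  # keep variation inside the contrast space
        s = np.outer(v, v)
        assert ed.gg_epsilon(s) == pytest.approx(0.5)

    def test_matches_literal_box_formula(self, rng):
        # independent transcription: eps = [k^2 (mean diag - grand mean)]^2 /
        # [(k-1) (SS of entries - 2k SS of row means + k^2 grandmean^2)]
        for _ in range(20):
            a = rng.standard_normal((6, 4))
            s = np.cov(a, rowvar=False) + 0.5 * np.eye(4)
            k = 4
            sbar = s.mean()
            dbar = np.trace(s) / k
            rowbar = s.mean(axis=1)
            num = (k * (dbar - sbar)) ** 2
            den = (k - 1) * (np.sum(s ** 2) - 2 * k * np.sum(rowbar ** 2)
                             + k ** 2 * sbar ** 2)
            expected = np.clip(num / den, 1 / (k - 1), 1.0)
            assert ed.gg_epsilon(s) == pytest.approx(expected, abs=1e-10)

    def test_small_matrix_rejected(self):
        with pytest.raises(ValidationError):
            ed.gg_epsilon(np.eye(1))


def _long(y, subjects=None, factor="condition"):
    n, k = y.shape
    rows = []
    for s in range(n):
        for c in range(k):
            rows.append({"subject": f"S{s}", factor: c, "dv": y[s, c]})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_two_level_f_equals_squared_paired_t(self, rng):
        y = rng.standard_normal((12, 2)) + [0.0, 0.4]
        res = ed.rm_anova(_long(y), "dv", "subject", ["condition"])[0]
        t, p = stats.ttest_rel(y[:, 1], y[:, 0])
        assert res.F == pytest.approx(t ** 2, abs=1e-9)
        assert res.p_uncorrected == pytest.approx(p, abs=1e-9)

    def test_matches_pingouin_one_way(self, rng):
        import pingouin as pg
        y = rng.standard_normal((10, 3)) @ np.diag([1.0, 2.0, 0.5]) + [0, .5, 1]
        df = _long(y)
        ours = ed.rm_anova(df, "dv", "subject", ["condition"])[0]
        theirs = pg.rm_anova(data=df, dv="dv", within="condition",
                             subject="subject", correction=True)
        assert ours.F == pytest.approx(float(theirs["F"].iloc[0]), rel=1e-9)
        assert ours.epsilon == pytest.approx(float(theirs["eps"].iloc[0]),
                                             abs=1e-6)
        assert ours.p_gg == pytest.approx(float(theirs["p_GG_corr"].iloc[0]),
                                          abs=1e-6)

    def test_planted_laterality_effect_pattern(self, rng):
        # strong laterality offset, no increment effect: the two-way ANOVA
        # must flag laterality and not the increment
        n = 16
        rows = []
        for s in range(n):
            base = rng.standard_normal()
            for inc in (1, 2, 3):
                for lat, off in (("left", 0.0), ("right", 1.0)):
                    rows.append({"subject": s, "condition": inc,
                                 "hemisphere": lat,
                                 "dv": base + off + 0.3 * rng.standard_normal()})
        res = ed.rm_anova(pd.DataFrame(rows), "dv", "subject",
                          ["condition", "hemisphere"])
        table = anova_frame(res).set_index("effect")
        assert table.loc["hemisphere", "p"] < 0.01
        assert table.loc["condition", "p"] > 0.05

    def test_identical_cells_degenerate(self):
        y = np.full((6, 3), 2.0)
        res = ed.rm_anova(_long(y), "dv", "subject", ["condition"])[0]
        assert res.degenerate and res.p == 1.0 and res.F == 0.0

    def test_missing_cell_rejected(self, rng):
        df = _long(rng.standard_normal((5, 3)))
        df = df[~((df["subject"] == "S2") & (df["condition"] == 1))]
        with pytest.raises(ValidationError, match="missing"):
            ed.rm_anova(df, "dv", "subject", ["condition"])

    def test_null_rejection_rate_nominal(self, rng):
        # global null: 1000 simulated datasets, increment effect should
        # reject at about the nominal 5% rate
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            y = rng.standard_normal((16, 3))
            res = ed.rm_anova(_long(y), "dv", "subject", ["condition"])[0]
            if res.p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sims <= 0.07

    def test_mauchly_two_level_trivial(self, rng):
        w, p = mauchly_test(rng.standard_normal((10, 2)))
        assert w == 1.0 and p == 1.0

    def test_mauchly_matches_pingouin(self, rng):
        import pingouin as pg
        y = rng.standard_normal((12, 4)) @ np.diag([1.0, 3.0, 0.5, 1.5])
        w, p = mauchly_test(y)
        spher = pg.sphericity(pd.DataFrame(y))
        assert w == pytest.approx(float(spher.W), abs=1e-8)
        # pingouin adds a second-order term to the chi-square approximation;
        # the first-order p agrees closely
        assert p == pytest.approx(float(spher.pval), abs=1e-3)


class TestErpComponentModel:
    def test_end_to_end_summary(self, session_data, montage):
        _, _, epochs = session_data
        ratings = ed.generate_ratings(3, seed=7)  # S01 matches session_data
        sched2 = ed.generate_design(seed=8)
        eff = [ed.EffectSpec(slope_uv=2.0, window_ms=(160.0, 200.0))]
        noise = ed.NoiseSpec(rms_uv=10.0)
        data = {}
        for pid, ep in (("S01", epochs),
                        ("S02", ed.generate_epochs(sched2, ratings, eff, noise,
                                                   "S02", seed=9)),
                        ("S03", ed.generate_epochs(sched2, ratings, eff, noise,
                                                   "S03", seed=10))):
            ep = ed.filter_epochs(ep, "lowpass30")
            inc = ratings.increments_for(pid, "time_reference")
            labels = inc.loc[ep.trial_meta["image_id"]].to_numpy()
            data[pid] = (ep, labels)
        results = ed.ErpComponentModel(data).fit()
        assert {"N1", "N2", "P3", "EPN"} == set(results.measures["component"])
        # peak latencies must lie inside their windows
        n1 = results.measures.query("component == 'N1'")
        assert n1["latency_ms"].between(50, 150).all()
        text = results.summary()
        assert "EPN amplitude" in text and "F" in text
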