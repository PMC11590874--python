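"""Morlet CWT, wavelet coherence, permuted-dyad null and POI selection."""

import numpy as np
import pandas as pd
import pytest

import dyadsync.coherence as coh
from dyadsync.coherence import (
    POI,
    ScaleComparisonTable,
    WaveletParams,
    build_permutated_dyads,
    compare_scales,
    cwt_morlet,
    fourier_factor,
    ibs_index,
    identify_poi,
    time_avg_coherence,
    wtc,
)

FS = 10.0


class TestCwt:
    def test_sinusoid_peaks_at_nearest_grid_period(self):
        t = np.arange(6000) / FS
        W, periods, _ = cwt_morlet(np.sin(2 * np.pi * t / 20.0), FS)
        peak = periods[(np.abs(W) ** 2).mean(axis=1).argmax()]
        nearest = periods[np.argmin(np.abs(periods - 20.0))]
        assert peak == nearest

    def test_zero_signal_gives_zero_coefficients(self):
        W, _, _ = cwt_morlet(np.zeros(2000), FS)
        assert np.allclose(W, 0.0)

    def test_linearity(self, rng):
        x, y = rng.standard_normal(1500), rng.standard_normal(1500)
        Wxy, _, _ = cwt_morlet(x + y, FS)
        Wx, _, _ = cwt_morlet(x, FS)
        Wy, _, _ = cwt_morlet(y, FS)
        denom = np.abs(Wxy).max()
        assert np.abs(Wxy - (Wx + Wy)).max() / denom < 1e-10

    def test_matches_pywavelets_peak_frequency(self):
        """Independent CWT implementation localizes the same oscillation."""
        pywt = pytest.importorskip("pywt")
        t = np.arange(4000) / FS
        sig = np.sin(2 * np.pi * 0.05 * t)
        W, periods, _ = cwt_morlet(sig, FS)
        mine = 1.0 / periods[(np.abs(W) ** 2).mean(axis=1).argmax()]
        freqs = np.linspace(0.02, 0.12, 60)
        scales = pywt.frequency2scale("cmor1.5-1.0", freqs / FS)
        Wp, _ = pywt.cwt(sig, scales, "cmor1.5-1.0", sampling_period=1 / FS)
        theirs = freqs[(np.abs(Wp) ** 2).mean(axis=1).argmax()]
        assert mine == pytest.approx(0.05, rel=0.06)
        assert theirs == pytest.approx(0.05, rel=0.06)

    def test_long_periods_trimmed_with_warning(self):
        with pytest.warns(UserWarning, match="trimmed"):
            _, periods, _ = cwt_morlet(np.random.default_rng(0).standard_normal(600), FS)
        assert periods[-1] <= 30.0

    def test_fourier_factor_convention(self):
        # period = 4 pi s / (omega0 + sqrt(2 + omega0^2)); for omega0=6 the
        # scale and period are within ~3.4% of each other
        assert fourier_factor(6.0) == pytest.approx(1.033043647, abs=1e-8)

    def test_params_validation(self):
        with pytest.raises(ValueError, match="omega0"):
            WaveletParams(omega0=2.0)
        with pytest.raises(ValueError, match="scales_per_octave"):
            WaveletParams(scales_per_octave=2)


class TestWtc:
    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal(3000)
        res = wtc(x, x, FS)
        assert res.coherence.min() >= 0.999

    def test_symmetry(self, rng):
        x, y = rng.standard_normal(2000), rng.standard_normal(2000)
        a = wtc(x, y, FS).coherence
        b = wtc(y, x, FS).coherence
        assert np.abs(a - b).max() < 1e-9

    def test_bounded_for_independent_noise(self, rng):
        x, y = rng.standard_normal(3000), rng.standard_normal(3000)
        res = wtc(x, y, FS)
        assert res.coherence.min() >= 0.0
        assert res.coherence.max() <= 1.0
        inside = res.coherence[res.coi_mask()]
        assert inside.mean() < 0.9  # far from perfect coherence

    def test_shared_band_oscillation_raises_in_band_coherence(self):
        """Partners sharing an 18 s rhythm at SNR 1 cohere inside 15-22 s."""
        diffs = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            t = np.arange(4000) / FS
            phase = rng.uniform(0, 2 * np.pi)
            common = np.sqrt(2.0) * np.sin(2 * np.pi * t / 18.0 + phase)
            x = common + rng.standard_normal(4000)
            y = common + rng.standard_normal(4000)
            res = wtc(x, y, FS)
            vec = time_avg_coherence(res)
            band = (res.periods_s >= 15) & (res.periods_s <= 22)
            diffs.append(np.nanmean(vec[band]) - np.nanmean(vec[~band]))
        diffs = np.array(diffs)
        ci_half = 1.96 * diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert diffs.mean() - ci_half > 0.1

    def test_unequal_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="aligned"):
            wtc(rng.standard_normal(100), rng.standard_normal(99), FS)


class TestTimeAverage:
    def _result(self, matrix, periods, times, coi):
        return coh.CoherenceResult(
            coherence=np.asarray(matrix, dtype=float),
            periods_s=np.asarray(periods, dtype=float),
            times_s=np.asarray(times, dtype=float),
            coi_s=np.asarray(coi, dtype=float),
        )

    def test_constant_matrix(self):
        res = self._result(np.full((3, 4), 0.7), [4, 8, 16], [0, 1, 2, 3], [100] * 4)
        assert np.allclose(time_avg_coherence(res), 0.7)

    def test_full_window_equals_global_mean(self, rng):
        mat = rng.random((3, 50))
        res = self._result(mat, [4, 8, 16], np.arange(50.0), [100] * 50)
        assert np.allclose(
            time_avg_coherence(res, (0.0, 50.0)), time_avg_coherence(res)
        )

    def test_hand_computed_row_means(self):
        mat = [[0.1, 0.2, 0.3, 0.4], [0.5, 0.5, 0.5, 0.5], [0.0, 1.0, 1.0, 0.0]]
        res = self._result(mat, [4, 8, 16], [0, 1, 2, 3], [100] * 4)
        assert np.allclose(time_avg_coherence(res), [0.25, 0.5, 0.5])

    def test_coi_exclusion(self):
        # long period valid only mid-record
        mat = np.ones((2, 4))
        res = self._result(mat, [4, 16], [0, 1, 2, 3], [5, 20, 20, 5])
        vec = time_avg_coherence(res, exclude_coi=True)
        assert np.allclose(vec, [1.0, 1.0])
        res2 = self._result([[1, 1, 1, 1], [0, 1, 1, 0]], [4, 16], [0, 1, 2, 3], [5, 20, 20, 5])
        assert np.allclose(time_avg_coherence(res2), [1.0, 1.0])

    def test_empty_window_rejected(self):
        res = self._result(np.ones((2, 4)), [4, 16], [0, 1, 2, 3], [100] * 4)
        with pytest.raises(ValueError, match="window"):
            time_avg_coherence(res, (10.0, 12.0))


class TestPermutedDyads:
    def test_two_dyads_enumeration(self):
        participants = [("A1", "dA"), ("A2", "dA"), ("B1", "dB"), ("B2", "dB")]
        pairs = build_permutated_dyads(participants, 4, seed=0)
        assert sorted(pairs) == [("A1", "B1"), ("A1", "B2"), ("A2", "B1"), ("A2", "B2")]

    def test_admissible_count_for_36_dyads(self):
        participants = [(f"P{d}_{m}", f"D{d}") for d in range(36) for m in "ab"]
        pairs = build_permutated_dyads(participants, 180, seed=1)
        assert len(pairs) == len(set(pairs)) == 180
        with pytest.raises(ValueError, match="2520"):
            build_permutated_dyads(participants, 2521, seed=1)

    def test_deterministic_given_seed(self):
        participants = [(f"P{d}_{m}", f"D{d}") for d in range(10) for m in "ab"]
        a = build_permutated_dyads(participants, 30, seed=42)
        b = build_permutated_dyads(participants, 30, seed=42)
        c = build_permutated_dyads(participants, 30, seed=43)
        assert a == b
        assert a != c

    def test_single_dyad_rejected(self):
        with pytest.raises(ValueError, match="2 dyads"):
            build_permutated_dyads([("x", "d"), ("y", "d")], 1, seed=0)


def _welch_oracle(a, b):
    """Textbook Welch formulas, evaluated stepwise."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    t = (a.mean() - b.mean()) / np.sqrt(v1 / n1 + v2 / n2)
    df = (v1 / n1 + v2 / n2) ** 2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    )
    return t, df


def _bh_oracle(pvals):
    """Benjamini-Hochberg step-up by hand."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * m / rank_from_top)
        q[i] = prev
    return q


class TestCompareScales:
    def test_identical_groups_give_t0_p1(self):
        mat = np.tile([[0.3, 0.4, 0.5]], (4, 1)) + np.arange(4)[:, None] * 0.01
        table = compare_scales(mat, mat.copy(), np.array([8.0, 16.0, 32.0])).table
        assert np.allclose(table["t"], 0.0)
        assert np.allclose(table["p"], 1.0)

    def test_welch_statistic_matches_hand_formula(self):
        g = np.array([[1.0], [2.0], [3.0]])
        p = np.array([[2.0], [3.0], [4.0], [5.0]])
        row = compare_scales(g, p, np.array([10.0])).table.iloc[0]
        t_ref, df_ref = _welch_oracle([1, 2, 3], [2, 3, 4, 5])
        assert row["t"] == pytest.approx(t_ref, abs=1e-12)
        assert row["df"] == pytest.approx(df_ref, abs=1e-12)
        # scipy as a second, independent route
        from scipy import stats

        sp = stats.ttest_ind([1, 2, 3], [2, 3, 4, 5], equal_var=False)
        assert row["t"] == pytest.approx(sp.statistic, abs=1e-12)
        assert row["p"] == pytest.approx(sp.pvalue, abs=1e-12)

    def test_bh_qvalues_match_step_up_by_hand(self, rng):
        pvals = [0.01, 0.02, 0.03, 0.04]
        # craft groups whose Welch p-values don't matter; patch q directly
        q = _bh_oracle(pvals)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        # and the module's q column agrees with the oracle on real data
        g = rng.normal(0.5, 0.1, size=(12, 6))
        p = rng.normal(0.45, 0.1, size=(30, 6))
        table = compare_scales(g, p, np.arange(1.0, 7.0)).table
        assert np.allclose(table["q"], _bh_oracle(table["p"]), atol=1e-12)
        assert (table["q"] >= table["p"] - 1e-15).all()

    def test_degenerate_rows_flagged_and_outside_family(self):
        g = np.array([[0.5, 0.1], [0.5, 0.2], [0.5, 0.3]])
        p = np.array([[0.5, 0.2], [0.5, 0.25], [0.5, 0.35]])
        table = compare_scales(g, p, np.array([8.0, 16.0])).table
        assert bool(table.loc[0, "degenerate"])
        assert np.isnan(table.loc[0, "q"])
        assert not bool(table.loc[1, "degenerate"])


def _table(periods, q, mg, mp):
    df = pd.DataFrame(
        dict(period_s=periods, mean_genuine=mg, mean_permutated=mp,
             t=np.nan, df=np.nan, p=q, q=q, cohens_d=np.nan,
             degenerate=[False] * len(periods))
    )
    return ScaleComparisonTable(table=df)


class TestPoi:
    def test_none_significant_gives_empty(self):
        t = _table([4, 8, 16], [0.5, 0.2, 0.9], [0.4] * 3, [0.3] * 3)
        assert identify_poi(t) == []

    def test_all_significant_single_run(self):
        t = _table([4, 8, 16], [0.01] * 3, [0.4] * 3, [0.3] * 3)
        (poi,) = identify_poi(t)
        assert (poi.period_lo_s, poi.period_hi_s) == (4, 16)

    def test_split_runs(self):
        q = [0.5, 0.01, 0.01, 0.5, 0.01]
        t = _table([4, 5, 6, 7, 8], q, [0.4] * 5, [0.3] * 5)
        runs = identify_poi(t)
        assert [(p.period_lo_s, p.period_hi_s) for p in runs] == [(5, 6), (8, 8)]

    def test_requires_genuine_above_permutated(self):
        t = _table([4, 8], [0.01, 0.01], [0.2, 0.4], [0.3, 0.3])
        (poi,) = identify_poi(t)
        assert poi.period_lo_s == 8

    def test_ibs_index_examples(self):
        periods = np.array([15.48, 16.40, 17.37])
        poi = POI(15.48, 17.37, periods)
        vec = np.array([0.336, 0.344, 0.352])
        assert ibs_index(vec, periods, poi).value == pytest.approx(0.344)
        single = POI(16.40, 16.40, np.array([16.40]))
        assert ibs_index(vec, periods, single).value == pytest.approx(0.344)
        constant = np.full(3, 0.5)
        assert ibs_index(constant, periods, poi).value == 0.5
        with pytest.raises(ValueError, match="empty"):
            ibs_index(vec, periods, POI(0, 0, np.array([])))


def test_smoothed_cross_spectra_matches_wtc(rng):
    """The cached/decimated batch path agrees with the reference pairwise path."""
    x, y = rng.standard_normal(3000), rng.standard_normal(3000)
    t = np.arange(3000) / FS
    shared = np.sin(2 * np.pi * t / 18.0)
    x, y = x + shared, y + shared
    full = wtc(x, y, FS)
    batch = coh.smoothed_cross_spectra({"a": x, "b": y}, [("a", "b")], FS, decimate=1)[("a", "b")]
    assert np.abs(batch.coherence - full.coherence).max() < 1e-12
    dec = coh.smoothed_cross_spectra({"a": x, "b": y}, [("a", "b")], FS, decimate=4)[("a", "b")]
    v_full = time_avg_coherence(full)
    v_dec = time_avg_coherence(dec)
    assert np.nanmax(np.abs(v_full - v_dec)) < 0.02
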