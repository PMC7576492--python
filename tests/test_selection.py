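"""Channel-selection scores: band power, PCR, PCA loadings, ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from emgforce import (
    band_power,
    dimensionality_reduction_pct,
    mean_abs_corr,
    normalized_power,
    pca_loadings,
    pcr_scores,
    pearson_r,
    select_channels,
    select_pca_freq,
    select_pca_time,
    select_pcr,
)
from emgforce.errors import DegenerateChannelError, UndefinedCorrelationError

FS = 2048.0


def _tones(freqs, n=8192, fs=FS):
    """Columns of unit sinusoids at distinct bin-aligned frequencies.

    Whole numbers of periods make distinct tones exactly orthogonal under
    the sample inner product.
    """
    t = np.arange(n) / fs
    return np.column_stack([np.sin(2 * np.pi * f * t) for f in freqs])


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

class TestBandPower:
    def test_unit_sinusoid_power_half(self):
        x = _tones([100.0])[:, 0]
        assert band_power(x, FS) == pytest.approx(0.5, rel=0.05)

    def test_quadratic_scaling(self):
        x = np.random.default_rng(0).standard_normal(8192)
        assert band_power(2 * x, FS) == pytest.approx(4 * band_power(x, FS), rel=1e-6)

    def test_full_band_integral_matches_variance(self):
        x = np.random.default_rng(1).standard_normal(16384)
        assert band_power(x, FS, low=0.0, high=FS / 2) == pytest.approx(x.var(), rel=0.1)

    def test_zero_signal_zero_power(self):
        assert band_power(np.zeros(4096), FS) == 0.0


class TestNormalizedPower:
    def test_divides_by_maximum(self):
        np.testing.assert_allclose(normalized_power([4.0, 2.0, 1.0]), [1.0, 0.5, 0.25])

    def test_all_equal_gives_ones(self):
        np.testing.assert_allclose(normalized_power([3.3] * 5), 1.0)

    def test_matches_elementwise_oracle(self):
        p = np.random.default_rng(2).random(7) + 0.1
        np.testing.assert_allclose(normalized_power(p), p / p.max())

    def test_degenerate_muscle_rejected(self):
        with pytest.raises(DegenerateChannelError):
            normalized_power([0.0, 0.0])


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

class TestPearson:
    def test_self_and_negation(self):
        x = np.random.default_rng(3).standard_normal(100)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson_r(np.array([1.0, 2, 3, 4]),
                         np.array([2.0, 1, 4, 3])) == pytest.approx(0.6)

    @given(a=st.floats(0.01, 10), b=st.floats(-5, 5), seed=st.integers(0, 20))
    def test_affine_invariance(self, a, b, seed):
        x, y = np.random.default_rng(seed).standard_normal((2, 50))
        assert pearson_r(a * x + b, y) == pytest.approx(pearson_r(x, y), abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r(np.ones(10), np.arange(10.0))


class TestMeanAbsCorr:
    def test_identical_channels_give_one(self):
        x = np.random.default_rng(4).standard_normal(200)
        sig = np.column_stack([x, 2 * x, -x])
        for c in range(3):
            assert mean_abs_corr(c, sig) == pytest.approx(1.0)

    def test_orthogonal_channel_gives_zero(self):
        sig = _tones([100.0, 150.0, 200.0])
        assert mean_abs_corr(0, sig) == pytest.approx(0.0, abs=1e-10)

    def test_matches_double_loop_oracle(self):
        sig = np.random.default_rng(5).standard_normal((300, 7))
        for c in range(7):
            expect = np.mean([abs(pearson_r(sig[:, c], sig[:, r]))
                              for r in range(7) if r != c])
            assert mean_abs_corr(c, sig) == pytest.approx(expect)


# ---------------------------------------------------------------------------
# PCR index
# ---------------------------------------------------------------------------

class TestPcrScores:
    def test_equal_power_half_correlation(self):
        # two unit-power signals with r = 0.5 exactly
        u, v = _tones([100.0, 150.0]).T
        sig = np.column_stack([u, 0.5 * u + np.sqrt(0.75) * v])
        tab = pcr_scores(sig, FS)
        np.testing.assert_allclose(tab["mean_abs_corr"], 0.5, atol=1e-9)
        np.testing.assert_allclose(tab["pcr"], 2.0, rtol=0.02)

    def test_amplified_channel_ranks_first(self):
        rng = np.random.default_rng(6)
        sig = rng.standard_normal((4096, 7))
        sig[:, 3] *= 2.0  # correlations are scale-invariant; power quadruples
        tab = pcr_scores(sig, FS)
        assert tab["pcr"].idxmax() == 3
        assert select_pcr_matrix(sig, k=1) == [3]

    def test_duplicating_a_channel_lowers_its_pcr(self):
        rng = np.random.default_rng(7)
        base = rng.standard_normal((4096, 6))
        before = pcr_scores(base, FS)["pcr"][0]
        dup = np.column_stack([base, base[:, 0]])
        after = pcr_scores(dup, FS)["pcr"]
        assert after[0] < before and after[6] < before

    def test_uncorrelated_channel_gets_infinite_pcr(self):
        u, v = _tones([100.0, 150.0]).T
        sig = np.column_stack([u, u, v])  # v orthogonal to both copies of u
        tab = pcr_scores(sig, FS)
        assert np.isinf(tab["pcr"][2])
        assert tab["pcr"].idxmax() == 2

    def test_common_gain_invariance(self):
        sig = np.random.default_rng(8).standard_normal((4096, 7))
        a = pcr_scores(sig, FS)["pcr"]
        b = pcr_scores(3.7 * sig, FS)["pcr"]
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_monotone_in_single_channel_gain(self):
        # attenuated channel keeps its power below the per-muscle maximum,
        # where normalized power (and hence PCR) responds strictly to gain
        base = np.random.default_rng(9).standard_normal((4096, 7))
        values = []
        for gain in (0.4, 0.7):
            sig = base.copy()
            sig[:, 2] *= gain
            values.append(pcr_scores(sig, FS)["pcr"][2])
        assert values[0] < values[1]


def select_pcr_matrix(sig, k):
    """Rank one matrix of channels by PCR (helper mirroring select_pcr)."""
    tab = pcr_scores(sig, FS)
    order = np.lexsort((tab["channel"], -tab["pcr"]))
    return list(order[:k])


# ---------------------------------------------------------------------------
# PCA loadings
# ---------------------------------------------------------------------------

class TestPcaLoadings:
    def test_duplicated_channel_pc1(self):
        x = np.random.default_rng(10).standard_normal(500)
        loadings, evf = pca_loadings(np.column_stack([x, x]), n_pcs=1)
        np.testing.assert_allclose(np.abs(loadings[0]), 1 / np.sqrt(2), atol=1e-9)
        assert evf[0] == pytest.approx(1.0)

    def test_diagonal_covariance(self):
        # two orthogonal mean-zero patterns with variances 9 and 1
        half = np.repeat([1.0, -1.0], 50)
        alt = np.tile([1.0, -1.0], 50)
        data = np.column_stack([3 * half, alt])
        loadings, evf = pca_loadings(data, n_pcs=2)
        np.testing.assert_allclose(np.abs(loadings[0]), [1.0, 0.0], atol=1e-9)
        assert evf[0] == pytest.approx(0.9)

    def test_matches_eigendecomposition_oracle(self):
        data = np.random.default_rng(11).standard_normal((100, 7))
        loadings, evf = pca_loadings(data, n_pcs=7)
        cov = np.cov(data, rowvar=False)
        w, v = np.linalg.eigh(cov)
        w, v = w[::-1], v[:, ::-1]
        np.testing.assert_allclose(np.abs(loadings), np.abs(v.T), atol=1e-8)
        np.testing.assert_allclose(evf, w / w.sum(), atol=1e-10)


# ---------------------------------------------------------------------------
# selectors on envelope sets
# ---------------------------------------------------------------------------

class TestSelectors:
    def test_pca_time_finds_dominant_variance_channel(self, make_env):
        rng = np.random.default_rng(12)
        emg = rng.standard_normal((2048, 7))
        le = np.abs(emg)
        le[:, 4] *= 10.0
        env = make_env(emg, le=le)
        sel = select_pca_time(env, k=1)
        assert sel.selected["biceps_long"] == [4]

    def test_k7_selects_everything(self, make_env):
        env = make_env(np.random.default_rng(13).standard_normal((2048, 21)))
        for method in ("pcr", "pca_time", "pca_freq"):
            sel = select_channels(env, method, k=7)
            for m in env.muscles:
                assert sorted(sel.selected[m]) == list(range(7))

    def test_pca_freq_finds_doubled_magnitude_channels(self, make_env):
        # spectrally near-identical channels (one shared source), three of
        # them with doubled magnitude -> those carry the largest PC1 loading
        rng = np.random.default_rng(14)
        source = rng.standard_normal(4096)
        gains = np.ones(21)
        boosted = {0: 2, 1: 10, 2: 18}  # one channel per muscle
        gains[list(boosted.values())] = 2.0
        emg = np.outer(source, gains) + 0.05 * rng.standard_normal((4096, 21))
        sel = select_pca_freq(make_env(emg), k=1)
        for mi, m in enumerate(("biceps_long", "biceps_short", "brachioradialis")):
            assert sel.selected[m] == [boosted[mi] - 7 * mi]

    def test_pca_freq_permutation_invariant(self, make_env):
        rng = np.random.default_rng(15)
        emg = rng.standard_normal((4096, 21)) * (1 + rng.random(21))
        base = select_pca_freq(make_env(emg), k=3)
        perm = np.concatenate([rng.permutation(7) + 7 * b for b in range(3)])
        permuted = select_pca_freq(make_env(emg[:, perm]), k=3)
        for b, m in enumerate(base.selected):
            relabeled = {np.flatnonzero(perm == 7 * b + c)[0] - 7 * b
                         for c in base.selected[m]}
            assert set(permuted.selected[m]) == relabeled

    def test_single_pc_matches_multi_pc_when_pc1_dominates(self, make_env):
        # common modulation drives almost all envelope variance -> PC1
        # fraction > 0.9 and variance-weighted voting agrees across n_pcs
        rng = np.random.default_rng(16)
        drive = np.abs(np.sin(np.linspace(0, 3 * np.pi, 4096)))
        gains = 0.5 + rng.random(7)
        le = np.outer(drive, gains) + 0.01 * rng.random((4096, 7))
        env = make_env(rng.standard_normal((4096, 7)), le=le)
        s1 = select_pca_time(env, k=3, n_pcs=1)
        s2 = select_pca_time(env, k=3, n_pcs=2)
        assert s1.score_table["evf_pc1"][0] > 0.9
        assert s1.selected == s2.selected

    def test_rankings_are_nested_in_k(self, env):
        for method in ("pcr", "pca_time", "pca_freq"):
            sels = {k: select_channels(env, method, k) for k in (1, 2, 3)}
            for m in env.muscles:
                assert sels[1].selected[m] == sels[2].selected[m][:1]
                assert sels[2].selected[m] == sels[3].selected[m][:2]

    def test_tie_break_prefers_lowest_index(self, make_env):
        x = np.random.default_rng(17).standard_normal(2048)
        emg = np.column_stack([x] * 7)  # identical channels: exact score ties
        sel = select_pcr(make_env(emg), k=3)
        assert sel.selected["biceps_long"] == [0, 1, 2]

    def test_k_out_of_range_rejected(self, env):
        with pytest.raises(ValueError):
            select_pcr(env, k=8)

    def test_selection_json_round_trip(self, env, tmp_path):
        from emgforce import SelectionResult

        sel = select_pcr(env, 3)
        path = tmp_path / "sel.json"
        sel.to_json(path)
        back = SelectionResult.from_json(path)
        assert back.selected == sel.selected
        assert back.method == sel.method and back.k == sel.k
        pd.testing.assert_frame_equal(
            back.score_table, sel.score_table.reset_index(drop=True))


def test_dimensionality_reduction_arithmetic():
    assert dimensionality_reduction_pct(3) == pytest.approx(100 * 4 / 7)
    assert dimensionality_reduction_pct(7) == 0.0
    with pytest.raises(ValueError):
        dimensionality_reduction_pct(0)
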