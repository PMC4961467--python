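"""Shift-corrected CCFs, directional tuning (NSR) and triggered averages."""
import numpy as np
import pytest

from pcmux.core import SaccadeEvent, SpikeTrain, TimeSeries
from pcmux.xcorr import (
    DirectionalCCF,
    ccf_significance,
    directional_ccf,
    nsr,
    nsr_compare,
    onset_triggered_average,
    rectified_projection,
    shift_corrected_ccf,
    subset_ccf_similarity,
)


def _noise_ts(n=20000, seed=0, rate=1000.0):
    return TimeSeries(np.random.default_rng(seed).standard_normal(n), rate)


class TestShiftCorrectedCcf:
    def test_autocorrelation_unity_at_zero(self):
        x = _noise_ts()
        r = shift_corrected_ccf(x, TimeSeries(x.samples.copy(), x.rate),
                                "ccf", M_shift=15, max_lag_ms=50)
        i0 = np.argmin(np.abs(r.lags_ms))
        assert r.value[i0] == pytest.approx(1.0, abs=0.02)

    def test_independent_noise_within_control_envelope(self):
        r = shift_corrected_ccf(_noise_ts(seed=1), _noise_ts(seed=2),
                                "ccf", M_shift=19, max_lag_ms=100)
        frac = np.mean(np.abs(r.value) < 3 * r.control_sd)
        assert frac >= 0.99

    def test_shift_correction_unbiased(self):
        # Monte-Carlo over pairs: mean corrected CCF ~ 0 within 3 SE
        vals = []
        for s in range(30):
            r = shift_corrected_ccf(_noise_ts(8000, seed=100 + s),
                                    _noise_ts(8000, seed=200 + s),
                                    "ccf", M_shift=6, max_lag_ms=50)
            vals.append(r.value)
        vals = np.asarray(vals)
        se = vals.std() / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se

    def test_single_spike_sta_collapses(self):
        x = _noise_ts(seed=5)
        r = shift_corrected_ccf(x, SpikeTrain([5.0]), "sta", M_shift=10, max_lag_ms=20)
        i0 = np.argmin(np.abs(r.lags_ms))
        raw = r.value[i0] + r.control_mean[i0]
        assert raw == pytest.approx(x.samples[5000] / x.samples.std(), abs=1e-12)

    def test_sta_equals_brute_force_spike_loop(self):
        x = _noise_ts(seed=6)
        spk = SpikeTrain(np.sort(np.random.default_rng(7).uniform(1, 19, 80)))
        r = shift_corrected_ccf(x, spk, "sta", M_shift=12, max_lag_ms=10)
        binned = spk.binned(x.rate, len(x.samples))
        idx = np.where(binned > 0)[0]
        lags = np.round(r.lags_ms).astype(int)
        L = len(x.samples)
        brute = np.array(
            [sum(binned[i] * x.samples[(i + k) % L] for i in idx) for k in lags]
        ) / (x.samples.std() * binned.sum())
        assert np.allclose(r.value + r.control_mean, brute, atol=1e-12)

    def test_too_many_shifts_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            shift_corrected_ccf(_noise_ts(3000), _noise_ts(3000), "ccf", M_shift=10)

    def test_zero_variance_errors(self):
        flat = TimeSeries(np.full(20000, 2.0), 1000.0)
        with pytest.raises(ValueError, match="variance"):
            shift_corrected_ccf(flat, _noise_ts(), "ccf", M_shift=5)


class TestCcfSignificance:
    def test_baseline_not_significant(self):
        r = shift_corrected_ccf(_noise_ts(seed=8), _noise_ts(seed=9),
                                "ccf", T=0.3, M_shift=60, max_lag_ms=100)
        assert not ccf_significance(r)["significant"]

    def test_large_excursion_significant(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(20000)
        y = np.roll(x, -20) + 0.5 * rng.standard_normal(20000)  # strong correlation
        r = shift_corrected_ccf(TimeSeries(x, 1000.0), TimeSeries(y, 1000.0),
                                "ccf", T=0.15, M_shift=120, max_lag_ms=100)
        assert ccf_significance(r)["significant"]

    def test_false_positive_rate_calibrated(self):
        hits = 0
        n_pairs = 150
        for s in range(n_pairs):
            r = shift_corrected_ccf(_noise_ts(6000, seed=1000 + s),
                                    _noise_ts(6000, seed=5000 + s),
                                    "ccf", M_shift=99, max_lag_ms=100, T=0.05)
            if ccf_significance(r)["significant"]:
                hits += 1
        assert hits / n_pairs <= 0.03  # nominal 1%


def _motion(seed=0, n=30000, rate=1000.0, axis=0.0):
    """Eye velocity along one axis (bursts), as a 2-vector TimeSeries."""
    rng = np.random.default_rng(seed)
    env = np.clip(rng.standard_normal(n), 0, None)
    th = np.radians(axis)
    v = np.outer(env * 100.0, [np.cos(th), np.sin(th)])
    return TimeSeries(v, rate)


class TestDirectionalCcf:
    def test_opposite_direction_row_flat(self):
        vel = _motion(axis=0.0)
        sig = _noise_ts(30000, seed=3)
        d = directional_ccf(sig, vel, angles=np.array([180.0]), M_shift=10)
        # rectification of pure 0-deg motion at 180 deg gives the zero signal
        assert np.allclose(rectified_projection(vel, 180.0).samples, 0.0)
        assert np.allclose(d.ccf_matrix, 0.0, atol=1e-12)

    def test_rotation_permutes_rows(self):
        rng = np.random.default_rng(11)
        env = np.clip(rng.standard_normal(30000), 0, None) * 100
        ang = rng.uniform(0, 2 * np.pi, 30000)
        v = np.column_stack([env * np.cos(ang), env * np.sin(ang)])
        vel = TimeSeries(v, 1000.0)
        rot = np.radians(45.0)
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        vel_rot = TimeSeries(v @ R.T, 1000.0)
        sig = _noise_ts(30000, seed=12)
        d0 = directional_ccf(sig, vel, M_shift=10)
        d1 = directional_ccf(sig, vel_rot, M_shift=10)
        assert np.allclose(np.roll(d0.ccf_matrix, 1, axis=0), d1.ccf_matrix, atol=1e-9)


class TestNsr:
    def test_identical_rows_zero(self):
        row = np.sin(np.linspace(0, 3, 50))
        d = DirectionalCCF(np.arange(8) * 45.0, np.arange(50), np.tile(row, (8, 1)))
        assert nsr(d) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_rows_closed_form(self):
        # rows = c * e_i: brute-force matrix arithmetic oracle
        c = 2.0
        M = c * np.eye(8)
        d = DirectionalCCF(np.arange(8) * 45.0, np.arange(8), M)
        mean_row = M.mean(axis=0)
        expected = M.var(axis=0, ddof=0).sum() / (mean_row**2).sum()
        assert nsr(d) == pytest.approx(expected)
        assert nsr(d) == pytest.approx(7.0)  # 8*(0.5 - 1/16) / (8 * 1/16)

    def test_scale_invariance(self):
        rng = np.random.default_rng(13)
        M = rng.standard_normal((8, 40))
        d1 = DirectionalCCF(np.arange(8) * 45.0, np.arange(40), M)
        d2 = DirectionalCCF(np.arange(8) * 45.0, np.arange(40), 17.0 * M)
        assert nsr(d1) == pytest.approx(nsr(d2))

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(14)
        M = rng.standard_normal((8, 40))
        d1 = DirectionalCCF(np.arange(8) * 45.0, np.arange(40), M)
        d2 = DirectionalCCF(np.arange(8) * 45.0, np.arange(40), M[::-1])
        assert nsr(d1) == pytest.approx(nsr(d2))

    def test_zero_mean_errors(self):
        d = DirectionalCCF(np.arange(8) * 45.0, np.arange(5), np.zeros((8, 5)))
        with pytest.raises(ValueError, match="NSR"):
            nsr(d)


class TestNsrCompare:
    def test_tuned_vs_untuned(self):
        # spikes carry direction tuning (generator truth); the LFP does not
        from pcmux.synthgen import SynthConfig, gen_session

        s = gen_session(SynthConfig(duration_s=120.0), seed=7)
        res = nsr_compare(
            s.spikes.simple(),
            s.lfp,
            s.velocity,
            n_controls=100,
            M_shift=60,
        )
        # direction-tuned spiking varies more across angles than the
        # direction-free LFP response
        assert res["nsr_a"] > res["nsr_b"]
        assert res["direction"] == "a_more" and res["p"] < 0.05

    def test_identical_signals_no_difference(self, session60):
        res = nsr_compare(session60.lfp, session60.lfp, session60.velocity,
                          n_controls=40, M_shift=30)
        assert res["direction"] == "none"
        assert res["nsr_a"] == pytest.approx(res["nsr_b"])

    def test_swap_symmetry(self, session60):
        a = nsr_compare(session60.lfp,
                        TimeSeries(session60.lfp.samples[::-1].copy(), 1000.0),
                        session60.velocity, n_controls=30, M_shift=20)
        b = nsr_compare(TimeSeries(session60.lfp.samples[::-1].copy(), 1000.0),
                        session60.lfp,
                        session60.velocity, n_controls=30, M_shift=20)
        assert a["t"] == pytest.approx(-b["t"], rel=1e-9)
        assert a["p"] == pytest.approx(b["p"], rel=1e-9)


class TestOnsetTriggeredAverage:
    def _saccades(self, onsets, thetas):
        return [
            SaccadeEvent(onset=o, offset=o + 0.03, angle_theta=th, amplitude=5.0)
            for o, th in zip(onsets, thetas)
        ]

    def test_identical_waveform_every_bin(self):
        sig = TimeSeries(np.tile(np.sin(np.linspace(0, 2 * np.pi, 1000)), 30), 1000.0)
        onsets = np.arange(2, 25, 1.0)  # every second: identical local signal
        sacc = self._saccades(onsets, np.linspace(0, 315, len(onsets)) % 360)
        out = onset_triggered_average(sig, sacc, bin_by="theta")
        filled = out["matrix"][out["counts"] > 0]
        assert np.allclose(filled - filled[0], 0.0, atol=1e-9)

    def test_circular_binning_wraparound(self):
        sig = _noise_ts(30000)
        sacc = self._saccades([5.0], [350.0])
        out = onset_triggered_average(sig, sacc, bin_by="theta")
        assert out["counts"][0] == 1  # theta=0 bin catches 350 deg

    def test_theta_independent_signal_uniform_bins(self):
        rng = np.random.default_rng(15)
        sig = _noise_ts(120000, seed=16)
        onsets = rng.uniform(2, 115, 300)
        sacc = self._saccades(onsets, rng.uniform(0, 360, 300))
        out = onset_triggered_average(sig, sacc, bin_by="theta")
        spread = out["matrix"].mean(axis=1)
        assert np.abs(spread - spread.mean()).max() < 4 / np.sqrt(out["counts"].min())

    def test_empty_bin_flagged(self):
        sig = _noise_ts(20000)
        sacc = self._saccades([3.0, 4.0], [0.0, 5.0])
        out = onset_triggered_average(sig, sacc, bin_by="theta")
        assert len(out["empty_bins"]) > 0
        assert np.isnan(out["matrix"][out["empty_bins"][0]]).all()


class TestSubsetCcfSimilarity:
    def _dccf(self, M):
        return DirectionalCCF(np.arange(8) * 45.0, np.arange(M.shape[1]), M)

    def test_self_similarity_one(self, rng):
        M = rng.standard_normal((8, 30))
        assert subset_ccf_similarity(self._dccf(M), self._dccf(M)) == pytest.approx(1.0)

    def test_negated_minus_one(self, rng):
        M = rng.standard_normal((8, 30))
        assert subset_ccf_similarity(self._dccf(M), self._dccf(-M)) == pytest.approx(-1.0)

    def test_noisy_subset_matches_closed_form(self, rng):
        M = rng.standard_normal((8, 2000))
        snr = 3.0
        N = M + rng.standard_normal(M.shape) * (M.std() / snr)
        expected = 1.0 / np.sqrt(1.0 + 1.0 / snr**2)
        assert subset_ccf_similarity(self._dccf(M), self._dccf(N)) == pytest.approx(
            expected, abs=0.02
        )

    def test_length_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="shapes"):
            subset_ccf_similarity(
                self._dccf(rng.standard_normal((8, 30))),
                self._dccf(rng.standard_normal((8, 31))),
            )
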