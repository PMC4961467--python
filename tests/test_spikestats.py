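"""ISI asymmetry, rate-matched controls, power-law tails, classification."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcmux.core import SpikeTrain
from pcmux.spikestats import (
    ai_excess_test,
    ai_isi_correlation,
    asymmetry_index,
    classify_spikes,
    fit_powerlaw_tail,
    local_rates,
    rate_matched_controls,
)
from pcmux.synthgen import gen_powerlaw_isis


def train_from_isis(isis, t0=0.0):
    return SpikeTrain(t0 + np.concatenate([[0.0], np.cumsum(isis)]))


class TestAsymmetryIndex:
    def test_symmetric_isis_zero(self):
        st_ = asymmetry_index(train_from_isis([0.02] * 10))
        assert np.allclose(st_.ai[st_.valid], 0.0)
        assert np.allclose(st_.cv2[st_.valid], 0.0)

    def test_direct_arithmetic(self):
        st_ = asymmetry_index(train_from_isis([0.020, 0.060]))
        assert st_.ai[1] == pytest.approx(0.5)
        assert st_.cv2[1] == pytest.approx(1.0)

    def test_limit_long_post_isi(self):
        st_ = asymmetry_index(train_from_isis([0.02, 50.0]))
        assert st_.ai[1] == pytest.approx(1.0, abs=1e-3)

    def test_boundary_spikes_flagged(self):
        st_ = asymmetry_index(train_from_isis([0.02] * 5))
        assert np.isnan(st_.ai[0]) and np.isnan(st_.ai[-1])

    def test_too_few_spikes(self):
        with pytest.raises(ValueError):
            asymmetry_index(SpikeTrain([0.0, 0.1]))

    @given(st.lists(st.floats(0.005, 0.5), min_size=3, max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_cv2_identity(self, isis):
        st_ = asymmetry_index(train_from_isis(isis))
        v = st_.valid
        assert np.allclose(st_.cv2[v], 2.0 * np.abs(st_.ai[v]))


class TestRateMatchedControls:
    def test_rate_matched_mean_isi(self):
        train = train_from_isis([0.02] * 500)
        ctrl = rate_matched_controls(train, n_controls=60, seed=0)
        mean_isi = np.mean([c.isis.mean() for c in ctrl])
        # refractory resampling lifts the mean slightly above 20 ms
        assert mean_isi == pytest.approx(0.020, rel=0.10)

    def test_literal_mode_mean_isi(self):
        train = train_from_isis([0.02] * 500)
        ctrl = rate_matched_controls(train, n_controls=40, mode="literal", seed=0)
        mean_isi = np.mean([c.isis.mean() for c in ctrl])
        assert mean_isi == pytest.approx(0.040, rel=0.08)

    def test_refractory_enforced(self):
        train = train_from_isis(np.full(300, 0.006))
        for c in rate_matched_controls(train, n_controls=10, seed=1):
            assert c.isis.min() >= 0.004

    def test_spike_count_preserved(self, simple60):
        ctrl = rate_matched_controls(simple60, n_controls=5, seed=2)
        for c in ctrl:
            assert abs(len(c) - len(simple60)) <= 0.1 * len(simple60)

    def test_local_rate_truncated_windows(self):
        train = train_from_isis([0.01, 0.02, 0.03, 0.04, 0.05, 0.06])
        r = local_rates(train)
        assert r[0] == pytest.approx(3 / (0.01 + 0.02 + 0.03))
        assert r[2] == pytest.approx(5 / (0.01 + 0.02 + 0.03 + 0.04 + 0.05))


class TestAiExcessTest:
    def test_regular_train_with_pauses_significant(self):
        rng = np.random.default_rng(4)
        isis = np.full(3000, 0.018) * rng.normal(1, 0.03, 3000)
        pause_at = rng.choice(3000, 100, replace=False)
        isis[pause_at] += rng.uniform(0.05, 0.2, 100)
        train = train_from_isis(isis)
        ctrl = rate_matched_controls(train, n_controls=60, seed=5)
        res = ai_excess_test(train, ctrl)
        assert res["p"] < 0.01 and res["excess_at_zero"] > 0

    def test_poisson_train_no_excess(self):
        rng = np.random.default_rng(6)
        train = train_from_isis(rng.exponential(0.02, 3000) + 0.004)
        ctrl = rate_matched_controls(train, n_controls=60, seed=7)
        assert ai_excess_test(train, ctrl)["p"] > 0.01

    def test_self_control_calibrated(self):
        rng = np.random.default_rng(8)
        train = train_from_isis(rng.gamma(2.0, 0.01, 2000) + 0.004)
        ctrl = rate_matched_controls(train, n_controls=40, seed=9)
        hits = sum(ai_excess_test(c, ctrl)["p"] < 0.01 for c in ctrl[:20])
        assert hits <= 2  # ~1% nominal rate, small-sample slack


class TestPowerlawFit:
    def test_closed_form_mle(self):
        fit = fit_powerlaw_tail(np.array([2.0, 4.0, 8.0]), xmin=2.0, min_tail=3)
        assert fit.alpha == pytest.approx(1.0 + 1.0 / np.log(2.0), rel=1e-12)

    def test_mle_consistency(self):
        x = gen_powerlaw_isis(2.5, 1.0, 100_000, seed=10)
        fit = fit_powerlaw_tail(x, xmin=1.0)
        assert fit.alpha == pytest.approx(2.5, abs=0.02)

    def test_xmin_selection_recovers_tail(self):
        rng = np.random.default_rng(11)
        body = rng.uniform(0.001, 0.03, 20000)
        tail = gen_powerlaw_isis(3.5, 0.03, 4000, seed=12)
        fit = fit_powerlaw_tail(np.concatenate([body, tail]))
        assert fit.alpha == pytest.approx(3.5, abs=0.25)
        assert fit.xmin == pytest.approx(0.03, rel=0.35)

    def test_exponential_favored_on_exponential_data(self):
        rng = np.random.default_rng(13)
        x = 0.01 + rng.exponential(0.02, 20000)
        fit = fit_powerlaw_tail(x, xmin=0.01)
        assert fit.loglik_ratio < 0

    def test_powerlaw_favored_on_powerlaw_data(self):
        x = gen_powerlaw_isis(3.78, 0.03, 20000, seed=14)
        fit = fit_powerlaw_tail(x, xmin=0.03)
        assert fit.loglik_ratio > 0 and fit.p_alt < 0.01

    def test_small_tail_errors(self):
        with pytest.raises(ValueError, match="tail"):
            fit_powerlaw_tail(np.array([1.0, 2.0, 3.0]), xmin=1.0)


def _distinct_ai_train(n=10_000, seed=42):
    """Regular ~10 ms firing with 20% long pauses, all AI values distinct."""
    rng = np.random.default_rng(seed)
    isis = 0.010 + rng.uniform(0, 0.002, n - 1)
    k = (n - 1) // 5
    isis[rng.choice(n - 1, k, replace=False)] = rng.uniform(0.05, 0.2, k)
    return train_from_isis(isis)


class TestClassifySpikes:
    def test_exact_percentile_arithmetic(self):
        train = _distinct_ai_train()
        cls = classify_spikes(train)
        # 15% of 9,998 AI-defined spikes -> 1500, minus 25% -> exactly 1,125
        assert cls.counts()["pause_initiating"] == 1125

    def test_selected_fraction_near_ten_percent(self):
        train = _distinct_ai_train()
        cls = classify_spikes(train)
        frac = cls.counts()["pause_initiating"] / len(train)
        assert 0.08 <= frac <= 0.13

    def test_periodic_train_pause_groups_empty(self):
        train = train_from_isis(np.full(999, 0.02))
        cls = classify_spikes(train)
        c = cls.counts()
        assert c.get("pause_initiating", 0) == 0
        assert c.get("pause_terminating", 0) == 0

    def test_translation_and_rescale_invariance(self):
        train = _distinct_ai_train(2000)
        c0 = classify_spikes(train).category
        shifted = SpikeTrain(train.times + 123.4)
        scaled = SpikeTrain(train.times * 2.0)
        assert (classify_spikes(shifted).category == c0).all()
        assert (classify_spikes(scaled).category == c0).all()

    def test_groups_disjoint_and_no_complex(self, session60):
        cls = classify_spikes(session60.spikes)
        cx = session60.spikes.kinds == "complex"
        assert (cls.category[cx] == "unclassified").all()
        # categories are a partition by construction; check counts sum
        assert sum(cls.counts().values()) == len(session60.spikes)

    def test_too_few_spikes_errors(self):
        with pytest.raises(ValueError):
            classify_spikes(train_from_isis(np.full(50, 0.02)))


class TestAiIsiCorrelation:
    def test_exact_exponential_relation(self):
        rng = np.random.default_rng(15)
        ai = rng.uniform(-0.8, 0.8, 500)
        from pcmux.spikestats import ISIStats

        post = 0.02 * 10**ai
        st_ = ISIStats(pre_isi=post, post_isi=post, ai=ai, cv2=2 * np.abs(ai))
        assert ai_isi_correlation(st_) == pytest.approx(1.0)

    def test_shuffled_near_zero(self):
        rng = np.random.default_rng(16)
        from pcmux.spikestats import ISIStats

        ai = rng.uniform(-0.8, 0.8, 2000)
        post = 0.02 * 10 ** rng.permutation(ai)
        st_ = ISIStats(pre_isi=post, post_isi=post, ai=ai, cv2=2 * np.abs(ai))
        assert abs(ai_isi_correlation(st_)) < 0.1

    def test_generator_pauses_positive_correlation(self, simple60):
        st_ = asymmetry_index(simple60)
        assert ai_isi_correlation(st_) > 0.5
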