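"""Point-process generator: refractoriness, rate compensation, ground truth."""

import warnings

import numpy as np
import pytest

from spikedeconv import (
    CohortSpec,
    NeuronSpec,
    PairSimConfig,
    apply_connectivity,
    burst_index,
    compute_ach,
    generate_cohort,
    make_rate_function,
    sample_spike_train,
    simulate_pair,
)


def cfg_for(n1=None, n2=None, **kw):
    return PairSimConfig(
        neuron1=n1 or NeuronSpec(rate=5.0),
        neuron2=n2 or NeuronSpec(rate=5.0),
        **kw,
    )


class TestRateFunction:
    def test_constant_without_comodulation(self):
        cfg = cfg_for(duration=10.0)
        r1, r2 = make_rate_function(cfg, np.random.default_rng(0))
        assert r1.size == cfg.n_samples
        np.testing.assert_allclose(r1, 5.0)

    def test_modified_rate_formula(self):
        # lambda_m = lambda_d * gamma / (1 + BR), BR = BR1 (1 + BR2)
        n = NeuronSpec(rate=5.0, gamma=2, br1=0.0)
        assert n.modified_rate == pytest.approx(10.0)
        n = NeuronSpec(rate=2.0, gamma=1, br1=0.4, br2=0.4)
        assert n.burst_fraction == pytest.approx(0.56)
        assert n.modified_rate == pytest.approx(2.0 / 1.56)

    def test_comodulation_is_shared_zero_mean_and_clipped(self):
        cfg = cfg_for(duration=200.0, comod_sigma=6.0)
        r1, r2 = make_rate_function(cfg, np.random.default_rng(0))
        rel1 = r1 / 5.0 - 1.0
        rel2 = r2 / 5.0 - 1.0
        np.testing.assert_allclose(rel1, rel2)  # identical modulation
        assert abs(rel1.mean()) < 0.05
        assert rel1.max() <= 1.0 and rel1.min() >= -1.0


class TestSampleSpikeTrain:
    def test_poisson_with_arp_rate_and_min_isi(self, rng):
        spec = NeuronSpec(rate=5.0)
        idx = sample_spike_train((spec.modified_rate, 3_600_000), spec, 0.001, rng)
        rate = idx.size / 3600.0
        assert rate == pytest.approx(5.0, rel=0.05)
        assert np.diff(idx).min() >= 2  # ARP = 2 ms at 1 ms steps

    def test_rate_compensation_with_bursts_and_gamma(self, rng):
        for spec in (NeuronSpec(rate=5.0, br1=0.4), NeuronSpec(rate=8.0, gamma=2)):
            idx = sample_spike_train(
                (spec.modified_rate, 3_600_000), spec, 0.001, rng
            )
            assert idx.size / 3600.0 == pytest.approx(spec.rate, rel=0.05)

    def test_burst_train_has_positive_burst_index(self, rng):
        from spikedeconv import SpikeTrain

        spec = NeuronSpec(rate=5.0, br1=0.4)
        idx = sample_spike_train((spec.modified_rate, 3_600_000), spec, 0.001, rng)
        tr = SpikeTrain(idx * 0.001, duration=3600.0)
        bi = burst_index(compute_ach(tr, half_width_bins=50)).burst_index
        assert bi > 0.2
        ach = compute_ach(tr)
        m = ach.half_width
        # inserted burst spikes produce a short-latency ACH peak (2-6 ms)
        assert ach.counts[m + 2 : m + 7].mean() > 2 * ach.counts[m + 20 : m + 31].mean()

    def test_gamma_two_delays_ach_rise(self, rng):
        poisson = NeuronSpec(rate=8.0)
        gamma2 = NeuronSpec(rate=8.0, gamma=2)
        ach_ratio = {}
        for name, spec in (("g1", poisson), ("g2", gamma2)):
            from spikedeconv import SpikeTrain

            idx = sample_spike_train(
                (spec.modified_rate, 3_600_000), spec, 0.001, rng
            )
            tr = SpikeTrain(idx * 0.001, duration=3600.0)
            ach = compute_ach(tr)
            m = ach.half_width
            ach_ratio[name] = ach.counts[m + 3] / max(ach.counts[m + 30], 1)
        assert ach_ratio["g2"] < ach_ratio["g1"]

    def test_excessive_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_spike_train((1200.0, 1000), NeuronSpec(rate=1200.0), 0.001, rng)


class TestApplyConnectivity:
    def test_zero_gain_is_identity(self, rng):
        post = np.array([10, 50, 90])
        out = apply_connectivity(np.array([5, 40]), post, 0.0, 100, rng)
        np.testing.assert_array_equal(out, post)

    def test_excitatory_added_count_concentrates_at_gain(self):
        added = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pre = np.arange(0, 600_000, 100)  # 6000 presynaptic spikes
            post = np.empty(0, dtype=int)
            out = apply_connectivity(pre, post, 0.04, 600_000, rng)
            added.append(out.size)
        mean_added = np.mean(added)
        assert mean_added == pytest.approx(0.04 * 6000, rel=0.05)

    def test_excitatory_latencies_within_stc_window(self, rng):
        pre = np.arange(0, 100_000, 50)
        out = apply_connectivity(pre, np.empty(0, dtype=int), 0.5, 100_000, rng)
        lags = out[:, None] - pre[None, :]
        lags = lags[(lags > 0) & (lags <= 10)]
        assert lags.min() >= 1 and lags.max() <= 5

    def test_inhibitory_realized_gain_matches_configured(self):
        import dataclasses

        gains = []
        for seed in range(4):
            base = cfg_for(
                n1=NeuronSpec(rate=2.0), n2=NeuronSpec(rate=8.0),
                duration=7200.0, seed=seed,
            )
            on = dataclasses.replace(base, stg12=-0.015)
            p_on = simulate_pair(on)
            p_off = simulate_pair(base)
            gains.append((p_on.s2.n_spikes - p_off.s2.n_spikes) / p_on.s1.n_spikes)
        assert np.mean(gains) == pytest.approx(-0.015, rel=0.12)

    def test_inhibitory_gain_magnitude_capped(self, rng):
        with pytest.raises(ValueError):
            apply_connectivity(np.array([1]), np.array([3]), -1.5, 100, rng)


class TestSimulatePair:
    def test_arp_respected_and_truth_recorded(self):
        cfg = cfg_for(
            n1=NeuronSpec(rate=4.0, br1=0.3),
            n2=NeuronSpec(rate=8.0, gamma=2),
            stg12=0.04, duration=1800.0, seed=3,
        )
        pair = simulate_pair(cfg)
        assert pair.truth == {
            "stg12": 0.04, "stg21": 0.0, "connection_label": "excitatory"
        }
        for tr in (pair.s1, pair.s2):
            assert tr.isis().min() >= 0.002 - 1e-12

    def test_same_seed_bit_identical(self):
        cfg = cfg_for(stg12=0.02, comod_sigma=4.0, duration=600.0, seed=11)
        a, b = simulate_pair(cfg), simulate_pair(cfg)
        np.testing.assert_array_equal(a.s1.times, b.s1.times)
        np.testing.assert_array_equal(a.s2.times, b.s2.times)

    def test_loop_gain_warning_only(self):
        cfg = cfg_for(stg12=0.05, stg21=0.05, duration=60.0, seed=0)
        with pytest.warns(UserWarning, match="loop gain"):
            pair = simulate_pair(cfg)
        assert pair.s1.n_spikes > 0


class TestCohort:
    def test_default_class_sizes_and_scaling(self):
        spec = CohortSpec()
        assert (spec.n_excitatory, spec.n_inhibitory, spec.n_unconnected) == (
            500, 500, 250,
        )
        small = spec.scaled(0.1)
        assert (small.n_excitatory, small.n_inhibitory, small.n_unconnected) == (
            50, 50, 25,
        )

    def test_gain_distribution_and_reproducibility(self):
        configs = generate_cohort(CohortSpec(), seed=5)
        assert len(configs) == 1250
        exc = [c.stg12 for _, c in configs if c.stg12 > 0]
        inh = [c.stg12 for _, c in configs if c.stg12 < 0]
        assert len(exc) == 500 and len(inh) == 500
        assert np.mean(exc) == pytest.approx(0.019, rel=0.08)
        assert np.mean(inh) == pytest.approx(-0.014, rel=0.08)
        brs = [c.neuron1.br1 for _, c in configs]
        assert 0 <= min(brs) and max(brs) <= 0.4
        comod = [c.comod_sigma > 0 for _, c in configs]
        assert np.mean(comod) == pytest.approx(0.6, abs=0.05)
        again = generate_cohort(CohortSpec(), seed=5)
        assert all(a[1] == b[1] for a, b in zip(configs, again))
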