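import numpy as np
import pytest

from cebsim.plasticity import PlasticityRuleParams
from cebsim.protocol import (LesionConfig, ProtocolConfig, cio_probability,
                             draw_cio_targets, generate_cs, generate_us,
                             run_experiment, schedule_cio)
from cebsim.scaffold import NetworkConfig
from cebsim.protocol import build_default_network


class TestProtocolConfig:
    def test_default_timeline(self):
        p = ProtocolConfig()
        assert p.trial_length == 1260
        assert p.cs_onset == 500
        assert p.us_onset == 750
        assert p.cr_window == (550, 750)

    def test_us_must_coterminate_with_cs(self):
        with pytest.raises(ValueError, match="co-terminate"):
            ProtocolConfig(isi_ms=200)          # CS still 260 ms

    def test_isi_variants_shift_us_window(self):
        p = ProtocolConfig().with_isi(200)
        assert p.cs_duration_ms == 210
        assert p.us_onset == 700
        assert ProtocolConfig().with_isi(300).us_onset == 800

    def test_cio_latency_must_precede_us(self):
        with pytest.raises(ValueError):
            ProtocolConfig(cio_latency_ms=260)


class TestGenerateCS:
    def test_nontargeted_mfs_carry_background_only(self):
        proto = ProtocolConfig()
        mask = np.array([True] * 5 + [False] * 7)
        rng = np.random.default_rng(0)
        counts_t = counts_o = 0
        n = 300
        for _ in range(n):
            tr = generate_cs(proto, rng, mask)
            counts_t += tr[mask, 500:760].sum()
            counts_o += tr[~mask, 500:760].sum()
        # targeted: 10 Hz CS + 1 Hz background; others: 1 Hz background
        per_t = counts_t / (n * 5)
        per_o = counts_o / (n * 7)
        se = np.sqrt(2.86 / (n * 5))
        assert per_t == pytest.approx(10e-3 * 260 + 1e-3 * 260, abs=3 * se)
        assert per_o == pytest.approx(1e-3 * 260, abs=0.1)

    def test_zero_rate_config_gives_empty_trains(self):
        proto = ProtocolConfig(cs_rate_hz=0.0, background_rate_hz=0.0)
        tr = generate_cs(proto, np.random.default_rng(0), np.ones(4, bool))
        assert tr.sum() == 0


class TestGenerateUS:
    def test_five_spikes_per_downbound_io(self):
        proto = ProtocolConfig()
        down = np.array([True, True, False])
        us = generate_us(proto, down)
        assert us[0].sum() == 5          # 500 Hz x 10 ms
        assert us[2].sum() == 0          # upbound receives nothing
        times = np.flatnonzero(us[0])
        assert times.min() >= 750 and times.max() < 760

    def test_isi_200_variant_window(self):
        proto = ProtocolConfig().with_isi(200)
        us = generate_us(proto, np.array([True]))
        times = np.flatnonzero(us[0])
        assert times.min() == 700 and times.max() < 710


class TestCIOSchedule:
    def test_probability_ramp(self):
        proto = ProtocolConfig()
        assert cio_probability(999, 1000, proto) == pytest.approx(0.43)
        assert cio_probability(0, 1000, proto) == pytest.approx(0.00043)
        assert cio_probability(499, 1000, proto) == pytest.approx(0.215)

    def test_out_of_range_trial(self):
        with pytest.raises(ValueError):
            cio_probability(10, 10, ProtocolConfig())

    def test_burst_shape_and_fixed_targets(self):
        proto = ProtocolConfig()
        down = np.array([True, True, True, False])
        rng = np.random.default_rng(0)
        targets = draw_cio_targets(down, 0.5, rng)
        assert targets.sum() == 2 and not targets[~down].any()
        burst = None
        for _ in range(50):
            burst = schedule_cio(999, 1000, proto, rng, targets)
            if burst is not None:
                break
        assert burst is not None
        row = burst[np.flatnonzero(targets)[0]]
        times = np.flatnonzero(row)
        assert times.size == 4                      # 400 Hz x 10 ms
        assert times.min() == 588                   # CS onset + 88 ms
        assert not burst[~targets].any()


class TestRunExperiment:
    @pytest.fixture(scope="class")
    def tiny_result(self):
        net = build_default_network(NetworkConfig(scale_factor=0.05, seed=3))
        proto = ProtocolConfig(n_blocks=1, trials_per_block=3, n_seeds=1)
        pl = PlasticityRuleParams(LTP_PC=1e-5, LTD_PC=1e-4, LTP_MLI=1e-4,
                                  LTD_MLI=1e-5)
        res = run_experiment(net, proto, pl, LesionConfig("control"),
                             master_seed=2)
        return net, proto, pl, res

    def test_trial_count_and_recording(self, tiny_result):
        net, proto, pl, res = tiny_result
        assert len(res.trials) == 1
        assert len(res.trials[0]) == 3
        ids, ts = res.trials[0][0].of("PC")
        assert ts.size > 0
        assert ts.min() >= 0 and ts.max() < proto.trial_length

    def test_weight_snapshots_once_per_block(self, tiny_result):
        net, proto, pl, res = tiny_result
        snaps = res.weight_snapshots[0]["GrC_pf_PC"]
        assert snaps.shape[0] == proto.n_blocks + 1   # initial + per block

    def test_master_seed_reproducibility(self, tiny_result):
        net, proto, pl, res = tiny_result
        res2 = run_experiment(net, proto, pl, LesionConfig("control"),
                              master_seed=2)
        for a, b in zip(res.trials[0], res2.trials[0]):
            for pop in a.spikes:
                np.testing.assert_array_equal(a.of(pop)[0], b.of(pop)[0])
                np.testing.assert_array_equal(a.of(pop)[1], b.of(pop)[1])


class TestIsiVariantEndToEnd:
    def test_isi_200_smoke(self, small_network):
        proto = ProtocolConfig(n_blocks=1, trials_per_block=2,
                               n_seeds=1).with_isi(200)
        res = run_experiment(small_network, proto, PlasticityRuleParams(),
                             LesionConfig("control"), master_seed=6)
        ids, ts = res.trials[0][0].of("PC")
        assert ts.max() < proto.trial_length == 1210
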