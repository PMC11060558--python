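"""Engine-level tests: determinism, lesions, and the online-plasticity
equivalence with the offline rule oracles."""

import numpy as np
import pytest

from cebsim.plasticity import PlasticityRuleParams, pf_mli_update, pf_pc_update
from cebsim.protocol import LesionConfig, make_engine
from cebsim.scaffold import NetworkConfig
from cebsim.protocol import build_default_network


def _background(engine, T, rng):
    return (rng.random((engine.n["mf"], T)) < 0.002).astype(float)


class TestDeterminism:
    def test_identical_seeds_identical_spikes(self, small_network):
        outs = []
        for _ in range(2):
            eng = make_engine(small_network, LesionConfig("control"),
                              PlasticityRuleParams(LTP_PC=1e-5, LTD_PC=1e-4,
                                                   LTP_MLI=1e-4, LTD_MLI=1e-5),
                              np.random.default_rng(42))
            rng = np.random.default_rng(7)
            eng.reset_trial_state(rng=rng)
            rec = eng.run_trial(_background(eng, 600, rng))
            outs.append(rec)
        for pop in outs[0].spikes:
            np.testing.assert_array_equal(outs[0].of(pop)[0], outs[1].of(pop)[0])
            np.testing.assert_array_equal(outs[0].of(pop)[1], outs[1].of(pop)[1])

    def test_zero_rates_freeze_weights(self, small_network):
        eng = make_engine(small_network, LesionConfig("control"),
                          PlasticityRuleParams(), np.random.default_rng(0))
        w0 = eng.plastic_weights()
        rng = np.random.default_rng(1)
        eng.reset_trial_state(rng=rng)
        # deliver a US-like IO burst so teaching spikes do occur
        io = np.zeros((eng.n["IO"], 600), dtype=bool)
        io[:, 300:310:2] = True
        eng.run_trial(_background(eng, 600, rng), io_input=io)
        for name, w in eng.plastic_weights().items():
            np.testing.assert_array_equal(w, w0[name])


class TestLesions:
    def test_mli_ko_zeroes_mli_pc_conductances(self, small_network):
        eng = make_engine(small_network, LesionConfig("mli_ko"),
                          PlasticityRuleParams(), np.random.default_rng(0))
        for g in eng.groups:
            if g.name in ("SC_PC", "BC_PC"):
                data = g.w_flat if g.gather else g.W.data
                assert np.all(data == 0.0)

    def test_control_keeps_mli_pc_conductances(self, small_network):
        eng = make_engine(small_network, LesionConfig("control"),
                          PlasticityRuleParams(), np.random.default_rng(0))
        for g in eng.groups:
            if g.name in ("SC_PC", "BC_PC"):
                data = g.w_flat if g.gather else g.W.data
                assert np.all(data > 0.0)


class TestOnlinePlasticityMatchesOracles:
    """The engine's online updates must equal the offline rule functions
    evaluated on the recorded (arrival-aligned) spike trains."""

    @pytest.fixture(scope="class")
    def run(self):
        net = build_default_network(NetworkConfig(scale_factor=0.05, seed=3))
        pl = PlasticityRuleParams(LTP_PC=1e-6, LTD_PC=1e-6,
                                  LTP_MLI=1e-6, LTD_MLI=1e-7)
        eng = make_engine(net, LesionConfig("control"), pl,
                          np.random.default_rng(5),
                          recorded=("GrC", "PC", "SC", "BC", "IO"))
        rng = np.random.default_rng(9)
        eng.reset_trial_state(rng=rng)
        T = 700
        mf = (rng.random((eng.n["mf"], T)) < 0.01).astype(float)
        io = np.zeros((eng.n["IO"], T), dtype=bool)
        io[:, 400:410:2] = True   # strong teaching burst
        w_before = eng.plastic_weights()
        rec = eng.run_trial(mf, io_input=io)
        return net, eng, pl, rec, w_before, T

    @staticmethod
    def _trains(rec, pop, n):
        out = {i: [] for i in range(n)}
        ids, ts = rec.of(pop)
        for i, t in zip(ids, ts):
            out[int(i)].append(float(t))
        return {i: np.array(v) for i, v in out.items()}

    def _cf_arrivals(self, net, eng, rec, post_pop, cf_type, delay):
        """Per-postsynaptic-cell sorted cf arrival times."""
        io_tr = self._trains(rec, "IO", eng.n["IO"])
        syn = net.synapses
        sub = syn[syn.type == cf_type]
        glob2loc = eng.glob2loc
        out = {}
        for post, grp in sub.groupby("post"):
            j = int(glob2loc[post])
            times = np.concatenate([io_tr[int(glob2loc[p])] + delay
                                    for p in grp.pre])
            out[j] = np.unique(times)
        return out

    def test_pf_mli_weights_match_convolution_oracle(self, run):
        net, eng, pl, rec, w_before, T = run
        grc_tr = self._trains(rec, "GrC", eng.n["GrC"])
        g = eng.plastic_group("GrC_pf_SC")
        cf_delay = net.spec_by_name("IO_SC").delay
        cf_arr = self._cf_arrivals(net, eng, rec, "SC", "IO_SC", cf_delay)
        checked = 0
        for k in range(0, g.w.size, 37):    # sample synapses
            pre, post = int(g.pre[k]), int(g.post[k])
            pf_arr = grc_tr[pre] + g.delay
            pf_arr = pf_arr[pf_arr < T]
            cf = cf_arr.get(post, np.array([]))
            cf = cf[cf < T]
            dw = pf_mli_update(np.sort(pf_arr), np.sort(cf), pl)
            got = eng.plastic_group("GrC_pf_SC").w[k] - w_before["GrC_pf_SC"][k]
            assert got == pytest.approx(dw, abs=1e-12), (pre, post)
            checked += 1
        assert checked > 10

    def test_pf_pc_weights_match_window_oracle(self, run):
        net, eng, pl, rec, w_before, T = run
        grc_tr = self._trains(rec, "GrC", eng.n["GrC"])
        g = eng.plastic_group("GrC_pf_PC")
        cf_delay = net.spec_by_name("IO_PC").delay
        cf_arr = self._cf_arrivals(net, eng, rec, "PC", "IO_PC", cf_delay)
        checked = 0
        for k in range(0, g.w.size, 53):
            pre, post = int(g.pre[k]), int(g.post[k])
            pf_arr = grc_tr[pre] + g.delay
            pf_arr = pf_arr[pf_arr < T]
            cf = cf_arr.get(post, np.array([]))
            cf = cf[cf < T]
            dw = pf_pc_update(np.sort(pf_arr), np.sort(cf), pl)
            got = eng.plastic_group("GrC_pf_PC").w[k] - w_before["GrC_pf_PC"][k]
            assert got == pytest.approx(dw, abs=1e-12), (pre, post)
            checked += 1
        assert checked > 10

    def test_weights_stay_inside_bounds(self, run):
        net, eng, pl, rec, w_before, T = run
        for g in eng.plastic_groups:
            assert np.all(g.w >= pl.w_min)
            assert np.all(g.w <= pl.w_max_factor * g.w_init + 1e-12)


class TestNumericSafety:
    def test_nonfinite_state_aborts(self, small_engine):
        small_engine.V[0] = np.nan
        with pytest.raises(FloatingPointError):
            small_engine.run_trial(np.zeros((small_engine.n["mf"], 60)))


class TestOlivaryFeedback:
    def test_dcn_gaba_feedback_lowers_io_response(self, small_network):
        """Nucleo-olivary feedback reduces the IO response to a
        conditioned-IO-like burst versus a feedback-severed network."""
        counts = {}
        for cut, label in ((False, "intact"), (True, "severed")):
            eng = make_engine(small_network, LesionConfig("control"),
                              PlasticityRuleParams(), np.random.default_rng(3),
                              plasticity_enabled=False)
            if cut:
                eng.scale_weights({"DCN_GABA_IO": 0.0})
            rng = np.random.default_rng(8)
            eng.reset_trial_state(rng=rng)
            total = 0
            for _ in range(10):
                T = 700
                mf = (rng.random((eng.n["mf"], T)) < 0.001).astype(float)
                io_in = np.zeros((eng.n["IO"], T), dtype=bool)
                io_in[:, 400:410:3] = True
                rec = eng.run_trial(mf, io_input=io_in)
                ids, ts = rec.of("IO")
                total += int(np.sum((ts >= 400) & (ts < 430)))
            counts[label] = total
        assert counts["intact"] <= counts["severed"]
        assert counts["severed"] > 0
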